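"""Population-level intersexual-dominance records: schema, classification,
contest-mix statistics, standardization and sensitivity-subset filters.

The unit of observation is a study population of a primate species.  Each
record may carry raw counts of intersexual contests won by adult females
(``wins_female``) and by adult males (``wins_male``), a summarized percentage
won by females, and/or a qualitative statement that one sex is always
dominant.  Two outcome codings are derived:

* a continuous coding, the proportion of intersexual contests won by
  females, and
* an ordered three-level coding — strict male dominance, no strict sex bias,
  strict female dominance — where "strict" means one sex won more than 90 %
  of contests or is reported to always win.

Ties at exactly 90 % are classified as no strict bias (the rule is strictly
greater-than).  Qualitative statements are used only when neither counts nor
a percentage are available.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AggregationError,
    ClassificationError,
    DataValidationError,
    StandardizationError,
    UndefinedMeasureError,
)

logger = logging.getLogger(__name__)

STRICT_THRESHOLD = 0.90  # strictly greater-than on the winning sex's share

__all__ = [
    "DominanceCategory",
    "Qualitative",
    "PopulationObservation",
    "classify_dominance",
    "percent_won_by_females",
    "contest_mix_fractions",
    "opposite_sex_dyad_fraction",
    "aggregate_groups",
    "standardize_predictor",
    "subset_exclude_lemurs",
    "subset_exclude_dimorphic",
    "read_dominance_table",
    "observations_from_table",
    "table_from_observations",
    "STRICT_THRESHOLD",
]


class DominanceCategory(enum.IntEnum):
    """Ordered three-level dominance coding (ascending female bias)."""

    STRICT_MALE = 0
    NO_STRICT_BIAS = 1
    STRICT_FEMALE = 2

    def __str__(self) -> str:  # stable names for tables/reports
        return self.name.lower()


class Qualitative(str, enum.Enum):
    """Qualitative dominance statement extracted from a source."""

    FEMALE_ALWAYS = "female_always"
    MALE_ALWAYS = "male_always"
    NONE = "none"
    UNKNOWN = "unknown"


@dataclass
class PopulationObservation:
    """One study population's dominance record.

    ``wins_female``/``wins_male`` are raw contest counts; ``pct_female_won``
    may be present without counts (summarized sources).  ``contests_mm/ff/mf``
    are within/between-sex interaction counts used for the contest-mix
    statistics; ``n_adult_males``/``n_adult_females`` describe group
    composition for the opposite-sex dyad fraction.
    """

    species: str
    population_id: str
    wins_female: int | None = None
    wins_male: int | None = None
    pct_female_won: float | None = None
    qualitative_dominance: Qualitative = Qualitative.UNKNOWN
    contests_mm: int | None = None
    contests_ff: int | None = None
    contests_mf: int | None = None
    n_adult_males: int | None = None
    n_adult_females: int | None = None
    captive: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.qualitative_dominance, str):
            self.qualitative_dominance = Qualitative(self.qualitative_dominance)
        for name in ("wins_female", "wins_male", "contests_mm", "contests_ff",
                     "contests_mf", "n_adult_males", "n_adult_females"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DataValidationError(f"{name} must be >= 0, got {v}")
        if (self.wins_female is None) != (self.wins_male is None):
            raise DataValidationError(
                f"{self.species}/{self.population_id}: wins_female and "
                "wins_male must be given together")
        if self.has_counts and self.pct_female_won is not None:
            if self.total_intersexual > 0 and not math.isclose(
                    self.pct_female_won,
                    self.wins_female / self.total_intersexual,
                    abs_tol=1e-9):
                raise DataValidationError(
                    f"{self.species}/{self.population_id}: pct_female_won "
                    "inconsistent with counts")
        if self.pct_female_won is not None and not 0 <= self.pct_female_won <= 1:
            raise DataValidationError("pct_female_won must be in [0, 1]")

    @property
    def has_counts(self) -> bool:
        return self.wins_female is not None and self.wins_male is not None

    @property
    def total_intersexual(self) -> int:
        if not self.has_counts:
            raise UndefinedMeasureError("no contest counts recorded")
        return self.wins_female + self.wins_male


def percent_won_by_females(obs: PopulationObservation) -> float:
    """Proportion of intersexual contests won by females, in [0, 1].

    Uses raw counts when available, else the stored summarized percentage.
    """
    if obs.has_counts and obs.total_intersexual > 0:
        return obs.wins_female / obs.total_intersexual
    if obs.pct_female_won is not None:
        return obs.pct_female_won
    raise UndefinedMeasureError(
        f"{obs.species}/{obs.population_id}: neither counts (N > 0) nor a "
        "percentage are available")


def classify_dominance(obs: PopulationObservation) -> DominanceCategory:
    """Three-level strict-dominance classification.

    Strict female dominance: females won > 90 % of intersexual contests, or a
    qualitative report that females always win; strict male dominance is the
    mirror image; everything else is no strict bias.  The qualitative
    statement is consulted only when no quantitative information exists.
    """
    try:
        p = percent_won_by_females(obs)
    except UndefinedMeasureError:
        q = obs.qualitative_dominance
        if q is Qualitative.FEMALE_ALWAYS:
            return DominanceCategory.STRICT_FEMALE
        if q is Qualitative.MALE_ALWAYS:
            return DominanceCategory.STRICT_MALE
        if q is Qualitative.NONE:
            return DominanceCategory.NO_STRICT_BIAS
        raise ClassificationError(
            f"{obs.species}/{obs.population_id}: no counts, percentage or "
            "qualitative statement") from None
    if p > STRICT_THRESHOLD:
        return DominanceCategory.STRICT_FEMALE
    if 1.0 - p > STRICT_THRESHOLD:
        return DominanceCategory.STRICT_MALE
    return DominanceCategory.NO_STRICT_BIAS


def contest_mix_fractions(mm: int, ff: int, mf: int) -> tuple[float, float, float]:
    """Fractions of agonistic interactions that are male-male, female-female
    and male-female.  Defined only for groups with at least one contest."""
    for name, v in (("mm", mm), ("ff", ff), ("mf", mf)):
        if v < 0:
            raise DataValidationError(f"contests_{name} must be >= 0")
    total = mm + ff + mf
    if total == 0:
        raise UndefinedMeasureError("no contests recorded in any dyad class")
    return mm / total, ff / total, mf / total


def opposite_sex_dyad_fraction(n_m: int, n_f: int) -> float:
    """Proportion of all adult dyads in a group that are male-female.

    With ``n_m`` adult males and ``n_f`` adult females there are
    ``n_m * n_f`` opposite-sex dyads out of ``C(n_m + n_f, 2)`` total.
    """
    n = n_m + n_f
    if n < 2:
        raise UndefinedMeasureError(
            f"need >= 2 adults to form a dyad, got {n}")
    return (n_m * n_f) / (n * (n - 1) / 2)


def aggregate_groups(groups: list[PopulationObservation],
                     pool_counts: bool = True) -> PopulationObservation:
    """Combine per-group records of one population into a single record.

    Contest counts are summed (pooled) when every group reports raw counts
    and ``pool_counts`` is true; otherwise quantitative fields are averaged
    across groups.  Composition and contest-class counts are summed when
    present in all groups.  Qualitative statements must agree or be unknown.
    """
    if not groups:
        raise AggregationError("no group records to aggregate")
    if len(groups) == 1:
        return groups[0]
    species = {g.species for g in groups}
    if len(species) != 1:
        raise AggregationError(f"records span multiple species: {species}")
    pop_ids = {g.population_id for g in groups}
    if len(pop_ids) != 1:
        raise AggregationError(f"records span multiple populations: {pop_ids}")
    g0 = groups[0]

    all_counts = all(g.has_counts for g in groups)
    any_counts = any(g.has_counts for g in groups)
    if any_counts and not all_counts and pool_counts:
        raise AggregationError(
            f"{g0.species}/{g0.population_id}: mixed count/percentage groups "
            "cannot be pooled; supply pool_counts=False to average")

    kwargs: dict = dict(species=g0.species, population_id=g0.population_id,
                        captive=any(g.captive for g in groups))
    if all_counts and pool_counts:
        kwargs["wins_female"] = sum(g.wins_female for g in groups)
        kwargs["wins_male"] = sum(g.wins_male for g in groups)
    else:
        pcts = [percent_won_by_females(g) for g in groups
                if g.has_counts or g.pct_female_won is not None]
        if pcts:
            kwargs["pct_female_won"] = float(np.mean(pcts))

    quals = {g.qualitative_dominance for g in groups} - {Qualitative.UNKNOWN}
    if len(quals) == 1:
        kwargs["qualitative_dominance"] = quals.pop()
    elif len(quals) > 1:
        kwargs["qualitative_dominance"] = Qualitative.UNKNOWN

    for name in ("contests_mm", "contests_ff", "contests_mf",
                 "n_adult_males", "n_adult_females"):
        vals = [getattr(g, name) for g in groups]
        if all(v is not None for v in vals):
            kwargs[name] = sum(vals)
    return PopulationObservation(**kwargs)


def standardize_predictor(values) -> np.ndarray:
    """Center and scale a continuous predictor to mean 0, sample SD 1.

    Missing values (NaN) are ignored for the moments and propagated to the
    output.  Uses the sample (n-1) SD convention.
    """
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    if mask.sum() < 2:
        raise StandardizationError(
            f"need >= 2 non-missing values, got {int(mask.sum())}")
    sd = float(np.std(x[mask], ddof=1))
    if sd == 0.0:
        raise StandardizationError("predictor has zero variance")
    out = x.copy()
    out[mask] = (x[mask] - x[mask].mean()) / sd
    return out


# ----------------------------------------------------------------------
# Sensitivity-subset filters (operate on the tabular representation)

LEMUR_CLADE = "lemuriformes"


def subset_exclude_lemurs(table: pd.DataFrame,
                          clade_map: dict[str, str]) -> pd.DataFrame:
    """Drop every record whose species is annotated as Lemuriformes.

    ``clade_map`` maps species name to a major-clade label; every species in
    the table must be annotated.  Used to check that associations are not
    driven solely by the lemur/non-lemur contrast.
    """
    species = table["species"].unique()
    missing = [s for s in species if s not in clade_map]
    if missing:
        raise DataValidationError(
            f"species lacking clade annotation: {', '.join(sorted(missing))}")
    is_lemur = table["species"].map(
        lambda s: clade_map[s].strip().casefold() == LEMUR_CLADE)
    n_drop = int(is_lemur.sum())
    if n_drop:
        logger.info("excluding %d lemur records (%d retained)",
                    n_drop, len(table) - n_drop)
    return table.loc[~is_lemur].reset_index(drop=True)


DIMORPHISM_RATIO = 1.10


def subset_exclude_dimorphic(table: pd.DataFrame,
                             male_mass: dict[str, float],
                             female_mass: dict[str, float]) -> pd.DataFrame:
    """Drop species whose male body mass exceeds 1.10 x female body mass.

    The rule is strictly greater-than: a ratio of exactly 1.10 is retained.
    Species with a missing mass are dropped with a logged warning rather
    than silently kept.
    """
    missing: set[str] = set()

    def keep(sp: str) -> bool:
        m, f = male_mass.get(sp), female_mass.get(sp)
        if m is None or f is None or not (math.isfinite(m) and math.isfinite(f)):
            missing.add(sp)
            return False
        return not (m > DIMORPHISM_RATIO * f)

    mask = table["species"].map(keep)
    if missing:
        logger.warning("dropping %d species with missing body mass: %s",
                       len(missing), ", ".join(sorted(missing)[:8])
                       + ("..." if len(missing) > 8 else ""))
    return table.loc[mask].reset_index(drop=True)


# ----------------------------------------------------------------------
# Delimited-text schema

SCHEMA_COLUMNS = [
    "species", "population_id", "wins_female", "wins_male", "pct_female_won",
    "qualitative_dominance", "contests_mm", "contests_ff", "contests_mf",
    "n_adult_males", "n_adult_females", "captive",
]

_COUNT_COLS = ["wins_female", "wins_male", "contests_mm", "contests_ff",
               "contests_mf", "n_adult_males", "n_adult_females"]


def read_dominance_table(path) -> pd.DataFrame:
    """Read the documented delimited-text schema (comma or tab, auto-detected).

    Extra columns (predictors declared elsewhere) pass through untouched.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"species", "population_id"} - set(df.columns)
    if missing:
        raise DataValidationError(
            f"table lacks required columns: {', '.join(sorted(missing))}")
    for col in SCHEMA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df


def observations_from_table(table: pd.DataFrame
                            ) -> tuple[list[PopulationObservation], list[dict]]:
    """Convert table rows into validated observations.

    Returns the valid observations and an audit log of excluded rows, each
    entry recording the row index, species and exclusion reason.
    """
    obs_list: list[PopulationObservation] = []
    audit: list[dict] = []
    known = set(SCHEMA_COLUMNS)
    for i, row in table.iterrows():
        try:
            qual = row.get("qualitative_dominance")
            if qual is None or (isinstance(qual, float) and math.isnan(qual)):
                qual = "unknown"
            kwargs = dict(
                species=str(row["species"]),
                population_id=str(row["population_id"]),
                qualitative_dominance=str(qual),
                captive=bool(row.get("captive", False))
                if not pd.isna(row.get("captive", False)) else False,
                extras={k: row[k] for k in table.columns if k not in known},
            )
            for col in _COUNT_COLS:
                v = row.get(col)
                kwargs[col] = None if pd.isna(v) else int(v)
            v = row.get("pct_female_won")
            kwargs["pct_female_won"] = None if pd.isna(v) else float(v)
            obs = PopulationObservation(**kwargs)
            classify_dominance(obs)  # must be classifiable to enter analysis
            obs_list.append(obs)
        except Exception as exc:
            audit.append({"row": int(i), "species": str(row.get("species")),
                          "reason": f"{type(exc).__name__}: {exc}"})
            logger.warning("excluding row %d (%s): %s", i,
                           row.get("species"), exc)
    return obs_list, audit


def table_from_observations(obs_list: list[PopulationObservation]) -> pd.DataFrame:
    """Inverse of :func:`observations_from_table` for the schema columns."""
    rows = []
    for o in obs_list:
        row = {c: getattr(o, c) for c in SCHEMA_COLUMNS
               if c not in ("qualitative_dominance", "captive")}
        row["qualitative_dominance"] = o.qualitative_dominance.value
        row["captive"] = o.captive
        row.update(o.extras)
        rows.append(row)
    return pd.DataFrame(rows)
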