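"""Orchestration: join data to tree, run the signal analysis and the
per-predictor model battery with sensitivity subsets, and render reports.

The battery mirrors the study design it implements: one univariate model
per predictor and outcome coding (binomial on win counts, ordinal on the
three-level category), followed by conditional subset reruns — a supported
(reliable) predictor is retested after excluding lemurs, an unsupported one
after excluding the most sexually dimorphic species.  No multiple-testing
correction is applied; each association is judged by its own 89 %
compatibility interval, and that choice is deliberate and documented.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    DominanceCategory,
    classify_dominance,
    observations_from_table,
    read_dominance_table,
    standardize_predictor,
    subset_exclude_dimorphic,
    subset_exclude_lemurs,
    table_from_observations,
)
from .errors import ConfigError, PhylodomError, SampleSizeError
from .models import (
    PhyloGLMSpec,
    PosteriorSummary,
    fit_binomial_phylo,
    fit_ordinal_phylo,
)
from .signal import KResult, blomberg_k, encode_categorical_for_k, k_significance
from .trees import (
    PhyloCovariance,
    normalize_label,
    normalize_vcv,
    phylo_vcv,
    prune_to_taxa,
    read_newick,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSpec",
    "RunConfig",
    "HypothesisReport",
    "load_config",
    "join_data_to_tree",
    "run_signal_analysis",
    "run_hypothesis_battery",
    "render_report",
    "parse_report",
]


@dataclass(frozen=True)
class PredictorSpec:
    """One predictor in the manifest: name, type, hypothesis, expected sign."""

    name: str
    type: str = "continuous"            # or "categorical"
    hypothesis: str = ""
    expected_direction: int = 0         # +1, -1, or 0 (no expectation)

    def __post_init__(self):
        if self.type not in ("continuous", "categorical"):
            raise ConfigError(f"predictor {self.name}: unknown type {self.type!r}")
        if self.expected_direction not in (-1, 0, 1):
            raise ConfigError(f"predictor {self.name}: expected_direction "
                              "must be -1, 0 or +1")


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration; echoed verbatim into the run manifest."""

    data_path: str
    tree_path: str
    out_dir: str
    predictors: tuple[PredictorSpec, ...] = ()
    exclude_lemurs: bool = False
    exclude_dimorphic: bool = False
    exclude_captive: bool = False
    vcv_normalization: str = "correlation"
    clade_column: str = "clade"
    male_mass_column: str = "male_mass"
    female_mass_column: str = "female_mass"
    chains: int = 4
    draws_total: int = 8000
    warmup_per_chain: int | None = None
    n_sims_signal: int = 10_000
    seed: int = 0

    def sampler_spec(self, seed: int) -> PhyloGLMSpec:
        return PhyloGLMSpec(chains=self.chains, draws_total=self.draws_total,
                            warmup_per_chain=self.warmup_per_chain, seed=seed)


def load_config(path) -> RunConfig:
    """Load a YAML run manifest into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    preds = tuple(PredictorSpec(**p) for p in raw.pop("predictors", []))
    try:
        return RunConfig(predictors=preds, **raw)
    except TypeError as exc:
        raise ConfigError(f"bad config keys: {exc}") from exc


def _split_seed(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n, dtype=np.uint64)]


# ----------------------------------------------------------------------
def join_data_to_tree(table: pd.DataFrame, tree) -> tuple[pd.DataFrame, object]:
    """Match data species to tree tips after label normalization.

    Species missing from the tree are dropped with a logged warning (never
    fuzzy-matched); the tree is pruned to the matched species with tip
    depths preserved.
    """
    tip_by_norm = {normalize_label(t): t for t in tree.tips}
    matched, dropped = {}, []
    for sp in table["species"].unique():
        hit = tip_by_norm.get(normalize_label(sp))
        if hit is None:
            dropped.append(sp)
        else:
            matched[sp] = hit
    if dropped:
        logger.warning("dropping %d species absent from tree: %s",
                       len(dropped), ", ".join(sorted(dropped)[:10]))
    if len(matched) < 3:
        raise SampleSizeError(
            f"only {len(matched)} species join to the tree; need >= 3")
    out = table[table["species"].isin(matched)].copy()
    out["species"] = out["species"].map(matched)   # adopt tree spelling
    pruned = prune_to_taxa(tree, set(matched.values())) \
        if len(matched) < tree.n_tips else tree
    return out.reset_index(drop=True), pruned


def _species_trait_means(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Species-level traits for the signal analysis.

    Continuous: species mean of the per-population proportion of contests
    won by females.  Categorical: the strict-dominance category of the
    pooled species record, scored 0/1/2.
    """
    obs, _ = observations_from_table(table)
    per_species_p: dict[str, list[float]] = {}
    per_species_cat: dict[str, list[int]] = {}
    from .data import percent_won_by_females
    from .errors import UndefinedMeasureError

    for o in obs:
        try:
            per_species_p.setdefault(o.species, []).append(
                percent_won_by_females(o))
        except UndefinedMeasureError:
            pass
        per_species_cat.setdefault(o.species, []).append(
            int(classify_dominance(o)))
    cont = pd.Series({s: float(np.mean(v))
                      for s, v in per_species_p.items()}, name="pct_female_won")
    # species category: median of population categories (ordered scale)
    cat = pd.Series({s: int(round(float(np.median(v))))
                     for s, v in per_species_cat.items()}, name="category")
    return cont, cat


def run_signal_analysis(config: RunConfig) -> dict[str, KResult]:
    """Blomberg's K with permutation significance for both outcome codings."""
    table = read_dominance_table(config.data_path)
    tree = read_newick(Path(config.tree_path).read_text())
    table, tree = join_data_to_tree(table, tree)
    cont, cat = _species_trait_means(table)
    seeds = _split_seed(config.seed, 2)
    results: dict[str, KResult] = {}

    cov = phylo_vcv(prune_to_taxa(tree, set(cont.index))
                    if len(cont) < tree.n_tips else tree)
    y = cont.reindex(list(cov.labels)).to_numpy()
    results["continuous"] = k_significance(
        y, cov, n_sims=config.n_sims_signal, seed=seeds[0])

    cov2 = phylo_vcv(prune_to_taxa(tree, set(cat.index))
                     if len(cat) < tree.n_tips else tree)
    scores = encode_categorical_for_k(
        cat.reindex(list(cov2.labels)).to_numpy())
    results["categorical"] = k_significance(
        scores, cov2, n_sims=config.n_sims_signal, seed=seeds[1])
    return results


# ----------------------------------------------------------------------
@dataclass
class HypothesisReport:
    """Battery results plus the run manifest.

    ``rows`` has one entry per predictor x outcome-coding x subset with the
    posterior summary for the slope (or the widest contrast), sample sizes,
    the reliability flag and, where an expectation exists, whether the sign
    of a reliable estimate matches it.
    """

    rows: list[dict] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = ["predictor", "outcome", "subset", "estimate", "lower",
                "upper", "n_populations", "n_species", "reliable",
                "direction_match", "converged", "max_rhat", "seed", "status"]
        if not self.rows:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.rows)[cols]


def _summary_row(pred: PredictorSpec, outcome: str, subset: str,
                 fit: PosteriorSummary | None, n_pop: int, n_sp: int,
                 seed: int, status: str = "ok", error: str = "") -> dict:
    row = {"predictor": pred.name, "outcome": outcome, "subset": subset,
           "estimate": np.nan, "lower": np.nan, "upper": np.nan,
           "n_populations": n_pop, "n_species": n_sp, "reliable": False,
           "direction_match": None, "converged": False, "max_rhat": np.nan,
           "seed": seed, "status": status, "error": error}
    if fit is not None:
        lo, hi = fit.beta_interval
        row.update(estimate=fit.beta_mean, lower=lo, upper=hi,
                   reliable=fit.reliable, converged=fit.converged,
                   max_rhat=fit.max_rhat)
        if fit.reliable and pred.expected_direction != 0:
            row["direction_match"] = bool(
                np.sign(fit.beta_mean) == pred.expected_direction)
    return row


def _prepare_tables(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial table (count records only) and ordinal table (all records)."""
    obs, _ = observations_from_table(table)
    full = table_from_observations(obs)
    full["category"] = [int(classify_dominance(o)) for o in obs]
    has_counts = full["wins_female"].notna() & full["wins_male"].notna()
    n_pos = (full.loc[has_counts, "wins_female"]
             + full.loc[has_counts, "wins_male"]) > 0
    binom = full.loc[has_counts].loc[n_pos].reset_index(drop=True)
    return binom, full


def _fit_one(outcome: str, data: pd.DataFrame, pred: PredictorSpec,
             cov: PhyloCovariance, spec: PhyloGLMSpec):
    fit_fn = fit_binomial_phylo if outcome == "binomial" else fit_ordinal_phylo
    return fit_fn(data, pred.name, cov, spec, strict=False,
                  standardize=(pred.type == "continuous"))


def run_hypothesis_battery(config: RunConfig) -> HypothesisReport:
    """Per-predictor binomial and ordinal fits with conditional subsets.

    Failures (non-convergence, empty subsets, too few species) become
    flagged rows; the battery always completes.
    """
    if not config.predictors:
        raise ConfigError("predictor manifest is empty")
    table = read_dominance_table(config.data_path)
    tree = read_newick(Path(config.tree_path).read_text())
    table, tree = join_data_to_tree(table, tree)
    if config.exclude_captive and "captive" in table:
        table = table[~table["captive"].fillna(False).astype(bool)]
        table = table.reset_index(drop=True)
    cov = normalize_vcv(phylo_vcv(tree), config.vcv_normalization)

    clade_map = {}
    if config.clade_column in table.columns:
        clade_map = (table.drop_duplicates("species")
                     .set_index("species")[config.clade_column]
                     .dropna().astype(str).to_dict())
    mass_m = mass_f = {}
    if config.male_mass_column in table.columns:
        sp = table.drop_duplicates("species").set_index("species")
        mass_m = sp[config.male_mass_column].dropna().to_dict()
        mass_f = sp[config.female_mass_column].dropna().to_dict()

    seeds = iter(_split_seed(config.seed, 4 * len(config.predictors) * 2))
    report = HypothesisReport(manifest=_manifest(config, table))

    for pred in config.predictors:
        for outcome in ("binomial", "ordinal"):
            seed = next(seeds)
            row = _battery_fit(table, pred, outcome, cov, config, seed)
            report.rows.append(row)
            # conditional subset rerun
            seed2 = next(seeds)
            if row["status"] == "not_estimable":
                continue
            if row["reliable"]:
                subset_name = "exclude_lemurs"
                try:
                    sub = subset_exclude_lemurs(table, clade_map)
                except PhylodomError as exc:
                    report.rows.append(_summary_row(
                        pred, outcome, subset_name, None, 0, 0, seed2,
                        status="not_estimable", error=str(exc)))
                    continue
            else:
                subset_name = "exclude_dimorphic"
                sub = subset_exclude_dimorphic(table, mass_m, mass_f)
            report.rows.append(
                _battery_fit(sub, pred, outcome, cov, config, seed2,
                             subset=subset_name))
    return report


def _battery_fit(table: pd.DataFrame, pred: PredictorSpec, outcome: str,
                 cov: PhyloCovariance, config: RunConfig, seed: int,
                 subset: str = "main") -> dict:
    binom, full = _prepare_tables(table) if len(table) else (table, table)
    data = binom if outcome == "binomial" else full
    n_pop = len(data)
    n_sp = data["species"].nunique() if n_pop else 0
    if n_pop == 0:
        return _summary_row(pred, outcome, subset, None, 0, 0, seed,
                            status="not_estimable", error="empty subset")
    try:
        fit = _fit_one(outcome, data, pred, cov,
                       config.sampler_spec(seed))
        status = "ok" if fit.converged else "not_converged"
        return _summary_row(pred, outcome, subset, fit, n_pop, n_sp, seed,
                            status=status)
    except PhylodomError as exc:
        logger.warning("%s/%s/%s failed: %s", pred.name, outcome, subset, exc)
        return _summary_row(pred, outcome, subset, None, n_pop, n_sp, seed,
                            status="not_estimable", error=str(exc))


def _manifest(config: RunConfig, table: pd.DataFrame) -> dict:
    payload = table.to_csv(index=False).encode()
    cfg = dataclasses.asdict(config)
    cfg["predictors"] = [dataclasses.asdict(p) for p in config.predictors]
    return {
        "config": cfg,
        "software": {"phylodom": __version__,
                     "python": platform.python_version(),
                     "numpy": np.__version__,
                     "pandas": pd.__version__},
        "data_hash": hashlib.sha256(payload).hexdigest(),
        "n_records": int(len(table)),
        "n_species": int(table["species"].nunique()),
    }


# ----------------------------------------------------------------------
def render_report(report: HypothesisReport, out_dir) -> dict[str, Path]:
    """Write the battery as delimited text + JSON plus a readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    paths = {
        "table": out / "battery.tsv",
        "json": out / "battery.json",
        "manifest": out / "manifest.json",
        "summary": out / "summary.txt",
    }
    frame.to_csv(paths["table"], sep="\t", index=False)
    paths["json"].write_text(json.dumps(
        {"rows": report.rows, "manifest": report.manifest},
        indent=2, default=_jsonify) + "\n")
    paths["manifest"].write_text(
        json.dumps(report.manifest, indent=2, default=_jsonify) + "\n")
    lines = ["predictor battery (89% compatibility intervals)", ""]
    if frame.empty:
        lines.append("(no rows)")
    for _, r in frame.iterrows():
        if np.isnan(r["estimate"]):
            lines.append(f"{r['predictor']:<20} {r['outcome']:<9} "
                         f"{r['subset']:<18} {r['status']}")
        else:
            flag = "reliable" if r["reliable"] else "not reliable"
            lines.append(
                f"{r['predictor']:<20} {r['outcome']:<9} {r['subset']:<18} "
                f"{r['estimate']:+.2f} [{r['lower']:+.2f}, {r['upper']:+.2f}]"
                f"  n={r['n_populations']}/{r['n_species']}sp  {flag}")
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths


def parse_report(json_path) -> HypothesisReport:
    """Inverse of :func:`render_report` for the JSON artifact."""
    payload = json.loads(Path(json_path).read_text())
    return HypothesisReport(rows=payload["rows"], manifest=payload["manifest"])


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
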