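"""Dominance records: classification, contest statistics, standardization,
aggregation and the sensitivity-subset filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylodom import (
    DominanceCategory,
    PopulationObservation,
    aggregate_groups,
    classify_dominance,
    contest_mix_fractions,
    opposite_sex_dyad_fraction,
    percent_won_by_females,
    standardize_predictor,
    subset_exclude_dimorphic,
    subset_exclude_lemurs,
)
from phylodom.data import (
    observations_from_table,
    read_dominance_table,
    table_from_observations,
)
from phylodom.errors import (
    AggregationError,
    ClassificationError,
    DataValidationError,
    StandardizationError,
    UndefinedMeasureError,
)


def obs(**kw):
    kw.setdefault("species", "sp")
    kw.setdefault("population_id", "p1")
    return PopulationObservation(**kw)


class TestClassification:
    @pytest.mark.parametrize("record, expected", [
        (dict(wins_female=91, wins_male=9), DominanceCategory.STRICT_FEMALE),
        (dict(wins_female=90, wins_male=10), DominanceCategory.NO_STRICT_BIAS),
        (dict(wins_female=0, wins_male=10), DominanceCategory.STRICT_MALE),
        (dict(qualitative_dominance="male_always"),
         DominanceCategory.STRICT_MALE),
        (dict(qualitative_dominance="female_always"),
         DominanceCategory.STRICT_FEMALE),
        (dict(pct_female_won=0.61), DominanceCategory.NO_STRICT_BIAS),
    ])
    def test_strict_rule(self, record, expected):
        assert classify_dominance(obs(**record)) is expected

    def test_counts_override_qualitative(self):
        rec = obs(wins_female=50, wins_male=50,
                  qualitative_dominance="female_always")
        assert classify_dominance(rec) is DominanceCategory.NO_STRICT_BIAS

    def test_no_information_raises(self):
        with pytest.raises(ClassificationError):
            classify_dominance(obs())

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_symmetry(self, p):
        """The category for female share p mirrors the one for 1 - p."""
        mirror = {DominanceCategory.STRICT_FEMALE: DominanceCategory.STRICT_MALE,
                  DominanceCategory.STRICT_MALE: DominanceCategory.STRICT_FEMALE,
                  DominanceCategory.NO_STRICT_BIAS:
                  DominanceCategory.NO_STRICT_BIAS}
        cat = classify_dominance(obs(pct_female_won=p))
        assert classify_dominance(obs(pct_female_won=1.0 - p)) is mirror[cat]

    @given(st.floats(min_value=0.0, max_value=1.0),
           st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_in_p(self, p1, p2):
        if p1 > p2:
            p1, p2 = p2, p1
        c1 = classify_dominance(obs(pct_female_won=p1))
        c2 = classify_dominance(obs(pct_female_won=p2))
        assert c1 <= c2


class TestPercentWon:
    @pytest.mark.parametrize("wf, wm, expected", [
        (0, 10, 0.0), (7, 3, 0.7), (10, 0, 1.0),
    ])
    def test_from_counts(self, wf, wm, expected):
        assert percent_won_by_females(
            obs(wins_female=wf, wins_male=wm)) == pytest.approx(expected)

    def test_percentage_passthrough(self):
        assert percent_won_by_females(obs(pct_female_won=0.61)) == 0.61

    def test_zero_contests_undefined(self):
        with pytest.raises(UndefinedMeasureError):
            percent_won_by_females(obs(wins_female=0, wins_male=0))


class TestContestMix:
    @pytest.mark.parametrize("mm, ff, mf, expected", [
        (10, 10, 20, (0.25, 0.25, 0.50)),
        (0, 0, 5, (0.0, 0.0, 1.0)),
    ])
    def test_examples(self, mm, ff, mf, expected):
        assert contest_mix_fractions(mm, ff, mf) == pytest.approx(expected)

    @given(st.integers(0, 1000), st.integers(0, 1000), st.integers(0, 1000))
    def test_sums_to_one(self, mm, ff, mf):
        if mm + ff + mf == 0:
            with pytest.raises(UndefinedMeasureError):
                contest_mix_fractions(mm, ff, mf)
        else:
            assert sum(contest_mix_fractions(mm, ff, mf)) == pytest.approx(1.0)


class TestDyadFraction:
    @pytest.mark.parametrize("nm, nf, expected", [
        (1, 1, 1.0), (2, 2, 4 / 6),
    ])
    def test_examples(self, nm, nf, expected):
        assert opposite_sex_dyad_fraction(nm, nf) == pytest.approx(expected)

    def test_enumeration_oracle(self):
        """(3, 5): count mixed pairs among all C(8, 2) = 28 dyads."""
        sexes = ["m"] * 3 + ["f"] * 5
        mixed = sum(1 for i in range(8) for j in range(i + 1, 8)
                    if sexes[i] != sexes[j])
        assert opposite_sex_dyad_fraction(3, 5) == pytest.approx(mixed / 28)
        assert mixed == 15

    def test_single_adult_undefined(self):
        with pytest.raises(UndefinedMeasureError):
            opposite_sex_dyad_fraction(1, 0)


class TestAggregation:
    def test_single_group_identity(self):
        g = obs(wins_female=4, wins_male=6)
        assert aggregate_groups([g]) is g

    def test_percentage_mean(self):
        out = aggregate_groups([obs(pct_female_won=0.4),
                                obs(pct_female_won=0.6)])
        assert out.pct_female_won == pytest.approx(0.5)

    def test_counts_pooled(self):
        out = aggregate_groups([obs(wins_female=4, wins_male=6),
                                obs(wins_female=6, wins_male=4)])
        assert (out.wins_female, out.wins_male) == (10, 10)
        assert percent_won_by_females(out) == pytest.approx(0.5)

    def test_permutation_invariance(self, rng):
        groups = [obs(wins_female=int(w), wins_male=int(m))
                  for w, m in rng.integers(0, 30, size=(6, 2))]
        a = aggregate_groups(groups)
        b = aggregate_groups(groups[::-1])
        assert (a.wins_female, a.wins_male) == (b.wins_female, b.wins_male)

    def test_mixed_units_rejected_when_pooling(self):
        with pytest.raises(AggregationError):
            aggregate_groups([obs(wins_female=4, wins_male=6),
                              obs(pct_female_won=0.5)])

    def test_cross_species_rejected(self):
        with pytest.raises(AggregationError):
            aggregate_groups([obs(species="a", pct_female_won=0.2),
                              obs(species="b", pct_female_won=0.4)])


class TestStandardize:
    def test_sample_sd_convention(self):
        assert np.allclose(standardize_predictor([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self, rng):
        x = standardize_predictor(rng.normal(5, 3, size=40))
        assert np.allclose(standardize_predictor(x), x, atol=1e-12)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50,
                    unique=True))
    def test_moments(self, values):
        z = standardize_predictor(values)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_missing_propagated(self):
        z = standardize_predictor([1.0, np.nan, 3.0, 5.0])
        assert np.isnan(z[1]) and not np.isnan(z[[0, 2, 3]]).any()

    def test_zero_variance_rejected(self):
        with pytest.raises(StandardizationError):
            standardize_predictor([2.0, 2.0, 2.0])


class TestSubsets:
    def make_table(self, species):
        return pd.DataFrame({"species": species,
                             "population_id": range(len(species))})

    def test_lemur_filter_by_tag(self, rng):
        species = [f"sp{i}" for i in range(20)]
        lemur = set(rng.choice(species, size=6, replace=False))
        clades = {s: ("Lemuriformes" if s in lemur else "Catarrhini")
                  for s in species}
        table = self.make_table(species)
        out = subset_exclude_lemurs(table, clades)
        assert set(out["species"]) == set(species) - lemur

    def test_no_lemurs_identity(self):
        table = self.make_table(["a", "b"])
        out = subset_exclude_lemurs(table, {"a": "Platyrrhini",
                                            "b": "Catarrhini"})
        assert len(out) == 2

    def test_missing_clade_annotation_rejected(self):
        with pytest.raises(DataValidationError):
            subset_exclude_lemurs(self.make_table(["a", "b"]), {"a": "x"})

    def test_dimorphism_threshold_strict(self):
        table = self.make_table(["at_ratio", "above", "below"])
        m = {"at_ratio": 1.10, "above": 1.11, "below": 0.9}
        f = {k: 1.0 for k in m}
        out = subset_exclude_dimorphic(table, m, f)
        assert set(out["species"]) == {"at_ratio", "below"}

    def test_dimorphism_matches_brute_force(self, rng):
        species = [f"sp{i}" for i in range(30)]
        m = {s: float(rng.uniform(0.8, 1.6)) for s in species}
        f = {s: 1.0 for s in species}
        out = subset_exclude_dimorphic(self.make_table(species), m, f)
        expected = {s for s in species if not m[s] > 1.10 * f[s]}
        assert set(out["species"]) == expected

    def test_missing_mass_dropped_with_warning(self, caplog):
        table = self.make_table(["known", "unknown"])
        with caplog.at_level("WARNING"):
            out = subset_exclude_dimorphic(table, {"known": 1.0},
                                           {"known": 1.0})
        assert set(out["species"]) == {"known"}
        assert "unknown" in caplog.text


class TestTableSchema:
    def test_roundtrip_with_audit(self, tmp_path):
        rows = [obs(species="a", population_id="1", wins_female=8,
                    wins_male=2, contests_mm=3, contests_ff=1, contests_mf=10),
                obs(species="b", population_id="1", pct_female_won=0.5),
                obs(species="c", population_id="1",
                    qualitative_dominance="female_always")]
        df = table_from_observations(rows)
        path = tmp_path / "table.csv"
        df.to_csv(path, index=False)
        back = read_dominance_table(path)
        parsed, audit = observations_from_table(back)
        assert len(parsed) == 3 and audit == []
        assert parsed[0].wins_female == 8
        assert parsed[1].pct_female_won == 0.5
        assert classify_dominance(parsed[2]) is DominanceCategory.STRICT_FEMALE

    def test_unusable_rows_audited(self):
        table = pd.DataFrame({"species": ["a", "b"],
                              "population_id": ["1", "1"],
                              "wins_female": [5, np.nan],
                              "wins_male": [5, np.nan]})
        parsed, audit = observations_from_table(table)
        assert len(parsed) == 1
        assert audit[0]["species"] == "b"

    def test_tab_delimiter_autodetected(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("species\tpopulation_id\twins_female\twins_male\n"
                        "a\tp1\t3\t7\n")
        df = read_dominance_table(path)
        assert df.loc[0, "wins_female"] == 3

    def test_inconsistent_pct_rejected(self):
        with pytest.raises(DataValidationError):
            obs(wins_female=9, wins_male=1, pct_female_won=0.5)
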