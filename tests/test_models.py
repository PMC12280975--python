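"""Phylogenetic regressions: covariance nesting, posterior summaries,
convergence diagnostics, and agreement with non-phylogenetic oracles."""

import numpy as np
import pandas as pd
import pytest

from phylodom import (
    PhyloGLMSpec,
    build_population_covariance,
    check_convergence,
    fit_binomial_phylo,
    fit_ordinal_phylo,
    normalize_vcv,
    phylo_vcv,
    summarize_posterior,
)
from phylodom.errors import (
    ConvergenceError,
    DataValidationError,
    SampleSizeError,
    StandardizationError,
    TaxonLookupError,
)
from phylodom.synthetic import SyntheticTruth, simulate_dominance_dataset

FAST = PhyloGLMSpec(draws_total=2000, warmup_per_chain=500, seed=0)


@pytest.fixture(scope="module")
def dataset():
    return simulate_dominance_dataset(
        SyntheticTruth(beta=0.8, eta=0.5, n_species=40, seed=10))


class TestPopulationCovariance:
    def test_one_population_per_species_is_identity(self, dataset):
        cov = dataset.covariance
        mapping = {f"pop_{s}": s for s in cov.labels}
        pc = build_population_covariance(cov, mapping)
        assert np.array_equal(pc.Z, np.eye(cov.n))

    def test_shared_species_shares_rows(self, dataset):
        cov = dataset.covariance
        sp = cov.labels[0]
        pc = build_population_covariance(cov, {"a": sp, "b": sp})
        assert np.array_equal(pc.Z[0], pc.Z[1])
        assert pc.expanded()[0, 1] == pytest.approx(cov.matrix[0, 0])

    def test_expanded_matches_brute_force(self, dataset, rng):
        cov = dataset.covariance
        pops = {f"p{i}": cov.labels[int(rng.integers(cov.n))]
                for i in range(25)}
        pc = build_population_covariance(cov, pops)
        pos = {lab: i for i, lab in enumerate(cov.labels)}
        expected = np.array([[cov.matrix[pos[pops[a]], pos[pops[b]]]
                              for b in pops] for a in pops])
        assert np.allclose(pc.expanded(), expected)

    def test_unknown_species_rejected(self, dataset):
        with pytest.raises(TaxonLookupError):
            build_population_covariance(dataset.covariance,
                                        {"p": "not_a_species"})


class TestSummaries:
    def test_symmetric_draws_not_reliable(self, rng):
        draws = {"beta": rng.normal(0, 1, size=(4, 500))}
        tab = summarize_posterior(draws)
        assert tab.loc["beta", "lower"] < 0 < tab.loc["beta", "upper"]

    def test_constant_draws(self):
        tab = summarize_posterior({"b": np.full((4, 300), 2.0)})
        row = tab.loc["b"]
        assert (row["mean"], row["lower"], row["upper"]) == (2.0, 2.0, 2.0)

    def test_matches_sorted_quantile_oracle(self, rng):
        x = rng.normal(size=(4, 400))
        tab = summarize_posterior({"p": x})
        flat = np.sort(x.reshape(-1))

        def quantile(q):  # linear interpolation on the sorted sample
            h = (len(flat) - 1) * q
            lo = int(np.floor(h))
            return flat[lo] + (h - lo) * (flat[min(lo + 1, len(flat) - 1)]
                                          - flat[lo])
        assert tab.loc["p", "lower"] == pytest.approx(quantile(0.055))
        assert tab.loc["p", "upper"] == pytest.approx(quantile(0.945))

    def test_too_few_draws_rejected(self):
        with pytest.raises(SampleSizeError):
            summarize_posterior({"b": np.zeros((2, 10))})

    def test_nan_draws_rejected(self):
        bad = np.zeros((2, 600))
        bad[0, 0] = np.nan
        with pytest.raises(DataValidationError):
            summarize_posterior({"b": bad})


def split_rhat_oracle(chains: np.ndarray) -> float:
    """Textbook split-R-hat: split each chain in half, compare between- and
    within-half variances."""
    m, n = chains.shape
    half = n // 2
    splits = np.vstack([chains[:, :half], chains[:, half:2 * half]])
    k, h = splits.shape
    means = splits.mean(axis=1)
    B = h * means.var(ddof=1)
    W = splits.var(axis=1, ddof=1).mean()
    var_plus = (h - 1) / h * W + B / h
    return float(np.sqrt(var_plus / W))


class TestConvergence:
    def test_identical_chains_near_one(self, rng):
        x = rng.normal(size=500)
        rh = check_convergence({"p": np.vstack([x, x, x, x])})
        assert rh["p"] == pytest.approx(1.0, abs=5e-3)

    def test_disjoint_chains_fail_gate(self, rng):
        chains = np.vstack([rng.normal(0, 0.1, 400),
                            rng.normal(5, 0.1, 400)])
        assert check_convergence({"p": chains})["p"] > 1.5

    def test_matches_textbook_formula(self, rng):
        for _ in range(5):
            chains = rng.normal(rng.normal(size=(4, 1)) * 0.3, 1.0,
                                size=(4, 400))
            rh = check_convergence({"p": chains})["p"]
            assert rh == pytest.approx(split_rhat_oracle(chains), abs=1e-6)

    def test_single_chain_rejected(self):
        with pytest.raises(DataValidationError):
            check_convergence({"p": np.zeros((1, 100))})


class TestBinomialFit:
    def test_recovers_generating_slope(self, dataset):
        fit = fit_binomial_phylo(dataset.table, "x", dataset.covariance,
                                 FAST, strict=False)
        lo, hi = fit.beta_interval
        assert lo < 0.8 < hi or abs(fit.beta_mean - 0.8) < 0.25

    def test_nonphylo_limit_matches_glm_oracle(self):
        """With the phylogenetic effect disabled the posterior slope agrees
        with a maximum-likelihood binomial GLM."""
        import statsmodels.api as sm

        ds = simulate_dominance_dataset(SyntheticTruth(
            beta=0.6, eta=0.0, n_species=70,
            populations_per_species=(2, 4), seed=3))
        spec = PhyloGLMSpec(draws_total=4000, warmup_per_chain=500,
                            seed=4, eta_fixed=0.0)
        fit = fit_binomial_phylo(ds.table, "x", ds.covariance, spec,
                                 strict=False)
        W = ds.table["wins_female"].to_numpy(float)
        N = W + ds.table["wins_male"].to_numpy(float)
        X = sm.add_constant(ds.table["x"].to_numpy(float))
        glm = sm.GLM(np.column_stack([W, N - W]), X,
                     family=sm.families.Binomial()).fit()
        assert abs(fit.beta_mean - glm.params[1]) < 0.05

    def test_sufficiency_under_record_splitting(self, dataset):
        """Halving every record (splitting W and N) leaves the slope
        posterior statistically indistinguishable."""
        t = dataset.table.copy()
        a = t.assign(wins_female=t.wins_female // 2,
                     wins_male=t.wins_male // 2)
        b = t.assign(wins_female=t.wins_female - t.wins_female // 2,
                     wins_male=t.wins_male - t.wins_male // 2,
                     population_id=t.population_id + "_b")
        split = pd.concat([a, b], ignore_index=True)
        split = split[(split.wins_female + split.wins_male) > 0]
        f1 = fit_binomial_phylo(dataset.table, "x", dataset.covariance,
                                FAST, strict=False)
        f2 = fit_binomial_phylo(split, "x", dataset.covariance,
                                PhyloGLMSpec(draws_total=2000,
                                             warmup_per_chain=500, seed=99),
                                strict=False)
        lo1, hi1 = f1.beta_interval
        lo2, hi2 = f2.beta_interval
        assert max(lo1, lo2) < min(hi1, hi2)  # intervals overlap

    def test_fit_artifacts_roundtrip(self, dataset, tmp_path):
        import json
        fit = fit_binomial_phylo(dataset.table, "x", dataset.covariance,
                                 FAST, strict=False)
        fit.save(tmp_path, extra={"priors": {"slope": 1.0}})
        draws = pd.read_csv(tmp_path / "draws.csv")
        assert {"chain", "draw", "alpha", "beta[x]", "eta"} <= \
            set(draws.columns)
        assert len(draws) == FAST.draws_total
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == FAST.seed
        assert manifest["priors"] == {"slope": 1.0}
        assert draws["beta[x]"].mean() == pytest.approx(fit.beta_mean,
                                                        abs=1e-9)

    def test_missing_counts_rejected(self, dataset):
        t = dataset.table.copy()
        t.loc[0, "wins_female"] = np.nan
        with pytest.raises(DataValidationError):
            fit_binomial_phylo(t, "x", dataset.covariance, FAST)

    def test_zero_variance_predictor_rejected(self, dataset):
        t = dataset.table.assign(flat=1.0)
        with pytest.raises(StandardizationError):
            fit_binomial_phylo(t, "flat", dataset.covariance, FAST)

    def test_too_few_species_rejected(self, dataset):
        t = dataset.table[dataset.table.species.isin(
            dataset.table.species.unique()[:5])]
        with pytest.raises(SampleSizeError):
            fit_binomial_phylo(t, "x", dataset.covariance, FAST)

    def test_strict_gate_raises_with_diagnostics(self, dataset):
        bad = PhyloGLMSpec(draws_total=40, warmup_per_chain=5, seed=1,
                           chains=4)
        with pytest.raises(ConvergenceError) as err:
            fit_binomial_phylo(dataset.table, "x", dataset.covariance, bad)
        assert err.value.diagnostics  # carries the R-hat table

    def test_categorical_predictor_reports_contrasts(self):
        ds = simulate_dominance_dataset(SyntheticTruth(
            beta=1.0, eta=0.3, n_species=30, predictor_type="categorical",
            seed=21))
        t = ds.table.assign(level=ds.table["x"].map(
            {0.0: "low", 1.0: "mid", 2.0: "high"}))
        fit = fit_binomial_phylo(t, "level", ds.covariance, FAST,
                                 strict=False)
        assert any(p.startswith("contrast[") for p in fit.slope_params)
        assert len(fit.slope_params) == 3  # pairwise among 3 levels


class TestOrdinalFit:
    def test_recovers_sign(self, dataset):
        fit = fit_ordinal_phylo(dataset.table, "x", dataset.covariance,
                                FAST, strict=False)
        assert fit.beta_mean > 0
        assert fit.table.loc["kappa_1", "mean"] < \
            fit.table.loc["kappa_2", "mean"]

    def test_two_categories_collapse_to_logit(self):
        """A 2-level cumulative-link model is a Bernoulli logit; its slope
        must agree with the binomial model on the same 0/1 data."""
        ds = simulate_dominance_dataset(SyntheticTruth(
            beta=1.0, eta=0.0, n_species=50,
            populations_per_species=(2, 3), seed=8))
        t = ds.table.copy()
        t["category"] = (t.wins_female > t.wins_male).astype(int)
        t["wins_female"] = t["category"]
        t["wins_male"] = 1 - t["category"]
        spec = PhyloGLMSpec(draws_total=4000, warmup_per_chain=500,
                            seed=12, eta_fixed=0.0)
        fo = fit_ordinal_phylo(t, "x", ds.covariance, spec, strict=False,
                               n_categories=2)
        fb = fit_binomial_phylo(t, "x", ds.covariance, spec, strict=False)
        assert abs(fo.beta_mean - fb.beta_mean) < 0.12
        assert fo.table.loc["kappa_1", "mean"] == pytest.approx(
            -fb.table.loc["alpha", "mean"], abs=0.12)

    def test_single_level_outcome_rejected(self, dataset):
        t = dataset.table.assign(category=1)
        with pytest.raises(DataValidationError):
            fit_ordinal_phylo(t, "x", dataset.covariance, FAST)

    def test_draws_not_divisible_rejected(self):
        with pytest.raises(DataValidationError):
            PhyloGLMSpec(chains=4, draws_total=1001)
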