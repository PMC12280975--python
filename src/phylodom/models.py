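"""Bayesian phylogenetic regressions for intersexual dominance.

Two likelihoods, one covariance structure:

* **Binomial logit** — per population *i* of species *s(i)*, the number of
  intersexual contests won by females is
  ``W_i ~ Binomial(N_i, p_i)`` with
  ``logit(p_i) = alpha + beta * x_{s(i)} + phi_{s(i)}``.
* **Cumulative-link ordinal** — the three-level dominance category obeys
  ``Pr(y_i <= k) = logistic(kappa_k - mu_i)`` with ordered cutpoints
  ``kappa_1 < kappa_2`` and ``mu_i = beta * x_{s(i)} + phi_{s(i)}`` (the
  latent location is anchored at zero; the cutpoints absorb the intercept).

In both, ``phi ~ MVNormal(0, eta^2 C)`` is a species-level effect whose
correlation matrix ``C`` is the (normalized) Brownian-motion covariance of
the phylogeny: populations of one species share a single ``phi_s``, which
nests repeated populations inside the phylogenetic structure with
within-species latent correlation 1.  ``phi`` is sampled non-centered
(``phi = eta L z`` with ``L`` the Cholesky factor of ``C`` and ``z``
standard normal), which is essential when ``C`` is near-singular.

Weakly regularizing priors: ``beta ~ Normal(0, 1)``, intercept and
cutpoints ``~ Normal(0, 1.5)``, ``eta ~ Exponential(1)``.  Categorical
predictors are index-coded (one effect per level under a shared prior) and
reported as pairwise contrasts.  Posterior summaries report the mean and
the central 89 % compatibility interval; an association is flagged
*reliable* when that interval excludes zero.  Fits are gated on the
split-R-hat convergence diagnostic (< 1.01 for every reported parameter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import cholesky, LinAlgError

from .data import standardize_predictor
from .errors import (
    ConvergenceError,
    DataValidationError,
    LinearAlgebraError,
    SampleSizeError,
    StandardizationError,
    TaxonLookupError,
)
from .hmc import sample_hmc
from .trees import PhyloCovariance

__all__ = [
    "PhyloGLMSpec",
    "PosteriorSummary",
    "PopulationCovariance",
    "build_population_covariance",
    "fit_binomial_phylo",
    "fit_ordinal_phylo",
    "summarize_posterior",
    "check_convergence",
]

RHAT_GATE = 1.01
DEFAULT_CI_LEVEL = 0.89
MIN_SPECIES = 10


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PhyloGLMSpec:
    """Sampler and prior configuration for one phylogenetic regression.

    ``draws_total`` is the total number of post-warmup posterior samples
    across all chains (the default, 8,000 from four chains, matches the
    convention of 2,000 draws per chain after an equal warmup).
    ``eta_fixed`` pins the phylogenetic scale (0 disables the phylogenetic
    effect entirely, giving an ordinary GLM); ``None`` estimates it.
    """

    chains: int = 4
    draws_total: int = 8000
    warmup_per_chain: int | None = None
    seed: int = 0
    prior_scale_slope: float = 1.0
    prior_scale_intercept: float = 1.5
    eta_rate: float = 1.0
    eta_fixed: float | None = None
    target_accept: float = 0.85
    max_leapfrog: int = 32
    min_species: int = MIN_SPECIES
    constrain_species_effect_mean: bool = True

    def __post_init__(self):
        if self.draws_total % self.chains:
            raise DataValidationError(
                f"draws_total={self.draws_total} not divisible by "
                f"chains={self.chains}")
        if self.chains < 2:
            raise DataValidationError("need >= 2 chains for R-hat")

    @property
    def draws_per_chain(self) -> int:
        return self.draws_total // self.chains

    @property
    def warmup(self) -> int:
        return self.warmup_per_chain if self.warmup_per_chain is not None \
            else self.draws_per_chain


@dataclass
class PosteriorSummary:
    """Per-parameter posterior summaries plus fit-level diagnostics.

    ``table`` is indexed by parameter name with columns
    mean/lower/upper/rhat/ess.  ``reliable`` refers to the slope (or, for a
    categorical predictor, any pairwise contrast) and is true when the
    credible interval excludes zero.
    """

    table: pd.DataFrame
    level: float
    slope_params: list[str]
    reliable: bool
    converged: bool
    max_rhat: float
    n_divergent: int
    seed: int
    draws: dict = field(default_factory=dict, repr=False)

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.loc[param]

    def save(self, outdir, extra: dict | None = None) -> None:
        """Write fit artifacts: posterior draws as columnar text plus a JSON
        manifest (summary table, diagnostics, seed)."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.draws:
            chains, n = next(iter(self.draws.values())).shape
            frame = pd.DataFrame({k: np.asarray(v).reshape(-1)
                                  for k, v in self.draws.items()})
            frame.insert(0, "chain", np.repeat(np.arange(chains), n))
            frame.insert(1, "draw", np.tile(np.arange(n), chains))
            frame.to_csv(out / "draws.csv", index=False)
        manifest = {
            "summary": self.table.to_dict(orient="index"),
            "level": self.level,
            "slope_params": self.slope_params,
            "reliable": self.reliable,
            "converged": self.converged,
            "max_rhat": self.max_rhat,
            "n_divergent": self.n_divergent,
            "seed": self.seed,
        }
        if extra:
            manifest.update(extra)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float) + "\n")

    @property
    def beta_mean(self) -> float:
        return float(self.table.loc[self.slope_params[0], "mean"])

    @property
    def beta_interval(self) -> tuple[float, float]:
        row = self.table.loc[self.slope_params[0]]
        return float(row["lower"]), float(row["upper"])


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PopulationCovariance:
    """Species covariance expanded to populations via a nesting design.

    ``Z`` is the (populations x species) indicator matrix; populations of
    one species share a row pattern and hence one latent effect.  The
    implied population-level covariance is ``Z C Z'``.
    """

    species_labels: tuple[str, ...]
    populations: tuple[str, ...]
    Z: np.ndarray
    C: np.ndarray

    @property
    def species_index(self) -> np.ndarray:
        return self.Z.argmax(axis=1)

    def expanded(self) -> np.ndarray:
        return self.Z @ self.C @ self.Z.T


def build_population_covariance(cov: PhyloCovariance,
                                species_of_population: dict[str, str]
                                ) -> PopulationCovariance:
    """Nest populations within the species-level phylogenetic covariance."""
    pos = {lab: i for i, lab in enumerate(cov.labels)}
    missing = sorted({s for s in species_of_population.values()
                      if s not in pos})
    if missing:
        raise TaxonLookupError(missing)
    pops = tuple(species_of_population)
    Z = np.zeros((len(pops), cov.n))
    for r, pop in enumerate(pops):
        Z[r, pos[species_of_population[pop]]] = 1.0
    return PopulationCovariance(cov.labels, pops, Z, cov.matrix)


# ----------------------------------------------------------------------
def _chol_psd(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor with escalating diagonal jitter for PSD C."""
    n = len(C)
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return cholesky(C + jitter * np.eye(n), lower=True)
        except LinAlgError:
            continue
    raise LinearAlgebraError("covariance not PSD even with 1e-6 jitter")


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class _PhyloGLMBase:
    """Shared structure: species design, phylogenetic effect, priors.

    Unconstrained parameter layout:
    ``[intercept-block | beta (p) | log eta (if estimated) | z (S, if phylo)]``.
    """

    def __init__(self, X_species: np.ndarray, species_idx: np.ndarray,
                 C: np.ndarray, spec: PhyloGLMSpec, n_intercept: int):
        self.Xs = X_species                      # (S, p)
        self.sp = species_idx                    # (P,) population -> species
        self.spec = spec
        self.S, self.p = X_species.shape
        self.P = len(species_idx)
        self.n_int = n_intercept
        self.estimate_eta = spec.eta_fixed is None
        self.has_phylo = self.estimate_eta or spec.eta_fixed > 0
        if self.has_phylo:
            C = np.asarray(C, dtype=float)
            if spec.constrain_species_effect_mean:
                # remove the GLS-mean (root-state) direction from the
                # kernel: the intercept already carries it, and the
                # redundancy otherwise creates a slow-mixing ridge
                c1 = C @ np.ones(len(C))
                C = C - np.outer(c1, c1) / c1.sum()
            self.L = _chol_psd(C)
        else:
            self.L = None
        # population -> species aggregation matrix (dense; S is small)
        M = np.zeros((self.P, self.S))
        M[np.arange(self.P), species_idx] = 1.0
        self.M = M
        self.dim = (n_intercept + self.p
                    + (1 if self.estimate_eta else 0)
                    + (self.S if self.has_phylo else 0))

    def _split(self, theta):
        i = self.n_int
        interc = theta[:, :i]
        beta = theta[:, i:i + self.p]
        j = i + self.p
        if self.estimate_eta:
            u = theta[:, j]
            eta = np.exp(np.minimum(u, 30.0))  # clip warmup excursions
            j += 1
        else:
            u = None
            eta = np.full(theta.shape[0], float(self.spec.eta_fixed))
        z = theta[:, j:] if self.has_phylo else None
        return interc, beta, u, eta, z

    def _species_term(self, beta, eta, z):
        t = beta @ self.Xs.T                         # (c, S)
        if self.has_phylo:
            Lz = z @ self.L.T
            t = t + eta[:, None] * Lz
            return t, Lz
        return t, None

    def _common_grads(self, gspec, beta, eta, u, z, Lz, logp):
        """Gradient blocks shared by both likelihoods.

        ``gspec`` is d loglik / d(species latent term), shape (c, S).
        Returns (d_beta, d_u, d_z) with priors included, and adds the
        prior log density for beta/eta/z to ``logp`` in place.
        """
        sb = self.spec.prior_scale_slope
        d_beta = gspec @ self.Xs - beta / sb ** 2
        logp -= 0.5 * np.sum(beta ** 2, axis=1) / sb ** 2
        d_u = d_z = None
        if self.has_phylo:
            gphi = gspec                               # phi enters t linearly
            d_z = eta[:, None] * (gphi @ self.L) - z
            logp -= 0.5 * np.sum(z ** 2, axis=1)
            if self.estimate_eta:
                rate = self.spec.eta_rate
                d_u = eta * np.einsum("cs,cs->c", gphi, Lz) - rate * eta + 1.0
                logp += -rate * eta + u               # Exp(rate) prior + Jacobian
        return d_beta, d_u, d_z, logp


class BinomialPhyloModel(_PhyloGLMBase):
    """Binomial logit with a phylogenetic species effect."""

    def __init__(self, wins, totals, X_species, species_idx, C, spec):
        super().__init__(X_species, species_idx, C, spec, n_intercept=1)
        self.W = np.asarray(wins, dtype=float)
        self.N = np.asarray(totals, dtype=float)

    def logp_grad(self, theta):
        interc, beta, u, eta, z = self._split(theta)
        alpha = interc[:, 0]
        t, Lz = self._species_term(beta, eta, z)
        m = alpha[:, None] + t[:, self.sp]           # (c, P)
        logp = np.sum(self.W * m - self.N * _softplus(m), axis=1)
        G = self.W - self.N * _sigmoid(m)            # d loglik / d m
        gspec = G @ self.M                           # (c, S)
        sa = self.spec.prior_scale_intercept
        d_alpha = G.sum(axis=1) - alpha / sa ** 2
        logp -= 0.5 * alpha ** 2 / sa ** 2
        d_beta, d_u, d_z, logp = self._common_grads(
            gspec, beta, eta, u, z, Lz, logp)
        return logp, self._pack(d_alpha[:, None], d_beta, d_u, d_z)

    def _pack(self, d_int, d_beta, d_u, d_z):
        parts = [d_int, d_beta]
        if self.estimate_eta:
            parts.append(d_u[:, None])
        if self.has_phylo:
            parts.append(d_z)
        return np.concatenate(parts, axis=1)

    def constrain(self, draws, beta_names):
        """Map (chains, draws, dim) unconstrained draws to named arrays."""
        out = {"alpha": draws[..., 0]}
        for k, name in enumerate(beta_names):
            out[name] = draws[..., 1 + k]
        if self.estimate_eta:
            out["eta"] = np.exp(draws[..., 1 + self.p])
        return out


class OrdinalPhyloModel(_PhyloGLMBase):
    """Cumulative-logit (proportional-odds) model with a phylogenetic effect.

    ``K`` ordered categories need ``K - 1`` ordered cutpoints, parameterized
    as ``kappa_1 = c`` and ``kappa_{j+1} = kappa_j + exp(d_j)``.  The latent
    location carries no intercept (the cutpoints absorb it), resolving the
    usual location non-identifiability.  With two categories the model is
    exactly a logistic regression with intercept ``-kappa_1``.
    """

    def __init__(self, y, X_species, species_idx, C, spec,
                 n_categories: int = 3):
        if n_categories < 2:
            raise DataValidationError("need >= 2 outcome categories")
        super().__init__(X_species, species_idx, C, spec,
                         n_intercept=n_categories - 1)
        y = np.asarray(y, dtype=int)
        if y.min() < 0 or y.max() >= n_categories:
            raise DataValidationError(
                f"ordinal outcome must be coded 0..{n_categories - 1}")
        self.K = n_categories
        self.y = y
        self.lowest = (y == 0)
        self.highest = (y == self.K - 1)

    def _cutpoints(self, interc):
        """(c, K-1) ordered cutpoints from c1 and log-gaps, plus Jacobian."""
        gaps = np.exp(np.minimum(interc[:, 1:], 30.0))
        kappa = np.concatenate(
            [interc[:, :1], interc[:, :1] + np.cumsum(gaps, axis=1)], axis=1)
        return kappa, gaps

    def logp_grad(self, theta):
        interc, beta, u, eta, z = self._split(theta)
        kappa, gaps = self._cutpoints(interc)            # (c, K-1)
        t, Lz = self._species_term(beta, eta, z)
        mu = t[:, self.sp]                               # (c, P)

        # F[j] = logistic(kappa_j - mu); boundaries F_0 = 0, F_K = 1
        k_lo = kappa[:, self.y - 1]                      # kappa_{y}   (lower)
        k_hi = kappa[:, np.minimum(self.y, self.K - 2)]  # kappa_{y+1} (upper)
        a_lo = k_lo - mu
        a_hi = k_hi - mu
        F_lo = np.where(self.lowest, 0.0, _sigmoid(a_lo))
        F_hi = np.where(self.highest, 1.0, _sigmoid(a_hi))
        f_lo = F_lo * (1.0 - F_lo)
        f_hi = F_hi * (1.0 - F_hi)
        D = np.clip(F_hi - F_lo, 1e-300, None)

        ll = np.where(self.lowest, -_softplus(-a_hi),
                      np.where(self.highest, -_softplus(a_lo), np.log(D)))
        logp = ll.sum(axis=1)

        dmu = -(f_hi - f_lo) / D
        # d loglik / d kappa_j, accumulated per cutpoint
        g_hi = f_hi / D                                  # coefficient on upper
        g_lo = -f_lo / D                                 # coefficient on lower
        dkappa = np.zeros_like(kappa)
        hi_idx = np.minimum(self.y, self.K - 2)
        lo_idx = np.maximum(self.y - 1, 0)
        c_idx = np.arange(theta.shape[0])[:, None]
        np.add.at(dkappa, (c_idx, np.broadcast_to(hi_idx, mu.shape)),
                  np.where(self.highest, 0.0, g_hi))
        np.add.at(dkappa, (c_idx, np.broadcast_to(lo_idx, mu.shape)),
                  np.where(self.lowest, 0.0, g_lo))

        sa = self.spec.prior_scale_intercept
        logp -= 0.5 * np.sum(kappa ** 2, axis=1) / sa ** 2
        dkappa -= kappa / sa ** 2
        logp += interc[:, 1:].sum(axis=1)                # Jacobians of exp gaps

        # chain rule to (c1, d_1 .. d_{K-2}): kappa_j depends on all gaps < j
        d_c1 = dkappa.sum(axis=1)
        rev_cum = np.cumsum(dkappa[:, ::-1], axis=1)[:, ::-1]
        d_gaps = rev_cum[:, 1:] * gaps + 1.0
        d_int = np.concatenate([d_c1[:, None], d_gaps], axis=1)

        gspec = dmu @ self.M                             # d loglik / d t_s
        d_beta, d_u, d_z, logp = self._common_grads(
            gspec, beta, eta, u, z, Lz, logp)
        parts = [d_int, d_beta]
        if self.estimate_eta:
            parts.append(d_u[:, None])
        if self.has_phylo:
            parts.append(d_z)
        return logp, np.concatenate(parts, axis=1)

    def constrain(self, draws, beta_names):
        nc = self.n_int
        out = {"kappa_1": draws[..., 0]}
        acc = draws[..., 0]
        for j in range(1, nc):
            acc = acc + np.exp(draws[..., j])
            out[f"kappa_{j + 1}"] = acc
        for k, name in enumerate(beta_names):
            out[name] = draws[..., nc + k]
        if self.estimate_eta:
            out["eta"] = np.exp(draws[..., nc + self.p])
        return out


# ----------------------------------------------------------------------
def summarize_posterior(draws: dict[str, np.ndarray],
                        level: float = DEFAULT_CI_LEVEL,
                        min_draws: int = 1000) -> pd.DataFrame:
    """Posterior mean and central credible interval per parameter.

    ``draws`` maps parameter name to a (chains, draws) array.  The 89 %
    level reports the central (5.5 %, 94.5 %) quantile interval.
    """
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = {}
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.size < min_draws:
            raise SampleSizeError(
                f"{name}: {arr.size} draws < required {min_draws}")
        if not np.all(np.isfinite(arr)):
            raise DataValidationError(f"{name}: non-finite posterior draws")
        flat = arr.reshape(-1)
        rows[name] = {"mean": flat.mean(),
                      "lower": np.quantile(flat, lo_q),
                      "upper": np.quantile(flat, hi_q)}
    return pd.DataFrame.from_dict(rows, orient="index")


def check_convergence(draws: dict[str, np.ndarray]) -> dict[str, float]:
    """Split-R-hat per parameter (Gelman–Rubin, split-chain form).

    Requires >= 2 chains; the conventional pass threshold is < 1.01.
    """
    for name, arr in draws.items():
        if np.asarray(arr).ndim != 2 or np.asarray(arr).shape[0] < 2:
            raise DataValidationError(
                f"{name}: need (chains >= 2, draws) shaped array")
    ds = az.convert_to_dataset({k: np.asarray(v) for k, v in draws.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rh = az.rhat(ds, method="split")
    return {k: float(rh[k].values) for k in draws}


def _effective_sample_size(draws: dict[str, np.ndarray]) -> dict[str, float]:
    ds = az.convert_to_dataset({k: np.asarray(v) for k, v in draws.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(ds)
    return {k: float(ess[k].values) for k in draws}


# ----------------------------------------------------------------------
def _prepare_predictor(data: pd.DataFrame, predictor: str,
                       species_order: list[str],
                       standardize: bool = False):
    """Species-level design matrix for a continuous or categorical predictor.

    The predictor must be constant within species.  Continuous predictors
    yield a single column (optionally standardized across species);
    categorical predictors are index-coded (one column per level).
    """
    per_species = {}
    for sp_name, grp in data.groupby("species"):
        vals = grp[predictor].dropna().unique()
        if len(vals) != 1:
            raise DataValidationError(
                f"predictor {predictor!r} not constant within {sp_name}")
        per_species[sp_name] = vals[0]
    values = [per_species[s] for s in species_order]
    if all(isinstance(v, (int, float, np.floating, np.integer))
           for v in values):
        x = np.asarray(values, dtype=float)
        if np.std(x, ddof=1) == 0:
            raise StandardizationError(
                f"predictor {predictor!r} has zero variance across species")
        if standardize:
            x = standardize_predictor(x)
        return x[:, None], [f"beta[{predictor}]"], "continuous"
    levels = sorted(set(str(v) for v in values))
    if len(levels) < 2:
        raise StandardizationError(
            f"categorical predictor {predictor!r} has a single level")
    X = np.zeros((len(values), len(levels)))
    for i, v in enumerate(values):
        X[i, levels.index(str(v))] = 1.0
    names = [f"beta[{predictor}={lv}]" for lv in levels]
    return X, names, "categorical"


def _contrast_draws(draws: dict, beta_names: list[str]) -> dict:
    """Pairwise level contrasts for an index-coded categorical predictor."""
    out = {}
    for i in range(len(beta_names)):
        for j in range(i + 1, len(beta_names)):
            a, b = beta_names[i], beta_names[j]
            la = a[a.index("=") + 1:-1]
            lb = b[b.index("=") + 1:-1]
            out[f"contrast[{la}-{lb}]"] = draws[a] - draws[b]
    return out


def _run_fit(model, beta_names: list[str], kind: str, spec: PhyloGLMSpec,
             strict: bool) -> PosteriorSummary:
    res = sample_hmc(model.logp_grad, model.dim, chains=spec.chains,
                     warmup=spec.warmup, draws=spec.draws_per_chain,
                     seed=spec.seed, target_accept=spec.target_accept,
                     max_leapfrog=spec.max_leapfrog)
    named = model.constrain(res.draws, beta_names)
    contrasts = _contrast_draws(named, beta_names) if kind == "categorical" \
        else {}
    named.update(contrasts)
    rhats = check_convergence(named)
    ess = _effective_sample_size(named)
    table = summarize_posterior(named, min_draws=min(1000, spec.draws_total))
    table["rhat"] = pd.Series(rhats)
    table["ess"] = pd.Series(ess)
    max_rhat = max(rhats.values())
    n_div = int(res.divergences.sum())
    converged = max_rhat < RHAT_GATE
    slope_params = list(contrasts) if contrasts else beta_names
    reliable = bool(any(
        not (table.loc[pnm, "lower"] <= 0.0 <= table.loc[pnm, "upper"])
        for pnm in slope_params))
    summary = PosteriorSummary(
        table=table, level=DEFAULT_CI_LEVEL, slope_params=slope_params,
        reliable=reliable, converged=converged, max_rhat=max_rhat,
        n_divergent=n_div, seed=spec.seed, draws=named)
    if strict and not converged:
        raise ConvergenceError(
            f"split-R-hat gate failed: max R-hat = {max_rhat:.4f} >= "
            f"{RHAT_GATE}", diagnostics=rhats)
    return summary


def _species_setup(data: pd.DataFrame, cov: PhyloCovariance,
                   min_species: int):
    species_order = list(dict.fromkeys(data["species"]))
    if len(species_order) < min_species:
        raise SampleSizeError(
            f"{len(species_order)} species < required {min_species}")
    C = cov.subset(species_order).matrix
    sp_index = {s: i for i, s in enumerate(species_order)}
    idx = data["species"].map(sp_index).to_numpy()
    return species_order, C, idx


def fit_binomial_phylo(data: pd.DataFrame, predictor: str,
                       cov: PhyloCovariance, spec: PhyloGLMSpec,
                       strict: bool = True,
                       standardize: bool = False) -> PosteriorSummary:
    """Fit the phylogenetic binomial-logit regression.

    ``data`` needs columns species, wins_female, wins_male and the predictor
    (constant within species); every record must carry counts with at least
    one contest.  ``cov`` is the species-level phylogenetic covariance
    (normalized; any species in ``data`` must appear in its labels).
    """
    req = {"species", "wins_female", "wins_male", predictor}
    missing = req - set(data.columns)
    if missing:
        raise DataValidationError(f"missing columns: {sorted(missing)}")
    W = data["wins_female"].to_numpy(dtype=float)
    N = W + data["wins_male"].to_numpy(dtype=float)
    if np.any(~np.isfinite(N)) or np.any(N <= 0):
        raise DataValidationError(
            "binomial fit requires raw counts with N > 0 for every record")
    species_order, C, idx = _species_setup(data, cov, spec.min_species)
    X, beta_names, kind = _prepare_predictor(data, predictor, species_order,
                                             standardize=standardize)
    model = BinomialPhyloModel(W, N, X, idx, C, spec)
    return _run_fit(model, beta_names, kind, spec, strict)


def fit_ordinal_phylo(data: pd.DataFrame, predictor: str,
                      cov: PhyloCovariance, spec: PhyloGLMSpec,
                      strict: bool = True, standardize: bool = False,
                      n_categories: int = 3) -> PosteriorSummary:
    """Fit the phylogenetic cumulative-link ordinal regression.

    ``data`` needs columns species and category (integer 0/1/2 coding of
    strict_male < no_strict_bias < strict_female) plus the predictor.
    A positive slope shifts probability mass toward strict female dominance.
    """
    req = {"species", "category", predictor}
    missing = req - set(data.columns)
    if missing:
        raise DataValidationError(f"missing columns: {sorted(missing)}")
    y = data["category"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise DataValidationError(
            "ordinal outcome has a single observed level")
    species_order, C, idx = _species_setup(data, cov, spec.min_species)
    X, beta_names, kind = _prepare_predictor(data, predictor, species_order,
                                             standardize=standardize)
    model = OrdinalPhyloModel(y, X, idx, C, spec, n_categories=n_categories)
    return _run_fit(model, beta_names, kind, spec, strict)
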