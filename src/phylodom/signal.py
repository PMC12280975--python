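"""Blomberg's K phylogenetic signal with permutation significance.

K compares the observed partitioning of trait variance on a phylogeny with
the expectation under Brownian motion (BM).  Writing ``V`` for the BM
covariance of the tree and ``a_hat`` for the GLS root-state estimate,

    MSE0 = (Y - a_hat 1)' (Y - a_hat 1) / (n - 1)
    MSE  = (Y - a_hat 1)' V^{-1} (Y - a_hat 1) / (n - 1)
    E[MSE0/MSE] = (tr V - n / (1' V^{-1} 1)) / (n - 1)
    K = (MSE0 / MSE) / E[MSE0/MSE]

K is approximately 1 for a trait evolving by BM on the true tree, near 0
when trait values are unrelated to phylogeny, and exactly 1 on an
equal-depth star tree.  Significance is assessed by permuting trait values
across tips, holding the tree fixed, and comparing the observed K with the
permutation distribution (one-sided: high K indicates signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .data import DominanceCategory
from .errors import (
    DegenerateTraitError,
    LinearAlgebraError,
    SampleSizeError,
)
from .trees import PhyloCovariance

__all__ = [
    "KResult",
    "phylogenetic_mean",
    "blomberg_k",
    "k_significance",
    "encode_categorical_for_k",
]

_JITTER = 1e-10


@dataclass(frozen=True)
class KResult:
    """Blomberg's K with its components and optional permutation p-value."""

    K: float
    observed_ratio: float   # MSE0 / MSE
    expected_ratio: float   # BM expectation of MSE0 / MSE
    n_tips: int
    p_value: float | None = None
    n_sims: int = 0
    seed: int | None = None

    def __post_init__(self):
        if self.p_value is not None and not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value out of (0, 1]: {self.p_value}")


def _chol(V: np.ndarray):
    """Cholesky factor of V, retrying once with a small diagonal jitter."""
    try:
        return cho_factor(V, lower=True)
    except LinAlgError:
        try:
            return cho_factor(V + _JITTER * np.trace(V) / len(V) * np.eye(len(V)),
                              lower=True)
        except LinAlgError as exc:
            raise LinearAlgebraError(
                "phylogenetic covariance is singular even after diagonal "
                "jitter; check for duplicated tips or zero branch lengths"
            ) from exc


def phylogenetic_mean(Y, cov: PhyloCovariance) -> float:
    """GLS estimate of the root state: (1'V^-1 1)^-1 (1'V^-1 Y)."""
    Y = np.asarray(Y, dtype=float)
    n = cov.n
    if Y.shape != (n,):
        raise ValueError(f"trait length {Y.shape} does not match {n} tips")
    if n < 3:
        raise SampleSizeError(f"need >= 3 tips, got {n}")
    c = _chol(cov.matrix)
    ones = np.ones(n)
    Vi1 = cho_solve(c, ones)
    return float(Vi1 @ Y / (Vi1 @ ones))


def blomberg_k(Y, cov: PhyloCovariance) -> KResult:
    """Blomberg's K for a continuous trait on a phylogeny."""
    Y = np.asarray(Y, dtype=float)
    n = cov.n
    if n < 3:
        raise SampleSizeError(f"need >= 3 tips, got {n}")
    if Y.shape != (n,):
        raise ValueError(f"trait length {Y.shape} does not match {n} tips")
    if np.ptp(Y) == 0:
        raise DegenerateTraitError("trait is constant across tips")
    V = cov.matrix
    c = _chol(V)
    ones = np.ones(n)
    Vi1 = cho_solve(c, ones)
    s = float(Vi1 @ ones)                    # 1' V^-1 1
    a_hat = float(Vi1 @ Y / s)
    r = Y - a_hat
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve(c, r)) / (n - 1)
    expected = (float(np.trace(V)) - n / s) / (n - 1)
    observed = mse0 / mse
    return KResult(K=observed / expected, observed_ratio=observed,
                   expected_ratio=expected, n_tips=n)


def k_significance(Y, cov: PhyloCovariance, n_sims: int = 10_000,
                   seed: int | None = None) -> KResult:
    """Permutation test for K: shuffle trait values across tips.

    One-sided p-value with add-one smoothing,
    ``p = (1 + #{K_perm >= K_obs}) / (1 + n_sims)``; never smaller than
    ``1 / (n_sims + 1)`` and deterministic given ``seed``.
    """
    import warnings

    if n_sims < 100:
        warnings.warn(f"n_sims={n_sims} gives a coarse p-value floor of "
                      f"{1 / (n_sims + 1):.3g}", stacklevel=2)
    obs = blomberg_k(Y, cov)
    Y = np.asarray(Y, dtype=float)
    n = cov.n
    rng = np.random.default_rng(seed)
    # all permutations at once: columns of Yp are tip-shuffled copies of Y
    Yp = rng.permuted(np.tile(Y, (n_sims, 1)), axis=1).T      # (n, n_sims)

    V = cov.matrix
    c = _chol(V)
    ones = np.ones(n)
    Vi1 = cho_solve(c, ones)
    s = float(Vi1 @ ones)
    A = cho_solve(c, Yp)                                       # V^-1 Yp
    a_hat = (ones @ A) / s                                     # (n_sims,)
    R = Yp - a_hat                                             # residuals
    mse0 = np.einsum("ij,ij->j", R, R) / (n - 1)
    # V^-1 (Yp - a 1) = A - a * V^-1 1  (linearity of the solve)
    mse = np.einsum("ij,ij->j", R, A - np.outer(Vi1, a_hat)) / (n - 1)
    expected = (float(np.trace(V)) - n / s) / (n - 1)
    k_perm = (mse0 / mse) / expected
    p = (1 + int(np.sum(k_perm >= obs.K))) / (1 + n_sims)
    return KResult(K=obs.K, observed_ratio=obs.observed_ratio,
                   expected_ratio=obs.expected_ratio, n_tips=n,
                   p_value=p, n_sims=n_sims, seed=seed)


_DEFAULT_SCORES = {
    DominanceCategory.STRICT_MALE: 0.0,
    DominanceCategory.NO_STRICT_BIAS: 1.0,
    DominanceCategory.STRICT_FEMALE: 2.0,
}


def encode_categorical_for_k(categories, scores: dict | None = None) -> np.ndarray:
    """Map the ordered three-level dominance coding onto numeric scores.

    Default scores 0/1/2 (strict_male -> 0 ... strict_female -> 2).  K is
    invariant to any affine recoding, so the choice only needs to preserve
    the ordering and equal spacing.
    """
    scores = scores or _DEFAULT_SCORES
    out = np.empty(len(categories), dtype=float)
    for i, cat in enumerate(categories):
        if isinstance(cat, str):
            try:
                cat = DominanceCategory[cat.upper()]
            except KeyError:
                raise ValueError(f"unknown dominance level: {cat!r}") from None
        elif not isinstance(cat, DominanceCategory):
            cat = DominanceCategory(cat)
        out[i] = scores[cat]
    return out
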