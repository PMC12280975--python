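"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter vector.

A compact HMC engine for the smooth, moderate-dimensional posteriors of the
phylogenetic regressions: static leapfrog trajectories with jittered length,
dual-averaging step-size adaptation toward a target acceptance rate, and a
single diagonal mass-matrix update mid-warmup estimated from early draws.
All chains run simultaneously as one batched numpy computation; the target
density must accept a ``(chains, dim)`` array and return per-chain log
density and gradient.

This is deliberately not a general-purpose probabilistic-programming
sampler: no U-turn criterion, no dense mass matrix, no reversible trees.
For the log-concave-ish GLMM posteriors here (tens of dimensions,
non-centered latent effects) jittered static trajectories mix well and the
implementation stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["sample_hmc", "HMCResult"]

LogpGrad = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]

_DIVERGENCE_ENERGY = 1000.0  # energy error beyond which a trajectory is divergent


@dataclass
class HMCResult:
    """Posterior draws with per-chain sampler diagnostics.

    ``draws`` has shape (chains, draws, dim) on the unconstrained scale.
    """

    draws: np.ndarray
    accept_rate: np.ndarray
    divergences: np.ndarray
    step_size: np.ndarray
    inv_mass: np.ndarray


def _leapfrog(logp_grad: LogpGrad, q, p, grad, eps, inv_mass, n_steps):
    """Vectorized leapfrog integrator; eps is per-chain."""
    eps = eps[:, None]
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * (inv_mass * p)
        logp, grad = logp_grad(q)
        if step != n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return q, p, logp, grad


def sample_hmc(logp_grad: LogpGrad, dim: int, *, chains: int = 4,
               warmup: int = 500, draws: int = 500,
               seed: int | None = None, target_accept: float = 0.8,
               max_leapfrog: int = 24, init: np.ndarray | None = None,
               init_scale: float = 0.1) -> HMCResult:
    """Run ``chains`` HMC chains and return post-warmup draws.

    Parameters
    ----------
    logp_grad
        Maps a ``(chains, dim)`` position array to per-chain log density
        ``(chains,)`` and gradient ``(chains, dim)``.  Non-finite values are
        treated as rejections.
    warmup, draws
        Adaptation iterations (discarded) and retained draws per chain.
    target_accept
        Dual-averaging target for the mean acceptance probability.
    max_leapfrog
        Trajectory length is drawn uniformly from {1, ..., max_leapfrog}
        each iteration (shared across chains), which decorrelates draws
        without a U-turn criterion.
    init
        Optional ``(chains, dim)`` or ``(dim,)`` initial positions; default
        is ``init_scale`` times standard normal jitter.
    """
    rng = np.random.default_rng(seed)
    if init is None:
        q = init_scale * rng.standard_normal((chains, dim))
    else:
        q = np.broadcast_to(np.asarray(init, dtype=float),
                            (chains, dim)).copy()
        q += init_scale * rng.standard_normal((chains, dim))
    logp, grad = logp_grad(q)
    if not np.all(np.isfinite(logp)):
        raise ValueError("log density not finite at the initial position")

    inv_mass = np.ones(dim)
    # dual averaging state (per chain)
    eps = np.full(chains, 0.1)
    log_eps_bar = np.zeros(chains)
    h_bar = np.zeros(chains)
    mu = np.log(10 * eps)
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    mass_window_start = max(1, int(0.25 * warmup))
    mass_update_at = max(mass_window_start + 2, int(0.6 * warmup))
    window: list[np.ndarray] = []

    total = warmup + draws
    out = np.empty((chains, draws, dim))
    n_accept = np.zeros(chains)
    n_div = np.zeros(chains, dtype=int)

    for it in range(total):
        adapting = it < warmup
        p0 = rng.standard_normal((chains, dim)) / np.sqrt(inv_mass)
        h0 = -logp + 0.5 * np.einsum("cd,d,cd->c", p0, inv_mass, p0)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        q1, p1, logp1, grad1 = _leapfrog(logp_grad, q, p0, grad, eps,
                                         inv_mass, n_steps)
        h1 = -logp1 + 0.5 * np.einsum("cd,d,cd->c", p1, inv_mass, p1)
        delta = h0 - h1
        delta = np.where(np.isfinite(delta), delta, -np.inf)
        accept_prob = np.exp(np.minimum(delta, 0.0))
        divergent = delta < -_DIVERGENCE_ENERGY
        accept = rng.random(chains) < accept_prob
        accept &= ~divergent

        q = np.where(accept[:, None], q1, q)
        logp = np.where(accept, logp1, logp)
        grad = np.where(accept[:, None], grad1, grad)

        if adapting:
            adapt_count += 1
            m = adapt_count
            eta = 1.0 / (m + t0)
            h_bar = (1 - eta) * h_bar + eta * (target_accept - accept_prob)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            eps = np.exp(log_eps)
            w = m ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            if mass_window_start <= it < mass_update_at:
                window.append(q.copy())
            if it == mass_update_at and window:
                pooled = np.concatenate(window, axis=0)
                n_w = pooled.shape[0]
                var = pooled.var(axis=0)
                # regularize toward unit scale (few-sample shrinkage)
                inv_mass = (n_w / (n_w + 5.0)) * var + 1e-3 * (5.0 / (n_w + 5.0))
                inv_mass = np.maximum(inv_mass, 1e-8)
                # restart step-size adaptation around the current value
                mu = np.log(10 * eps)
                h_bar[:] = 0.0
                log_eps_bar = np.log(eps)
                adapt_count = 0
            if it == warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            out[:, it - warmup, :] = q
            n_accept += accept_prob
            n_div += divergent.astype(int)

    return HMCResult(draws=out, accept_rate=n_accept / draws,
                     divergences=n_div, step_size=eps, inv_mass=inv_mass)
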