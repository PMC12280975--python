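"""Fit the Bayesian phylogenetic binomial regression.

Generates a dataset in which a standardized species-level predictor x
raises the odds that females win intersexual contests (true slope
beta = 0.8 on the logit scale, phylogenetic effect scale eta = 0.5), then
refits the generating model: W_i ~ Binomial(N_i, p_i) with
logit(p_i) = alpha + beta * x_s + phi_s and phi ~ MVN(0, eta^2 C).
"""

from phylodom import (
    PhyloGLMSpec,
    SyntheticTruth,
    fit_binomial_phylo,
    simulate_dominance_dataset,
)

truth = SyntheticTruth(alpha=0.0, beta=0.8, eta=0.5, n_species=60, seed=7)
ds = simulate_dominance_dataset(truth)
print(f"dataset: {len(ds.table)} populations, {truth.n_species} species")

spec = PhyloGLMSpec(draws_total=8000, warmup_per_chain=1000, seed=11)
fit = fit_binomial_phylo(ds.table, "x", ds.covariance, spec)

print(fit.table.round(3))
lo, hi = fit.beta_interval
print(f"\ntrue slope: {truth.beta}  |  posterior mean "
      f"{fit.beta_mean:.2f}, 89% CI [{lo:.2f}, {hi:.2f}]")
print(f"reliable (interval excludes 0): {fit.reliable}; "
      f"max split-R-hat {fit.max_rhat:.3f} (< 1.01 means converged)")
print("\nThe 89% interval should cover 0.8; eta's posterior measures how")
print("much of the variation in female wins tracks the phylogeny.")
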