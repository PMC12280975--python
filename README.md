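# phylodom

Phylogenetic comparative analysis of **intersexual dominance** — sex biases
in the outcomes of aggressive interactions ("contests") between adult males
and females — across primate populations.  The package is written for
comparative behavioral ecologists who have (i) a time-calibrated phylogeny
in newick format and (ii) a table of population-level records with contest
counts, group composition and species-level predictors, and who want the
full analysis chain as tested, scriptable Python:

1. **Dominance quantification** — the proportion of intersexual contests won
   by females, and the ordered three-level coding *strict male dominance <
   no strict bias < strict female dominance*, where "strict" means one sex
   won more than 90 % of contests or is reported to always win.
2. **Phylogenetic signal** — Blomberg's K with permutation significance,
   for both outcome codings.
3. **Bayesian phylogenetic regressions** — a binomial logit on female win
   counts and a cumulative-link ordinal model on the three-level category,
   with populations nested inside a Brownian-motion species covariance,
   run as a per-predictor hypothesis battery with conditional sensitivity
   subsets (excluding lemurs, or excluding sexually dimorphic species).
4. **Synthetic validation** — a generator with known ground truth that is
   the exact inverse of the fitted likelihood, plus a parameter-recovery
   harness.

## The models

With V the phylogenetic covariance (shared root-to-tip branch length),
Blomberg's K compares observed to Brownian-expected variance partitioning:

    K = (MSE0 / MSE) / E[MSE0 / MSE],
    MSE0 = (Y − â1)ᵀ(Y − â1)/(n−1),   MSE = (Y − â1)ᵀV⁻¹(Y − â1)/(n−1)

K ≈ 1 under Brownian motion, K ≈ 0 without signal; significance comes from
shuffling trait values across tips (default 10,000 permutations).

The regressions share one latent structure.  For population *i* of species
*s(i)* with predictor x:

    W_i ~ Binomial(N_i, p_i),   logit(p_i) = α + β·x_{s(i)} + φ_{s(i)}
    Pr(y_i ≤ k) = logistic(κ_k − β·x_{s(i)} − φ_{s(i)}),  κ₁ < κ₂
    φ ~ MVNormal(0, η² C)

where C is the correlation-normalized V.  Priors are weakly regularizing
(β ~ N(0,1), α/κ ~ N(0,1.5), η ~ Exponential(1)); fits report the posterior
mean and 89 % compatibility interval, flag a predictor *reliable* when that
interval excludes zero, and gate on split-R-hat < 1.01.  Sampling is the
package's own batched adaptive HMC with hand-derived gradients (see
`docs/methods.md`).

## Worked example

`examples/03_binomial_regression.py` simulates 60 species (118 populations)
with a true slope β = 0.8 and phylogenetic scale η = 0.5, then refits the
generating model:

```
dataset: 118 populations, 60 species
          mean  lower  upper  rhat       ess
alpha    0.106  0.056  0.157   1.0  6997.596
beta[x]  0.840  0.732  0.948   1.0  7787.808
eta      0.488  0.374  0.620   1.0  2364.305

true slope: 0.8  |  posterior mean 0.84, 89% CI [0.73, 0.95]
reliable (interval excludes 0): True; max split-R-hat 1.000 (< 1.01 means converged)
```

The 89 % interval covers the generating slope, η is recovered at 0.49, and
every R-hat passes the 1.01 gate.  The other examples cover classification
(`01`), phylogenetic signal (`02`), the ordinal model (`04`), the recovery
harness (`05`) and the full pipeline with reports (`06`).

## Command line

A thin CLI wraps the pipeline:

```sh
phylodom signal  --data table.csv --tree tree.nwk --out out/ --seed 1
phylodom battery --config run.yaml
phylodom simulate --truth truth.json --out sim/
phylodom recover --grid grid.json --reps 20 --seed 1
```

The input table is delimited text (comma or tab, auto-detected) with one
row per population: `species, population_id, wins_female, wins_male,
pct_female_won, qualitative_dominance, contests_mm, contests_ff,
contests_mf, n_adult_males, n_adult_females, captive`, plus any predictor
columns named in the config.  Species names are matched to tree tips after
space/underscore and case normalization.

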