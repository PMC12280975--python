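# Methods

This note documents the statistical machinery in `phylodom`: the quantities
it computes, the models it fits, the synthetic data it validates itself on,
and the numerical and design choices a user should know about.

## The data model

The unit of observation is a *population* of a primate species.  A record
may carry raw counts of intersexual contests won by adult females
(`wins_female`, W) and by adult males, so that the total is N and the
continuous outcome is the win proportion p = W/N; or only a summarized
percentage; or only a qualitative statement that one sex always wins.
The ordered three-level coding is derived by the strict-dominance rule:

* **strict female dominance** — females won strictly more than 90 % of
  intersexual contests, or are reported to always win;
* **strict male dominance** — the mirror image;
* **no strict bias** — everything else (a share of exactly 90 % is *not*
  strict; the rule is strictly greater-than).

Qualitative statements are consulted only when no quantitative information
exists.  Multi-group studies are pooled by summing counts when every group
reports counts, otherwise by averaging percentages.  Records with only
qualitative or percentage information enter the ordinal analysis but are
excluded from the binomial analysis, which requires a real N; no pseudo-N
is ever invented.

Group-level descriptive statistics: the contest-mix fractions (male-male,
female-female, male-female shares of all agonistic interactions) and the
opposite-sex dyad fraction n_m·n_f / C(n_m+n_f, 2), defined for groups with
at least two adults.

## Phylogenetic covariance

A rooted, time-calibrated tree induces the Brownian-motion covariance
V[i,j] = shared root-to-tip branch length of tips i and j.  `phylo_vcv`
computes it in one postorder sweep; a root stem left by pruning counts
toward every pair.  Zero-length branches are permitted (MCC trees contain
them); V stays positive semidefinite.  Before model fitting V is rescaled:
the default is the correlation normalization V[i,j]/√(V[i,i]V[j,j]), which
puts the kernel on a unit diagonal regardless of tree depth and makes the
prior on the effect scale interpretable; a `unit_depth` alternative (divide
by max depth) preserves relative tip depths on non-ultrametric trees.
Species names are matched between table and tree after normalizing
spaces/underscores and case; unmatched species are dropped with a logged
warning, never fuzzy-matched.

## Blomberg's K

For a species-level trait Y (the species mean of p for the continuous
coding; the 0/1/2 scores of the category for the ordinal coding — K is
invariant to any affine recoding, so only order and equal spacing matter):

    â    = (1ᵀV⁻¹1)⁻¹ 1ᵀV⁻¹Y                 (GLS root-state estimate)
    MSE0 = (Y−â1)ᵀ(Y−â1)/(n−1)
    MSE  = (Y−â1)ᵀV⁻¹(Y−â1)/(n−1)
    K    = (MSE0/MSE) / E[MSE0/MSE],   E[MSE0/MSE] = (tr V − n/(1ᵀV⁻¹1))/(n−1)

K ≈ 1 for a trait evolving by Brownian motion on the true tree, K ≈ 0 when
trait values are unrelated to phylogeny, and K = 1 exactly on an
equal-depth star tree.  The implementation agrees with
`phytools::phylosig` to machine precision on a fixed fixture.
Significance is a one-sided permutation test: trait values are shuffled
across tips (the tree held fixed), the default 10,000 times, and
p = (1 + #{K_perm ≥ K_obs}) / (1 + n_sims), which floors at 1/(n_sims+1)
and is deterministic given a seed.  All permutations are evaluated in one
vectorized linear solve.  V is factorized by Cholesky with an escalating
diagonal jitter (10⁻¹⁰ up) for near-singular trees.

## Bayesian phylogenetic regressions

Two likelihoods share one latent structure.  With x_s the species-level
predictor (standardized if continuous, index-coded one-effect-per-level if
categorical) and s(i) the species of population i:

* **Binomial logit**: W_i ~ Binomial(N_i, p_i),
  logit(p_i) = α + β·x_{s(i)} + φ_{s(i)}.
* **Cumulative-link ordinal**: Pr(y_i ≤ k) = logistic(κ_k − μ_i),
  μ_i = β·x_{s(i)} + φ_{s(i)}, with ordered cutpoints κ₁ < κ₂ (three
  categories; the class is generic in the number of categories, and with
  two it reduces exactly to a logistic regression).  The latent location
  has no intercept — the cutpoints absorb it — which fixes the usual
  location non-identifiability.  A positive β shifts mass toward strict
  female dominance.

φ ~ MVNormal(0, η²C) is a species-level effect with C the
correlation-normalized phylogenetic covariance.  Populations of one
species share a single φ_s: repeated populations are nested inside the
phylogenetic structure with within-species latent correlation 1.

**Priors** (weakly regularizing, recorded in every run manifest):
β ~ Normal(0, 1); α and cutpoints ~ Normal(0, 1.5); η ~ Exponential(1).
Sensitivity over slope-prior scales {0.5, 1, 2} is available through
`PhyloGLMSpec.prior_scale_slope`.

**Identifiability of the intercept.** Because C is close to a
correlation matrix with a large shared component, the all-ones direction
of φ is nearly redundant with α (or with the cutpoints), which creates a
slow-mixing posterior ridge.  By default the kernel is therefore
conditioned to have zero GLS mean, C* = C − C11ᵀC/(1ᵀC1): the species
effect represents deviations from the grand mean and the intercept carries
the level.  This removes the exactly redundant direction, leaves β and the
fitted associations unchanged, and is switchable off via
`constrain_species_effect_mean=False`.

**Sampling.** No probabilistic-programming backend is used: the models
have hand-derived gradients (verified against finite differences) and are
sampled by the package's own adaptive Hamiltonian Monte Carlo
(`phylodom.hmc`) — static leapfrog trajectories with length jittered
uniformly on {1..32}, dual-averaging step-size adaptation to a 0.85 target
acceptance rate, one diagonal mass-matrix update mid-warmup, and all
chains advanced as a single batched numpy computation.  φ is always
sampled non-centered (φ = ηLz, L the Cholesky factor of C*), which is
essential near-singular kernels.  Divergent trajectories (energy error
> 1000) are rejected and counted.

The default budget is 4 chains × 2,000 post-warmup draws (8,000 total)
after an equal warmup.  The recovery harnesses and the battery examples
use a desk-scale budget of 4 × 500 draws after 500 warmup, which keeps a
full 150-fit recovery grid under ten minutes on one core; non-converged
replicates at that budget are recorded, never dropped.

**Summaries and gates.** Every fit reports posterior means and central
89 % compatibility intervals (the 5.5 %/94.5 % quantiles); an association
is *reliable* when the slope interval (for categorical predictors: any
pairwise level contrast) excludes zero.  Convergence is gated on
split-R-hat < 1.01 for every reported parameter (intercept/cutpoints,
slopes, contrasts, η), computed by `arviz` with the classic split method;
`strict=True` (the default) raises on gate failure with the full R-hat
table attached, while the battery and recovery harness run with
`strict=False` and flag the affected rows.  The R-hat gate is not applied
to the individual z coordinates of the non-centered effect, whose
mixing is reflected in the reported parameters.

## Synthetic data and validation

The generator is the exact inverse of the binomial likelihood:

1. a pure-birth (Yule) tree, depth-normalized to 1 (terminal branches are
   extended by the Exp(nλ) waiting time to the next unrealized speciation,
   so the covariance is never singular);
2. a species predictor from Brownian motion on that tree (standardized;
   categorical predictors are BM thresholded at equal quantiles, which
   preserves the phylogenetic clustering real categorical predictors
   show);
3. φ ~ MVNormal(0, η²C), with C the correlation-normalized covariance;
4. per species, 1–3 populations (configurable); per population,
   N ~ Uniform{10..120} contests and W ~ Binomial(N, logistic(α+βx_s+φ_s));
5. the ordinal outcome induced from the realized counts by the >90 % rule
   — the two codings are mutually consistent by construction, as in real
   data; an optional fraction of records is converted to qualitative-only.

Defaults (60 species, 1–3 populations, 10–120 contests) are a deliberately
desk-sized configuration comparable in shape to real comparative datasets.
What the generator does **not** emulate: literature-driven missingness
patterns, observer error in contest attribution, non-Brownian predictor
evolution, within-species predictor variation, or correlated predictor
batteries.  Passing recovery tests therefore demonstrate that the
inference machinery is calibrated for the assumed generative process, not
that the assumptions hold for any real dataset.

`recovery_experiment` runs the full loop over a grid of generating truths
and reports bias, RMSE, 89 %-interval coverage of the true slope, and sign
accuracy.  At the default conditions (η = 0.5, 60 species) the binomial
model's 89 % intervals cover the truth in well over 80 % of replicates at
β ∈ {0, 0.5, 1} and both models recover the sign of β = 1 essentially
always; with η fixed at 0 the posterior slope matches a maximum-likelihood
binomial GLM to < 0.05 at ~200 populations.  These are recomputed by
`scripts/acceptance.py` and by the test suite on every run.

## Pipeline conventions

The battery fits one univariate model per predictor and outcome coding —
deliberately no multivariate fits and no multiple-testing correction; each
association is judged only by its own 89 % interval, and reports say so.
Supported (reliable) predictors are retested after excluding lemurs
(Lemuriformes, where female-biased dominance concentrates); unsupported
ones after excluding species with male body mass > 1.10 × female body mass
(strictly greater).  Captive populations are retained by default with an
exclusion flag for sensitivity runs.  Every run manifest echoes the full
configuration, seeds (one master seed, split deterministically per fit),
software versions and a SHA-256 hash of the input table; identical
configuration and seed reproduce byte-identical machine-readable outputs.

## Known limitations

* Only the Brownian linear kernel η²C is implemented; an
  Ornstein–Uhlenbeck distance kernel would be a natural alternative for
  strongly constrained traits.
* The HMC engine has no U-turn criterion; pathological posteriors far
  outside the intended model family may need a larger `max_leapfrog`.
* Blomberg's K on the 3-level scores treats an ordinal trait as numeric;
  the 0/1/2 scoring is a documented convention (alternatives configurable),
  not a likelihood-based treatment of ordinal evolution.
* The >90 % rule is applied to pooled counts in multi-group studies; a
  per-group variant is not implemented.
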