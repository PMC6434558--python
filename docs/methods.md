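# Methods

## The design and the model

`halfsibqg` analyzes a nested paternal half-sib / maternal full-sib
breeding design: sires are mated in temporal blocks, several dams are
nested within each sire, and each dam's offspring are split between two
rearing-density treatments (`high`/`low`) and two sexes. For a trait
*y*, the standard ("with block") model is the Gaussian linear mixed model

    y = mu + density + sex + density:sex (+ covariates)
        + block + sire(block) + dam(sire) (+ test day) + e

with every random term an independent Gaussian intercept and `e ~ N(0,
V_R)`. The test-day intercept is crossed with the family hierarchy and is
used for behavioral traits whose assay day varies. Nesting is encoded by
composite group labels (`sire:block`, `dam:sire`) rather than formula
syntax, which keeps the fitting engine agnostic about where labels came
from.

Because paternal half-sibs share only additive genetic variance, the
among-sire component estimates V_A/4, so the package reports

    h2 = 4*V_S / (4*V_S + V_M + V_block + V_R)
    m2 =   V_M / (4*V_S + V_M + V_block + V_R)

and, for the model variant without the block intercept, the same ratios
with the block term omitted. Test-day variance — assay-day noise, neither
genetic nor maternal — is excluded from these denominators but included
in the percent-of-phenotypic-variance table, where every fitted component
(V_S counted once, not times 4) is expressed against the summed total.
This split of denominators is forced by the published worked examples the
acceptance suite reproduces: for the boldness-type rows, m2 and %V_P are
only mutually consistent if the ratio denominator drops test-day variance
while the %V_P total keeps it. For repeated-measures traits the
individual-level intercept/slope variances likewise count in %V_P but
never in h2/m2; whether the individual slope variance belongs in the m2
denominator is not decidable from the published numbers, so both
conventions exist behind `summary_from_components` (default: exclude).

Genotype-by-environment interaction is modeled as a sire-level reaction
norm: each sire carries a correlated (intercept, slope) pair where the
slope is its deviation in the low-density environment (high density is
the reference level). The 2-df likelihood-ratio test drops the slope
variance and the intercept-slope covariance together. The same machinery
runs with `dam` as the slope factor for the maternal-by-environment
check.

## REML engine

Estimation profiles out the fixed effects and the residual variance and
optimizes the restricted (or full) likelihood over variance *ratios*
γ_k = V_k/V_R on the log scale, with intercept-slope correlations mapped
through tanh. This enforces V_k ≥ 0 and |r| ≤ 1 and lets a component run
cleanly to the zero boundary: a ratio below 1e-8 is reported as exactly 0
with a boundary flag. All linear algebra uses the Woodbury identity, so
one likelihood evaluation costs a Cholesky factorization of the q × q
matrix Γ⁻¹ + Z'Z (q = total random-effect columns), never an n × n
factorization. The restricted log-likelihood follows the convention that
includes log|X'V⁻¹X| without the compensating log|X'X| term — the same
convention lme4 uses, and the test suite verifies agreement with lme4 on
a full reaction-norm model to three decimals in every component, the
fixed effects, and the log-likelihood itself.

The optimizer is Nelder-Mead started from method-of-moments ratios
(group-mean variances of OLS residuals), with three accuracy profiles:

* `full` (default): three deterministic multi-starts, a simplex restart
  at the best optimum, and an L-BFGS-B polish; convergence to ~1e-11 on
  the deviance. Used for reported fits and oracle-equivalence tests.
* `medium`: a single start at looser tolerance (~1e-9); agrees with
  `full` to ~1e-9 in practice and is used inside simulation loops.
* `fast`: a short warm-started simplex reserved for bootstrap refits,
  where the coefficient estimates are insensitive to third-decimal
  movement in the variance ratios.

Rows with missing values in any referenced column are deleted per model
and counted. Estimates are invariant to row order and group relabeling,
and a degenerate constant response is caught by a floor on the profiled
residual sum of squares rather than a crash.

Information criteria use k = number of covariance parameters (plus fixed
coefficients under ML); under REML they are only comparable across models
sharing a fixed part, which is the only way the package uses them (the
three-way random-structure comparison below).

## Inference

**LRTs for random effects** compare nested REML fits with identical
fixed parts: 1 df for an intercept variance, 2 df for a slope variance
plus covariance. Because the null value of a variance lies on the
boundary of its parameter space, the chi-square reference is
conservative — p-values up to twice their correct size. Unmodified
p-values are reported (the convention the reproduced analysis uses), and
each result also carries the 50:50 chi-square-mixture p-value
(`p_mixture`) for readers who want the boundary-corrected version.

**Fixed-effect uncertainty** comes from a nonparametric case bootstrap:
individuals are resampled with replacement (whole-individual row blocks
when measurements repeat within individuals — a redrawn individual is
treated as a new realized individual, while its sire/dam/block labels are
retained), the model is refit per resample from a warm start, and
percentile 95% CIs plus the two-sided sign p-value
`max(2·min(P(b≤0), P(b≥0)), 1/(R+1))` are collected. The resampling unit
is a design choice: residual and family-cluster bootstraps are defensible
alternatives, but the case bootstrap of individuals is the common default
and respects within-individual correlation. The production default is
R = 10,000 replicates; the coverage simulations in the test suite use
500 inner replicates as documented there.

**Per-minute activity** is modeled in long format (five 1-minute
distances per individual, log(x+1)-transformed, with standardized time
and time² as fixed covariates) under three candidate random structures:
(1) individual, sire, dam, block, test-day intercepts; (2) correlated
random time slopes within individual; (3) correlated random time slopes
within sire. Models 2 and 3 are each tested against model 1 with a 2-df
LRT; model 1 is retained unless a larger model rejects at α = 0.05, in
which case the significant model with the greater likelihood (lower AIC)
is selected, with parsimony breaking exact ties.

## Synthetic data

The simulator draws every random effect Gaussian with configured
variances, bivariate-normal (intercept, slope) pairs at the sire level
(reaction norms) and at the individual level (activity trajectories),
and exports the latent draws in a truth table so additive bookkeeping
and parameter recovery are exactly checkable. Default study-scale
configuration: 7 temporal blocks; 23 sires allocated 2–6 per block; 59
dams allocated 2–3 per sire; 6 offspring per dam per density treatment
(3 female / 3 male); independent per-offspring attrition of 4.1%,
bringing the balanced 708 down to ≈679 tested offspring. Test days are
assigned round-robin within each full-sib family with shuffled offsets,
so every family spans several assay days and every day mixes families.
Emergence latency is generated on the log(seconds + 1) scale,
back-transformed, and right-censored at 1800 s with a censoring flag;
the boldness score is log(1801) − log(latency + 1), so a censored animal
scores exactly 0. The +1 offset is this package's convention (raw
latencies and per-minute distances can be 0); analyses transformed
elsewhere without an offset will differ near zero.

What the simulator does *not* emulate: non-Gaussian traits, selection or
multi-generation pedigrees, dominance/epistatic variance,
group-rearing container effects, or dependence between attrition and
phenotype (dropout is completely at random). Passing recovery tests
therefore show that the estimation machinery is correct for the assumed
generating process, not that real data satisfy those assumptions.

## Numerical and scale choices in the test suite

Simulation-based checks are sized to run on one CPU in minutes: 200
replicates for recovery and bootstrap-coverage studies, 500 for the
boundary type-I-error study, 100 for model selection (run at a reduced
design of 8 sires / 16 dams / 96 individuals, where the individual-slope
signal at the published effect sizes keeps selection power essentially
at 1). Monte-Carlo tolerances are stated per test.

Known limitations worth keeping in mind:

* A variance whose truth is 0 (boundary) has a right-truncated sampling
  distribution under nonnegative REML; its mean estimate is strictly
  positive, and neighboring components absorb small compensating biases.
  Recovery checks that assert mean-unbiasedness componentwise will
  flag this for boundary-true components — the truncation is a property
  of bounded variance estimation, not an implementation defect.
* With 23 sires, heritability estimates from a half-sib design are
  intrinsically noisy (median absolute h² error ≈ 0.07 at the simulated
  mass-trait configuration); single-study h² values at this scale carry
  wide sampling intervals.
* Variance-component confidence intervals are not produced; the
  bootstrap machinery covers fixed effects only, and profile-likelihood
  or parametric-bootstrap intervals for components are out of scope.
* The engine fits Gaussian responses only; censored latency is handled
  by transformation and reverse-scoring, not by a survival model.
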