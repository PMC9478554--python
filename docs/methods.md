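# Methods

`woolgs` implements a genomic-selection analysis pipeline for traits
recorded repeatedly through an animal's life — the motivating case is wool
and body-weight traits of Angora rabbits measured at 70, 140 and 210 days
of age in a population of 629 genotyped animals. This note documents the
models, the synthetic-data generator used to exercise them, and the
numerical choices; it is written for someone who wants to judge what the
package's passing tests do and do not demonstrate.

## Models

### Univariate GBLUP

For one trait at one age,

    y = X b + Z u + e,      u ~ N(0, G σ²_u),   e ~ N(0, I σ²_e),

where `X` carries intercept, sex and batch (treatment coding, first level
reference; aliased columns dropped with a warning) and `G` is VanRaden's
genomic relationship matrix

    G = W W' / (2 Σ_k p_k (1 − p_k)),    W = dosages − 2p,

with `p` the in-sample alternate-allele frequency (method 1; the marker-wise
scaled method 2 is available behind a flag). Missing dosages are
mean-imputed (to `2p`) immediately before GRM construction and never before
QC. With in-sample frequencies `G` has a zero eigenvalue (row sums vanish),
so a diagonal shift of 1e-6 is applied before any fit.

REML estimation exploits the standard eigendecomposition trick: with
`G = Q D Q'` the rotated model has diagonal covariance `σ²_e (λ D + I)`,
`λ = σ²_u/σ²_e`; `σ²_e` is profiled out analytically and the restricted
likelihood is maximized over `log₁₀ λ ∈ [−6, 6]` by bounded scalar search
(tolerance 1e-10 on `log₁₀ λ`). This is deterministic and has no
starting-value sensitivity. `h² = σ²_u/(σ²_u+σ²_e)`; its standard error
comes from the delta method applied to a central-difference observed
information matrix of `(σ²_u, σ²_e)`. Estimates whose ratio lands at the
search boundary are flagged, and `h²` is reported as 0 when
`σ²_u < 1e-8 ×` phenotypic variance.

GEBVs are `û = σ̂²_u G[·, obs] V̂⁻¹ (y − X β̂)` for *all* individuals in
the GRM; unphenotyped animals are predicted purely through their genomic
relationships, which is the mechanism cross-validation evaluates. The
GBLUP fit is algebraically identical to a ridge regression on centered
marker dosages with per-marker variance `σ²_u / (2Σ p q)`; the test suite
verifies this equivalence against an independently coded marker-effects
solver.

### Trivariate GBLUP (three ages as distinct traits)

The three ages of one trait are modelled jointly:

    vec(U) ~ N(0, Σ_u ⊗ G),    vec(E) ~ N(0, Σ_e ⊗ I),

with 3×3 genetic and residual covariance matrices. Records may be missing
per (individual, age) cell; each age has its own incidence matrix and its
own fixed-effect coefficients, and missing records are handled by row
deletion, never phenotype imputation — a requirement for the leave-out
designs to mean anything.

Two REML engines compute the same restricted likelihood:

* **complete-record path** — when every phenotyped individual has all three
  ages, the model rotates into the eigenbasis of (the phenotyped submatrix
  of) `G`, where the likelihood factorizes over individuals into 3×3
  blocks `V_i = d_i Σ_u + Σ_e`. Each iteration is O(n).
* **general path** — with arbitrary missing patterns, the observed-record
  covariance `V` (records × records) is assembled from `Σ_u ⊗ G` blocks
  plus `Σ_e` on same-individual overlaps and factorized densely.

The two paths agree to ~1e-8 on complete data (tested). Optimization runs
a short expectation-maximization warm-up (5 iterations; a supplied starting
value replaces it) followed by average-information (AI) updates with
Levenberg-style damping: when the raw AI step fails to improve the
restricted likelihood, the step is re-solved with an increasingly damped
curvature matrix, interpolating toward steepest ascent, with a pure EM step
as the final fallback. Every proposed covariance matrix is "bent":
symmetrized and eigenvalue-floored at `1e-6 × trace/3`.

Traits measured repeatedly at high genetic correlation (the design premise
here, r_g ≈ 0.8) push `Σ_u` toward rank deficiency, where AI-REML
characteristically crawls along the positive-semidefinite boundary. The
fit therefore finishes with an L-BFGS-B refinement in log-Cholesky
coordinates (`Σ = L L'`, log-transformed diagonal), which is smooth up to
the boundary and uses the analytic gradient `∂ll/∂L = 2 (∂ll/∂Σ) L`. EM
iterations are monotone in the restricted likelihood (asserted per
iteration in the tests); convergence is declared at a relative
log-likelihood change below 1e-8, with a stall detector that hands
slow-crawling runs to the Cholesky refinement early.

### Cross-validation and the experiment designs

Prediction accuracy is the fold-wise Pearson correlation between GEBVs and
corrected phenotypes `yc` (phenotype minus the full OLS fit of intercept +
sex + batch, computed once on all phenotyped animals so the evaluation
target is identical across models and densities), averaged over folds.
Folds are as equal as possible (629 → nine folds of 63 and one of 62). The
GRM always includes the validation animals — information may flow through
genomic relationships, records may not. Every fit records exactly which
(individual, age) records it used, and the CV driver asserts that no masked
record ever entered a training fit.

Four model tags: `uvLMM` (univariate per age), and the trivariate model
under three leave-out strategies — `mvLMM` (validation animals lose all
three ages), `mvLMM23` (lose ages 2 and 3), `mvLMM3` (lose age 3 only).
For the partial strategies, accuracies at ages observed in validation are
reported but flagged as such. Partial-strategy fits are warm-started from
the same fold's leave-all-out fit, which is itself estimated without any
masked record.

The marker-density experiment subsamples k markers uniformly without
replacement (deterministic per-replicate seeds spawned from one base seed),
rebuilds the GRM, re-estimates heritability, optionally reruns CV, and
records all pairwise correlations (upper triangle including the diagonal)
between the replicate GRMs of a density. Accuracy groups are compared with
Welch's two-sample t-test (Student's behind a flag).

## The synthetic-data generator

The generator produces the data structure the analysis assumes, with known
truth:

* **Genotypes.** Founder haplotypes are first-order Markov chains along
  each of 10 chromosomes with adjacent-marker correlation `ld_rho = 0.9`
  and per-marker MAF uniform on [0.05, 0.5]. The study cohort is bred from
  a closed pool of 25 sires and 100 dams for 5 non-overlapping generations
  (parents drawn uniformly per offspring, emulating mixed-semen
  insemination with no recorded pedigree), each gamete recombined with on
  average one crossover per chromosome. The resulting half/full-sib
  families and background relatedness give `G` the eigenvalue spread real
  farm populations have. This matters twice: REML heritability information
  at n ≈ 629 comes almost entirely from relatedness variance (with
  unrelated individuals, reported SEs of ĥ² exceed 0.2 and nothing is
  recoverable), and GBLUP's prediction of masked animals works through
  relatives. The family-structure intensity was chosen so the reported
  standard errors of ĥ² (~0.05–0.06) match the scale typical of
  single-farm populations of this size; `n_sires=None` switches back to
  unrelated individuals.
* **Phenotypes.** 200 of the markers act as pleiotropic QTL whose 3-vector
  effects are drawn from N(0, R_g) with R_g the target genetic correlation
  matrix (default all off-diagonals 0.8); breeding values are the centered
  QTL dosage scores. Genetic and residual parts are rescaled *on the
  realized sample* so that realized h² equals the target exactly (default
  (0.05, 0.30, 0.30), spanning the low/medium/high range of wool traits)
  and phenotypic variance is 1. Sex (298:331 male:female ratio, additive
  effect 0.5) and batch (3 round-robin batches, effects 0/0.3/0.6) enter as
  fixed shifts. Residuals are independent across ages by default; a
  residual-correlation option exists.

What the generator does **not** emulate: genotyping/imputation error,
dominance or epistasis, QTL outside the marker panel, selection, age-
dependent residual variances, and LD with realistic physical decay
distances. Passing tests therefore demonstrate correctness and the
qualitative behaviour of the designs (density plateaus, multi-trait
borrowing, leave-out ordering), not real-data effect sizes.

## Problem sizes used by the tests and acceptance run

Parameter recovery, univariate/multivariate consistency, and the
borrowing comparison run at the study scale (n = 629, 10K markers, 20 and
10 replicate seeds). The density scan uses a 200K-marker panel at n = 400
with densities 0.5K/5K/50K and 10 replicates. The gain-versus-heritability
grid runs at n = 450 with 10 folds and varies the *focal* age's h² over
{0.05, …, 0.4} while the two donor ages stay at 0.3 (r_g = 0.7) —
borrowing requires the correlated ages to carry information, which is how
real low-heritability trait-ages sit inside their trait profiles.
Following the convention of reporting percentage improvements, the gain is
*relative*: (mv − uv) accuracy divided by the uv baseline (floored at 0.05,
below which a percent gain is not meaningful) — absolute gains are roughly
flat in h² while baselines rise with it, so the borrowing advantage of
low-h² traits is a statement about relative gain. Each grid point averages
the gain over three phenotype realizations on the experiment's genotype
panel; a single realization's gain at h² = 0.05 is noise-dominated. The partial leave-out
strategies, whose
general-path fits cost O(records³) per iteration, run at n = 220 with 3
folds and 10 replicate seeds — enough for the sign and ordering of the
contrasts, which is what those experiments establish.

## Known limitations

* The HWE filter needs hard genotype calls, so dosages are rounded for
  that test only; with heavily imputed data this understates
  disequilibrium. The exact test (not chi-squared) is used.
* The multivariate fitter reports no standard errors; the univariate
  delta-method SE is calibrated within ~30% (tested), which is adequate
  for the ±SE reporting convention but not for formal inference.
* `G` is never inverted; all solves go through factorizations, but the
  general multivariate path is dense and O(records³) per iteration —
  fine for a few thousand records, not for hundreds of thousands.
* Batch is a simulated fixed effect exercised by the machinery; with a
  single batch the aliased column is dropped automatically.
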