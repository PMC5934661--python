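# Methods

This note documents the statistical model behind `iwscoring`, the defaults
and why they were chosen, what the synthetic data generator does and does
not emulate, and the numerical decisions a maintainer would want written
down.

## The weighting model

The package integrates k per-variant functional scores into one score per
variant without labelled training data. The premise is a latent-signal
model: each variant has an unobserved functional state, and each scoring
system reports that state plus system-specific noise. Conditional on the
state, systems are treated as (approximately) independent. Under that
premise the systems' correlation matrix is, up to noise structure, a
rank-one signal plus diagonal — and the lead eigenvector of the correlation
matrix points along the signal loadings. Its components are therefore used
directly as integration weights: systems that agree most with the common
signal get the largest weights, and weakly informative or idiosyncratic
systems are down-weighted, with no tuning against labels.

The conditional-independence premise is knowingly optimistic — real scoring
systems share input annotations and training resources, so blocks of them
are residually correlated beyond the shared signal. A residually correlated
block pulls the lead eigenvector toward itself, inflating its members'
weights relative to their true informativeness. The panel is chosen to mix
methodologically distinct systems precisely to dilute this effect, and the
weight-recovery simulations (below) quantify it: with a realistic block
structure the estimated weights still rank-track the true loadings with
Spearman ≈ 0.98.

Weights are reported as the raw unit-norm eigenvector, not renormalized to
sum 1: any fixed rescaling of the weights rescales every integrated score
and the fitted null identically, so p-values and ranks are invariant to the
convention. The eigenvector sign is fixed by requiring a positive component
sum (all-positive weights are the expected regime for a panel of
like-oriented scores). A tied lead eigenvalue leaves the direction
undefined and is reported as an error rather than resolved arbitrarily —
it essentially never occurs on real correlation matrices but is the correct
behaviour on, e.g., the identity.

### Covariance as pairwise correlation

The covariance matrix is computed as pairwise-complete Pearson correlations
of the standardized columns (for standardized data the two notions
coincide). Pairwise-complete estimation lets every variant contribute to
the pairs it is scored on, which matters because per-system coverage is
uneven; the cost is that the assembled matrix is not guaranteed positive
semidefinite, which is harmless here since only the lead eigenpair is used
and pairs must share at least 3 joint observations (an error otherwise).

### Weight stability

Because the weights are a spectral statistic of a correlation matrix over
hundreds of thousands of variants, they should be insensitive to which
variants were sampled. `weight_stability` re-estimates weights on random
20/40/60/80% row subsets; on the default synthetic panel at n = 50 000 the
maximum per-component deviation from full-data weights stays below 0.05
(measured ≈ 0.01).

## Rescaling

Training columns are standardized to mean 0, variance 1 using the sample
standard deviation (n−1). Query scores are mapped onto that scale by the
linear map anchored at the retained training extremes, i.e. the unique
solution of (Max_A − m)/(m − Min_A) = (Max_R − x)/(x − Min_R). Two
numerical points:

- the endpoints are pinned exactly (the floating-point quotient can
  otherwise be off by 1 ulp at the anchors);
- values beyond the training range extrapolate linearly — novel mutations
  can exceed the training extremes — and extrapolated cells are counted in
  a warning rather than clipped.

For a training variant the anchored map reproduces (m − mean)/sd
algebraically, which is what makes re-scored training rows reproduce their
training integrated scores.

## Missing scores: EM with bootstrapping

Missing values are imputed under a single multivariate-normal model with
ignorable missingness. Each of 10 completions bootstraps the rows, fits the
normal by EM on the bootstrap sample (bootstrapping supplies
between-imputation parameter uncertainty), and draws every missing cell
from its conditional normal given the row's observed cells — conditional
mean plus conditional-variance noise, i.e. proper imputation. The final
value is the mean of the 10 draws; observed cells are never altered.

Defaults and guards:

- `n_imputations = 10`; EM tolerance 1e-5 on the max parameter change, cap
  200 iterations (non-convergence is an error, not a warning);
- covariance ridge 1e-6 × mean diagonal — bootstrap samples of strongly
  correlated score blocks are frequently near-singular, and the ridge keeps
  the conditional covariances factorizable; a semidefinite eigenvalue
  factorization backs up the Cholesky for the degenerate residue;
- identifiability is checked up front: every column needs ≥ 2 observations
  and every pair at least one joint observation.

Query sets are typically far too small to estimate an 11×11 covariance, so
they are stacked on a complete-case reference pool retained from training
(up to 100 000 rows, seeded sampling) and the union is imputed; only the
query rows are returned. Imputation runs in the standardized training
space — observed query cells are rescaled before the merge — because the
pool is stored in that space; imputing in raw units would require carrying
per-system raw pools instead and makes no difference to the linear model
beyond bookkeeping.

## Significance

Integrated training scores straddle zero with a long right tail, so a plain
lognormal cannot describe them. The null is a shifted (three-parameter)
lognormal fitted by maximum likelihood over shift, meanlog and sdlog; if
the location estimate fails or lands inside the data support the shift
falls back to −min(score) + 1e-6 × range with moment estimates of
meanlog/sdlog on the shifted logs. The full-ML fit was preferred after
measuring the fallback's bias: with the fallback shift, the recovered sdlog
on simulated shifted-lognormal data is off by up to ~0.05 (the realized
minimum underestimates the true support boundary), while the full fit
recovers parameters to ~0.01. p-values are the upper-tail probability,
clamped to (0, 1] — never exactly 0; scores below the fitted support get
p = 1.

An empirical alternative (`family="empirical"`) uses the training-score
quantiles directly: p = (r + 1)/(N + 1) with r the count of training scores
at or above the query score, so a score beating all N training scores gets
1/(N + 1). The sorted training scores are retained in the model file either
way, so the choice can be revisited after training.

A second, deliberately different significance mode (`local_significance`)
asks whether one variant is exceptional *within its locus*: the target
score is z-scored against the mean and SD of nearby variants' scores and
mapped through the upper-tail normal probability. The genome-wide null and
the local background answer different questions; the caller chooses.

## Workflows

`K11` uses the full panel; `K10` drops fitCons (purely
evolutionary-conservation signal, the weakest contributor on clinical
variants); `N8` drops the three GWAVA classifiers, which only score
catalogued variants and therefore cannot cover novel somatic mutations;
`N6` further drops CADD and DeepSEA, the weakest discriminators of
recurrent somatic mutations. Each workflow retrains weights, rescaling and
the null on its own subset — weights from a larger panel are not reused
with columns zeroed out, because removing a system changes the correlation
structure the eigenvector is computed from. A model file is bound to one
workflow.

## Ranking and clusters

Query variants are ranked by descending integrated score; ties are broken
by (chrom, pos, ref, alt) lexicographic order (the choice is arbitrary but
documented and total). Internally the scoring pipeline sorts query rows
into canonical key order before imputation and restores input order on
return, which makes scores, p-values and ranks exactly invariant to the
input row order.

Cluster detection chains significant mutations (p strictly < 0.05) along a
chromosome while each consecutive inter-distance is strictly < 10 kb, and
reports maximal chains with ≥ 3 members. The gap criterion applies to
consecutive member positions, not to the total span, so a long cluster of
closely spaced mutations is a single report. Recurrence across samples is
expressed by pooling the cohort's mutations before detection; the module
does not deduplicate by sample — whether multi-sample support is required
is left to the caller.

## The synthetic generator

`generate_two_class_scores` draws, per variant, a functional label
(Bernoulli, prevalence 0.1), a latent signal N(2·label, 1), and per-system
emissions `a_i·signal + noise` with unit-variance noise correlated within
two blocks (a tight five-system block at residual r = 0.6 — Eigen, DeepSEA,
FATHMM-MKL, ReMM, CADD — and a moderate three-system GWAVA block at 0.3),
then masks cells MCAR at per-system rates. Defaults:

- loadings 1.0 down to 0.35, distinct per system, largest in the tight
  block — the qualitative informativeness ordering observed on real panels;
- missingness ~5% for well-covered systems, 9–13% for the annotation-hungry
  ones, 45% for the worst-covered — the coverage span reported for real
  panels between training-set and clinical-set conditions;
- prevalence 0.1 and class shift 2.0, giving single-system AUCs of roughly
  0.6–0.84 — a "good but imperfect scorer" regime.

What the generator does not emulate: the real systems' marginal score
distributions (bounded scores, point masses, heavy tails), informative
(MAR/MNAR) missingness beyond the optional MAR stress mode, linkage between
nearby variants, and any genomic covariates of the signal. Passing tests
on this generator therefore demonstrate correctness of the machinery and
its behaviour under the model's own assumptions — not performance claims
about real cohorts.

`generate_positions` plants clusters with intra-gaps below 10 kb among
background positions guarded to be at least 10 kb apart, so detection at
the same threshold must recover exactly the planted groups; the guard is
what makes the recovery test sharp rather than probabilistic. All
generation uses NumPy's PCG64 generator seeded from the config.

## Problem sizes

Simulation-based checks use n = 50 000 variants for weight recovery and
stability (5 seeds / 20 subsamples), n = 20 000 for the integration-benefit
AUC comparison, 10 000 held-out draws for null calibration, and ~3000×11
matrices for imputation accuracy — sizes at which the measured quantities
are stable to well within the tolerances asserted, as chosen for the
bundled acceptance script.

## Known limitations

- The multivariate-normal imputation model is misspecified for bounded or
  discrete scores; it is the interdependency structure, not the marginals,
  that it is relied on for.
- Pairwise-complete correlation can in principle produce an indefinite
  matrix under adversarial missingness patterns; only the lead eigenpair is
  consumed, and the joint-observation floor keeps entries estimable.
- The lead-eigenvector weights are only identified up to the block
  structure of residual correlations; a heavily redundant sub-panel will
  attract weight beyond its marginal informativeness.
- p-values inherit the null's fit quality in the extreme tail; for
  tail-critical applications the empirical null bounded by 1/(N+1) is the
  conservative choice.
- Scoring assumes the query systems' raw values are on the same scale as
  the training table that produced the model (including any upstream
  transform conventions); the model file records the transform per system
  but cannot detect a scale mismatch in identity-transform systems.
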