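# Methods

This note documents the statistical procedures implemented in `esbench`, the
choices made where several conventions exist, and what the synthetic-data
generator does and does not emulate.

## Data model and cleaning

An effect record is one signed standardized mean difference (SMD) extracted
from a meta-analysis, labelled as Cohen's *d* or Hedges' *g*, with optional
95% CI bounds, group sample sizes, publication year, vessel bed
(macro/micro), measurement modality and biological category. Records from
the same parent meta-analysis share a cluster label. Missing metadata maps
to explicit `unknown` levels rather than dropping rows, so subgroup analyses
can exclude unknowns without losing them from the pooled distribution.

Cleaning applies two rules in a fixed order: (1) records flagged as
duplicates are removed (an exact-tuple auto-detector over value, CI bounds
and sample sizes exists but is off by default — duplicate status is an
extraction-time judgement, not a numeric coincidence); (2) records with
absolute value strictly greater than the outlier threshold (default 8) are
removed. The threshold is applied to the value on its extracted metric,
before any d/g conversion: the rule screens implausibly large reported
numbers, and applying it pre-conversion keeps it independent of whether
sample sizes happen to be available. Counts of each removal reason are
retained and always conserve the input count.

## Metric harmonization

Hedges' *g* corrects the small-sample bias of Cohen's *d*:
*g* = *d* · *J*(*N*) with *J*(*N*) = 1 − 3/(4*N* − 9) and *N* = *n*₁ + *n*₂.
The inverse *d* = *g*/*J* is exact, so harmonization to the *d* scale is a
deterministic rescaling; CI bounds are scaled by the same factor. Because
*J* depends only on the combined sample size, a record reporting a single
total *N* is corrected using that total; for paired designs the reported
total is used as given. *g* records lacking sample sizes cannot be rescaled
and are passed through with an `unconverted_g` flag; by default they stay in
the pooled magnitude distribution (the shrinkage *J* is within a few percent
of 1 at typical sample sizes), and a strict mode can exclude them.
Numerical edge case: at *N* = 3 the correction factor is exactly 0, so the
*g*→*d* inverse is undefined and raises.

Standard errors are derived from symmetric normal-theory intervals as
(upper − lower)/(2·z₍(1+level)/2₎); an asymmetric interval (detected when
the point estimate is supplied) still uses half the full width, with a
warning.

## Benchmarks

Small/medium/large benchmarks are the 25th/50th/75th percentiles of the
absolute effect sizes, estimated by linear interpolation between order
statistics at plotting positions (k−1)/(n−1) (R's default type 7, exposed as
a config option since definitions differ at small n). Shape is summarised
by moment-based skewness g₁ = m₃/m₂^{3/2} and excess kurtosis
g₂ = m₄/m₂² − 3 using population central moments by default; the
small-sample-adjusted estimators are selectable. Groups need at least 4
values; smaller subgroups are flagged `insufficient` rather than producing
an unstable triple. Peripheral arterial tonometry is treated as a
plethysmographic modality at extraction time; the enum reflects that pooling.

## Correlate regressions

Effect magnitudes from the same meta-analysis are correlated, so the
bivariate OLS fits (magnitude vs publication year, magnitude vs
log₁₀(total N)) use the cluster-robust sandwich: scores summed within each
of G clusters, meat = Σ_g s_g s_gᵀ, variance
c·(XᵀX)⁻¹·meat·(XᵀX)⁻¹ with c = [G/(G−1)]·[(N−1)/(N−k)], and a *t*
reference with G−1 degrees of freedom (a normal reference is available).
The implementation delegates to statsmodels' clustered covariance, which the
test suite verifies against an explicit brute-force sandwich to 1e-10.
The log base for the sample-size covariate defaults to 10 and is
configurable; the covariate is the combined (treatment + control) size.

The clustered bootstrap resamples G clusters with replacement, keeps all
rows of each drawn cluster, refits OLS per replicate (implemented via
per-cluster sufficient statistics, which is algebraically identical for a
bivariate fit), and reports the percentile interval (10,000 replicates by
default; BCa was not used because the percentile interval is the plain
reading of a clustered bootstrap CI). Replicates whose resample has a
constant covariate are redrawn with a logged count and a retry cap. A
single seeded generator drives each call; the seed is part of the bootstrap
spec with a documented default.

LOESS uses tricube weights over the span-nearest neighbours (span 0.75,
local degree 2 — the defaults of the R `loess` smoother) and refuses to
extrapolate beyond the data range. statsmodels' `lowess` is degree-1 only,
so the local-polynomial smoother is implemented here directly.

## Power analysis

Power is computed from the noncentral *t* distribution: two-sample tests use
df = n₁+n₂−2 and noncentrality λ = d·√(n₁n₂/(n₁+n₂)); paired tests use
df = n−1 and λ = d·√n with d on the paired-difference scale. Two-tailed
power includes the wrong-direction rejection tail, so power at d = 0 equals
α exactly. (scipy's noncentral-*t* CDF underflows to NaN deep in the wrong
tail at large λ; the term is numerically zero there and is treated as such.)

`required_n` returns the *smallest integer* sample size whose power meets
the target — the returned result always satisfies power(n) ≥ target and
power(n−1) < target — found by bracket doubling and integer bisection on the
monotone power function. The continuous crossing point is solved as well
and reported as `n_continuous`, because some power software prints the
fractional solution and users round it in different directions; the
smallest-sufficient-integer rule is the convention here. Unequal group
sizes are supported for power evaluation; the sample-size solver solves the
balanced case.

## Meta-analysis power

A meta-analysis with summary standard error se has two-tailed z-test power
1 − Φ(z₁₋α/₂ − δ/se) + Φ(−z₁₋α/₂ − δ/se) against an assumed true effect δ.
The z (not t) reference matches how pooled summary effects are tested.
Profiles are evaluated on the δ grid 0.1…1.0 (step 0.1, overridable) and at
the *absolute* observed summary effect — power depends on magnitude and
summary effects may be negative. Standard errors are taken directly when
present, otherwise derived from the 95% CI half-width (the default, since
summary CIs are the universally reported uncertainty). Medians across
meta-analyses are element-wise on the shared grid.

## Synthetic-data generator

The generator emulates one extraction dataset at the study's conditions:

- 40 clusters; 752 clean rows allocated multinomially (so about 19 per
  cluster), plus 6 flagged duplicates and 2 planted outliers, i.e. 760 raw
  rows by default.
- Magnitudes: lognormal with median 0.69 and log-sd σ = 0.83. σ was set so
  the 75th/50th percentile ratio is ≈ 1.75, matching the target medium→large
  ratio; a two-parameter law cannot match all three target quantiles at
  once, and the 25th percentile is the one left free. A gamma alternative
  is available. Clean rows are drawn from the law conditioned on
  [0, threshold] and the planted outliers from beyond it, so the cleaning
  rules remove exactly the planted rows; `GroundTruth` reports the
  closed-form quantiles of the truncated law (at the default parameters the
  truncation holds 99.8% of the mass, so these sit within ~0.005 of the
  unconditional quantiles).
- Within-cluster correlation: a shared normal random effect on the log
  magnitude (default sd 0.3), with the residual log-sd shrunk so the
  marginal law is preserved exactly.
- Covariate links: additive slopes on centred covariates — default −0.19
  per unit log₁₀(total N) and 0 per publication year — injected after the
  base draw, with out-of-range rows redrawn. Centring keeps the marginal
  median essentially unchanged.
- Sample sizes: discretized lognormals with medians 21 (treatment) and 20
  (control), log-sd 0.45, truncated at 5. Years: uniform 1990–2021. Signs:
  negative with probability 0.35 (the literature mixes directions).
  Metrics: half the rows are labelled Hedges' g (values shrunk by the true
  correction factor so harmonization recovers d exactly), and 2% are g
  without sample sizes. CI bounds are symmetric normal-theory intervals
  from the standard SMD standard error.
- Vessel beds are assigned 72.3% macro / 27.3% micro / 0.4% unknown, with
  modality mixes conditional on bed. By default the two beds share the
  magnitude law, keeping the pooled ground truth closed-form; a
  `bed_log_shift` knob makes the microvascular bed stochastically smaller
  for tests of subgroup ordering. Real data differ here: the observed
  macro/micro distributions genuinely differ, so passing subgroup tests
  shows correct mechanics, not a claim about real subgroup contrasts.
- The meta-summary generator draws per-meta standard errors lognormally
  (median 0.18) and mixed-sign summary effects N(0.10, 0.55), with CIs
  exactly consistent with the standard errors.

Seeding: one `SeedSequence` per config seed, spawned into independent
sub-streams for the effects table and the meta table, so each table is
reproducible on its own and runs are byte-identical for a fixed seed.

What the generator does **not** emulate: publication-bias selection, genuine
macro/micro and modality differences in magnitude (unless `bed_log_shift` is
set), dependence between a meta-analysis's summary effect and its standard
error, and heavy-tailed summary-effect outliers. Tests passing on this
synthetic world therefore validate the pipeline's mechanics and its
frequentist calibration, not substantive claims about real endothelial
function literatures — those require the real extraction table, which the
pipeline reads in the documented CSV schema.

## Test and verification scales

The test suite exercises: hand-computed oracles (interpolated quantiles for
n ≤ 12, a brute-force cluster sandwich, moment arithmetic, normal-CDF power
values), independent library cross-checks (statsmodels power classes), and
seeded simulations — quantile recovery at n = 50,000 against closed-form
truth (tolerance 0.01), 500-run coverage of the cluster-robust CI (≥ 93%),
200-replicate coverage of the clustered-bootstrap CI for the injected slope
(≥ 90%), and 20-replicate shape brackets (skewness 1.5–4, excess kurtosis
4–16). Replicate counts were sized to keep the full suite under a minute on
one CPU while leaving the binomial noise of each empirical rate well inside
the asserted margin.

## Known limitations

- The quantile, skewness and kurtosis estimators come in several variants;
  the defaults (type-7 quantiles, population-moment shape statistics) are
  stated above and alternatives are exposed, but results from other
  software may differ slightly at small n.
- The sample-size solver's smallest-sufficient-integer convention can
  disagree by one unit with tools that round the continuous solution to the
  nearest integer when the crossing point falls just above an integer;
  `n_continuous` is reported to make such comparisons transparent.
- The clustered bootstrap resamples clusters only (no residual schemes) and
  reports percentile intervals; with few clusters these can undercover
  slightly, as the coverage simulations quantify.
- LOESS assumes a dense enough design within each span window; degenerate
  windows fall back to including all span points with floor weights.
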