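# Methods

## Setting and assumptions

All inputs are 3D scalar volumes on one shared grid ("standard space"):
spatial normalisation, brain extraction and tissue segmentation happen
upstream and are out of scope. `normatlas` never resamples or reorients —
grids must match exactly (shape identical, affines within 1e-5
elementwise), and a mismatch is an error naming the offending file. For
grey-matter proportion images, values inside the analysis mask must lie in
[0, 1] with no NaN; out-of-range values are rejected by default (an
explicit `clamp=True` clips instead), because the bounded support is the
scientific point, not a nuisance.

Every atlas and classification treats voxels independently. No spatial
smoothing is applied anywhere: smoothing would blur exactly the localized,
single-subject deviations the method is meant to detect.

## Distribution-shape diagnosis

Per voxel, across the cohort, the package computes the third and fourth
standardised central moments with population (divide-by-n) normalisation:

    skewness = (1/n) Σᵢ ((xᵢ − μ)/σ)³        kurtosis = (1/n) Σᵢ ((xᵢ − μ)/σ)⁴

with σ the divide-by-n standard deviation. This convention is chosen so the
Gaussian reference values are exactly 0 and 3 in the large-n limit; no
small-sample bias correction is applied, and the choice is recorded in the
map metadata. Useful facts the tests lean on: kurtosis ≥ 1 for any
distribution (equality for symmetric two-point data) and
kurtosis ≥ 1 + skewness² always.

Zero-variance voxels have no defined moments. They are returned as NaN with
a companion boolean validity mask rather than silently zeroed. "Zero
variance" is decided against a scale-aware threshold
(100·eps·max(1, |μ|))², since a constant sample accumulates O(eps)
round-off in its mean. Moment maps require ≥ 4 subjects and warn below 20,
where a fourth-moment estimate is mostly noise.

Formal normality tests (e.g. Kolmogorov–Smirnov) are deliberately not
provided: a rejection says the data are not Gaussian but nothing about
*how* they deviate, which is what the maps show.

## Percentile atlases

Both estimators consume a `CohortStack` (subjects × in-mask voxels) and
produce values for an ascending rank list, default {2.5, 25, 50, 75, 97.5}.

**Parametric.** Fixed multipliers on the per-voxel mean and population SD:
−2, −0.7, 0, +0.7, +2 for the five canonical ranks. The ±2 multiplier
(rather than the exact Gaussian 1.96) is the conventional, more
generalisable choice for normal limits; the resulting systematic 0.04·σ
offset from the true Gaussian 2.5th percentile is visible in the tests.
Requesting non-canonical ranks under the parametric method falls back to
exact Gaussian quantile multipliers and flags the atlas as an `extension`
in its metadata, so the canonical scheme is never silently extrapolated.
Parametric values are never clamped to [0, 1]: negative lower limits on
proportion data are the phenomenon under study.

**Nonparametric.** Order statistics with 1-based ascending indexing. For
percentile p ∈ (0, 100) and sample size n, compute np·(p/100) = j + g;
return (x_j + x_{j+1})/2 when g = 0 and x_{j+1} when g > 0. Edge cases not
fixed by that rule are clamped to the sample range: j = 0 returns x₁, and
g = 0 with j = n returns xₙ. Whether g = 0 is decided with absolute
tolerance 1e-9 on the fractional part, because n·p/100 can be integral in
decimal yet inexact in binary (e.g. n = 10,000, p = 2.5). The
implementation is vectorised over voxels; its scalar form is verified
exactly against an independent rational-arithmetic (`fractions.Fraction`)
oracle on 1,000 random cases.

Atlas invariants asserted in tests: values non-decreasing across ranks at
every voxel for both methods; nonparametric values inside the per-voxel
sample range; permutation invariance in subject order. Atlases built from
fewer than 70 subjects warn that extreme ranks may still oscillate (see
Stability below); the threshold is configurable.

**Serialisation.** An atlas bundle is a 4D NIfTI (4th axis = ranks,
float32), a companion mask NIfTI, and a JSON sidecar that is the authority
for rank labels, method, and subject count. The explicit mask file exists
because reconstructing the mask from nonzero voxel values would drop
in-mask voxels whose atlas values are legitimately zero. Round-trips are
exact at the declared float32 precision.

## Classification and discordance

A subject voxel is assigned the atlas rank whose value is nearest in
absolute difference; exact ties break to the **lower** rank. The tie
direction is not scientifically forced — it is fixed for reproducibility,
and lower is the conservative choice next to the abnormality threshold. A
voxel is **abnormal** when the subject value is *strictly below* the
lowest stored rank value (2.5th by default); equality is normal.

Two consequences follow directly and are property-tested: (1) classifying
the atlas cohort against its own nonparametric atlas can flag at most 2/n
of subjects per voxel (only x₁ and x₂ lie strictly below x₃ = the 2.5th
value at n = 98); (2) wherever the parametric 2.5th value is negative, no
subject with values in [0, 1] can ever be parametric-abnormal — the
mechanism that generates "normal by parametric, abnormal by nonparametric"
voxels.

Discordance between a parametric and a nonparametric classification of the
same subject partitions the mask into four categories: concordant-normal,
concordant-abnormal, normalP_abnormalNP, abnormalP_normalNP. The category
names are neutral; neither atlas is treated as ground truth. Per subject,
the summary reports

* pct_normalP_abnormalNP = 100 · |normalP_abnormalNP| / |NP-abnormal voxels|
* pct_abnormalP_normalNP = 100 · |abnormalP_normalNP| / |P-abnormal voxels|

with cohort median and IQR over subjects; subjects with a zero denominator
are excluded from the median/IQR and their count reported. Regional
proportions (which lobe the discordant voxels fall in) are **pooled over
subjects** by default — category voxels in region r divided by all
category voxels — with a per-subject-averaged alternative behind a flag;
the pooling mode is recorded in the report.

## Simulation

`simulate_comparison` draws one seeded sample (Poisson, Gaussian, Beta or
exponential), then computes the parametric values from the sample mean and
population SD and the nonparametric values from the order statistics — the
same estimators the atlases use, on a 1-voxel problem. For Poisson counts
at rate 2 (rate chosen to put the median at 2 and make the skew visible at
the default ranks) the nonparametric percentiles at n = 10,000 are integer
order statistics pinned by the Poisson CDF — 0, 1, 2, 3, 5 at the five
default ranks — while the parametric 2.5th percentile is ≈ μ − 2σ ≈ −0.83,
negative although the sample minimum is 0.

Two facts about the tail gap deserve emphasis, because they are tested:
the |parametric − nonparametric| divergence is larger at the extreme ranks
than at the median (the Gaussian approximation fails in the tails first),
and the gap does **not** close as n grows — averaged over seeds it changes
by only a few percent between n = 98 and n = 10,000, because it is a
model-misfit bias, not sampling error. More data cannot rescue a wrong
distributional assumption; only the estimator change does.

## Stability (oscillation) analysis

To ask how many subjects a stable nonparametric atlas needs, the atlas is
rebuilt from growing prefixes of the cohort (sizes step, 2·step, …, n, in
cohort order, or one seeded shuffle recorded in the output) and compared to
the full-cohort atlas by **percent histogram similarity**: per rank, voxel
values of subset and full atlas are histogrammed on 64 shared bins spanning
the full atlas's pooled value range, normalised to unit mass, and
similarity = 100 · Σ min(h_subset, h_full); per-rank similarities are
averaged. The metric is symmetric, bounded in [0, 100], and 100 exactly at
the full size. The curve reports the minimal n crossing 95% and 99%.
Averaging per rank (rather than pooling ranks into one histogram) keeps a
drifting extreme rank from being masked by stable central ranks; this is a
design choice, and the metric is pluggable. The similarity numbers depend
on bin count and cohort; they characterise convergence, not a universal
subject-count requirement.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
MRI physics. A brain-like ellipsoid mask on a 32³ grid (2 mm isotropic
affine; defaults overridable) is split into four lobe-like quadrants plus a
small spherical hippocampus-like sublabel. Each region has a Beta(a, b)
voxel distribution; defaults are Beta(2,2) frontal (symmetric), Beta(4,2)
temporal and Beta(3,2) parietal (left-skewed), Beta(2,3) occipital
(right-skewed), and Beta(5, 1.5) hippocampus — strongly left-skewed and
leptokurtic, mirroring where real GM-proportion data deviate most from
Gaussian. The manifest records each region's parameters and the analytic
Beta moments they imply, enabling parameter-recovery tests of the moment
maps. The normal cohort defaults to n = 98 subjects — the size a normative
atlas of this kind is typically built from — and disease-like subjects
(default 10) are normal draws whose values in the affected labels (default
temporal + hippocampus) are multiplied by (1 − severity), severity ~
Uniform(0.2, 0.5) per subject, clamped to [0, 1], with the ground-truth
effect mask saved alongside.

Voxels are spatially independent across space by default (a Gaussian
smoothing option exists but is off): the method itself is voxel-wise, so
passing tests on independent voxels validates the estimators and the
pipeline, but says nothing about spatially correlated noise, registration
error, partial-volume structure, or age trends — none of which the
generator emulates. Results on real cohorts will differ in those respects.

All randomness flows from the spec's single seed through
`numpy.random.default_rng`; the disease subjects use a child seed sequence
so normal and atrophied sets are independent but jointly reproducible.
Identical spec + seed yields byte-identical volumes.

## Problem sizes

Tests run on 12³–16³ grids with cohorts of 40–500 subjects and finish in a
few seconds; the acceptance script's simulation uses n = 10,000 draws.
These sizes are where the checked properties (order-statistic exactness,
moment calibration at 10⁶ draws, concentration of injected atrophy) are
already decisive; larger grids change runtime, not conclusions, since all
computations are per-voxel.

## Known limitations

* The parametric method defines multipliers only for the five canonical
  ranks; other ranks use exact Gaussian quantiles and are flagged.
* Discordance category naming assumes the comparison pair is
  (parametric, nonparametric) in that order; other pairings are rejected.
* Nonparametric extreme percentiles at n = 98 rest on the 3rd-smallest/
  largest observations; they are sample values, not population limits.
* No covariate conditioning (age, sex) — atlases describe the cohort as
  given. No group-level diagnosis: the tool highlights voxels, it does not
  classify patients.
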