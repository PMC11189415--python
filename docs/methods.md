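# Methods

This note records the modelling assumptions, numerical conventions and open
design choices behind `anxrpt`, in the order the pipeline runs them.

## Exclusion filters

Four survey-quality rules mirror common vendor practice: straight-lining
(zero response variance within any declared question block; the STAI-S block
by default), ten or more self-reported clinician diagnoses, an education
level inconsistent with reported years of education (minimum-years table in
`survey_scores.EDU_MIN_YEARS`, shipped as editable config), and completion
in under 800 s (the boundary is strict: 799 s is excluded, 800 s retained;
a missing completion time is unevaluable and excluded). Rating-based
exclusions follow: a rating span ≤ 1 point across all 48 pictures, an
incomplete judgment profile (any of the 15 features undefined), or an
extreme outlier — |value − median| > 5·MAD on any judgment variable, the
multiplier being configurable because no canonical value exists. The rules
are mutually independent, so the retained set does not depend on the order
of application.

## STAI-S scoring

Items are scored 1–4, the ten reverse-keyed items of form Y-1
({1, 2, 5, 8, 10, 11, 15, 16, 19, 20}) mapped r → 5 − r, and summed to
20–80. The reverse key is a module constant so it can be corrected without
code changes. Records with missing or out-of-range items are rejected, not
imputed.

## RPT feature extraction

Zeros are neutral and belong to neither signed set. Entropy is computed over
rating magnitudes {1, 2, 3} in base 2 with 0·log 0 = 0, so H ∈ [0, log₂3];
the variance convention is population variance (a sample-variance flag
exists). An empty signed set yields an undefined tuple — flagged, never
fabricated.

Value limbs are fit as K = f(H) (an axis-swap would be a one-line change in
the fitting helpers); both the logarithmic and power families are fit by
least squares (the power fit via `scipy.optimize.curve_fit`, seeded from a
log–log linearization) and the family with the higher adjusted R² is kept,
ties favouring log. H = 0 points are excluded from these fits (ln undefined)
and recorded in the fit notes. A limb needs ≥ 3 usable points. Slope-sign
violations (a⁺ ≤ 0 or a⁻ ≥ 0) are flagged on the fit but the curvature and
intercept features are still evaluated; only LA, which divides by the
positive-limb steepness, becomes undefined when that steepness is not
positive. For the power family the characteristic steepness and curvature
are evaluated at H = 1 and at the participant's mean entropy respectively,
so the log- and power-family features are on the same scale.

The limit function is one concave quadratic fit jointly across both signs
(12 points); a per-limb variant was considered and rejected because the
tipping points are defined by roots straddling zero. α ≥ 0 or complex roots
leave the six limit features undefined. Peak risks take the supremum of the
fitted curve over the relevant half-interval, evaluating the open endpoint
at K = 0 — so a vertex inside the approach domain gives Peak PR = σ(vertex)
and Peak NR = σ(0). Total risks use the closed-form antiderivative (checked
against quadrature to 1e-9 in the tests).

The tradeoff function maps each category with both entropies defined to
r = √(H⁺² + H⁻²), θ = atan2(H⁻, H⁺) ∈ [0, π/2]; the four features are the
mean and range of θ and of r. At least two valid categories are required.

Curve-fit failures never raise; they mark the profile incomplete, and
incomplete profiles are removed by the exclusion stage.

## Classification

Thresholding is inclusive on the high side (score ≥ threshold → 'higher').
The 70:30 split is simple random sampling with a recorded seed — not
stratified, since nothing indicates stratification in the original design;
a stratified option exists. Both forest modes are built on CART trees with
5 candidate variables per split and 1000 trees by default. The balanced
mode draws, for every tree, the minority-class count from each class with
replacement; the per-tree drawn counts are retained so the balance contract
is assertable tree by tree. OOB accuracy aggregates each tree's votes on
its out-of-bag samples over the untouched training set; down-sampling never
touches evaluation. AUC uses the vote fraction for 'higher' (a hard-label
AUC would waste the forest's ranking information). Importance is the
R-convention mean decrease in Gini — per-node impurity decrease weighted by
node size, summed per feature, averaged over trees — normalized to shares
summing to 1. Proximities count shared terminal nodes over trees (O(n²)
memory, so callers should cap n) and feed classical metric MDS
(double-centering + eigendecomposition) on 1 − P.

## Mediation and moderation

Ordinary least squares throughout, via statsmodels. The Sobel statistic
uses the algebraic identity c − c′ = a·b (exact for these nested OLS fits;
asserted in tests) with a two-tailed normal reference. T_eff = 100·(1 −
c′/c) is undefined when c = 0 (verdict false with a reason). Ordinal
contextual variables enter as numeric codes, mirroring single-coefficient
treatment; a categorical-dummy alternative sits behind a flag. The partial
F-test for the single interaction term equals the squared t-test of β₃ —
kept as an explicit restricted-vs-full computation because that is the
stated procedure, with the equivalence asserted in tests. No
multiple-testing correction is applied across the 60 + 60 screens (raw
significance is reported); a Bonferroni option exists but defaults off.

## Post hoc tests

Two-level variables use the Wilcoxon rank-sum test, more levels
Kruskal–Wallis, both tie-corrected; years of education is excluded and age
enters as its 3-level bin (18–39 / 40–55 / 56+; only the 39/40 boundary is
anchored by the young-vs-older adult convention, the 55 cut is config).
Judgment variables are tested one-sidedly in both directions at each
threshold, with Bonferroni correction across the six tests per variable
(α = 0.05/6 ≈ 0.0083). The exact rank-sum distribution is used when a group
has fewer than 50 members, the tie-corrected normal approximation otherwise.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the content of the rating task. One latent trait z ~ N(0,1) drives
everything; all randomness flows from a single `numpy` generator seeded by
the spec, so equal seeds give bit-identical cohorts.

**STAI items** follow a cumulative-logit model with item-specific
thresholds; reverse-keyed items load negatively on z so their scored
contribution rises with z. The item slope (1.1 per unit `anxiety_effect`)
was set so that at effect 1.5 the rank correlation between z and the score
clears 0.5 by a wide margin, and a constant offset anchors the score
distribution so that 35/45/55 fall near the 50th/75th/90th percentiles —
the percentile anchors the thresholds are meant to have.

**Contextual gradients**: loneliness (5 levels by default; the level count
is a parameter because no canonical value exists) rises with z, age and
household income fall with z; other demographics are drawn from fixed
marginal frequencies approximating a general-population online panel
(predominantly female, married, white, employed full-time). Education years
are drawn consistent with the education level so clean participants pass
the consistency filter.

**Ratings** are built per category from magnitude distributions over
{1, 2, 3} that interpolate between a concentrated low anchor and a broad
high anchor; the interpolation weight varies across categories, so the six
(H, K) points trace a rising value limb while σ falls off with |K| — the
concave limit-curve shape the extraction assumes. Magnitude multisets are
allocated by largest-remainder rounding, so participant-level parameters
rather than small-sample noise dominate the fitted curves (with 8 ratings
per category, i.i.d. draws would swamp the 6-point fits and leave most
profiles unusable). Three shifts are planted with z: the positive limb's
high anchor weakens (raising LA = |a⁻|/a⁺, and with it lowering RA and
raising Ante — directions consistent with high-anxiety cohorts), the
negative limb weakens much more slowly (lowering LR without cancelling the
LA shift), and the cross-category spread of interpolation weights shrinks
(narrowing the tradeoff range). Lever strengths were calibrated once
against the extraction pipeline so all three directions are jointly
recoverable; they are deliberate study conditions, not free dials.

What the generator does **not** emulate: picture-level semantics, real
response-style heterogeneity (acquiescence, central tendency), missing-data
mechanisms beyond missing-completely-at-random, and the full contextual
correlation structure of a real panel. Passing tests therefore demonstrate
that the pipeline recovers planted structure of realistic size and shape —
not that the original study's effect sizes are correct.

**Invalid responders** are injected by rewriting a chosen fraction of
participants to violate one filter each (straight-line ratings, < 800 s
completion, ≥ 10 diagnoses, education mismatch, straight-line STAI
section), tagged in a ground-truth column so filter recovery is testable.

## Problem sizes

The acceptance script runs a 1200-participant cohort (≈ 900 after
exclusions) with 1000-tree forests at all three thresholds and both modes;
the permutation null uses 100 label shuffles with 100-tree forests, since
chance-level AUC is insensitive to forest size. The test suite uses
150–520-participant cohorts for unit-level checks and a 2000-participant
cohort for direction-recovery checks, sizes at which the planted effects
are comfortably detectable. A full pipeline run on 500 participants takes
a few seconds on one CPU.

## Known limitations

- The 15 judgment-variable formulas are operationalized from their verbal
  definitions (steepness ratio, curvature at mean entropy, unit-entropy
  intercepts); each is an injectable strategy so alternative
  operationalizations can be swapped in.
- The limit-curve features are undefined for participants whose quadratic
  is non-concave or lacks sign-straddling roots; in noisy data this is the
  dominant source of incomplete profiles.
- The mediation verdict's T_eff > 50% rule is scale-dependent through c;
  it is invariant to positive rescaling of Y (asserted in tests) but not to
  affine changes that flip the sign of c.
- Proximity matrices are dense; embedding more than a few thousand samples
  needs a cap or subsampling.
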