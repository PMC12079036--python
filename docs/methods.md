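# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Data model

A segment is a 5-second clip sampled at 10 frames/s (50 frames), each frame
mapping blendshape names to activations in [0, 1]. Frame time is derived
(`frame_index / fps`, 0-based) and never stored. Values are validated to
the closed interval; exact 0 and 1 are legal. All frames of a segment must
carry the same blendshape set.

**Segment aggregation.** A clip-level "smile event" is present if the
expression appears at any moment, so each channel is reduced to its
**maximum over frames** before thresholding. Under this choice,
thresholding per frame and then OR-ing over frames is mathematically
identical to thresholding the aggregate, so the order of the two steps is
immaterial. Mean or sustained-exceedance aggregates would weaken brief
smiles and are not used; the aggregation rule is the one genuinely open
design choice in the feature path and is isolated in `aggregate_segment`
for sensitivity analysis.

## Classifier

`BilateralClassifier` holds a (left, right) channel pair and one shared
threshold θ ∈ [0, 1]. The decision is `max(left, right) > θ` with **strict**
exceedance; boundary equality classifies negative. Strictness matters only
when a score coincides with a grid threshold; the convention is applied
uniformly in prediction and in the ROC sweep so the two never disagree.

## Threshold optimisation

* **Grid:** θ = 0.000 … 1.000 in steps of 0.001, both endpoints included
  (1001 thresholds).
* **ROC:** TPR(θ) and FPR(θ) are exceedance proportions over the positive
  and negative class respectively; both are non-increasing in θ.
* **AUC:** trapezoidal integral of the piecewise-linear curve through the
  unique (FPR, TPR) points sorted by FPR then TPR and anchored at (0, 0)
  and (1, 1). The integral is evaluated on the underlying integer
  exceedance counts, so the numerator is exact: a perfectly separating
  score set yields AUC = 1.0 exactly, and for tie-free scores the value
  equals the Mann–Whitney pairwise concordance probability (property-tested
  to 1e-9).
* **Operating point:** θ* maximises Youden's J = TPR − FPR; among tied
  maximisers the **smallest** grid threshold is returned, which maximises
  sensitivity at equal J and makes the rule deterministic. With class-
  separated training scores this places θ* at the smallest grid point at or
  above the highest negative score, i.e. at the lower edge of the empirical
  amplitude gap.

## Train/test split

`stratified_split` halves the data within each (participant × label)
stratum: ids are shuffled by the seeded generator and assigned alternately.
The half receiving the surplus element of an odd-sized stratum alternates
from one odd stratum to the next, with the starting side drawn once from
the generator. Since an even total implies an even number of odd strata,
an even-sized dataset (e.g. 158 segments) always splits exactly in half
(79/79) while per-stratum imbalance stays ≤ 1. Train/test overlap is
impossible by construction and re-checked at evaluation time.

## Agreement statistics

**Fleiss' κ** (r raters, n items, binary categories):
P_i = (Σ_j n_ij² − r)/(r(r−1)), P̄ its mean, P̄ₑ = Σ_j p_j², and
κ_F = (P̄ − P̄ₑ)/(1 − P̄ₑ). The standard error is the Fleiss–Nee–Landis
large-sample variance of overall kappa,

    var(κ_F) = 2 [ (Σ p_j q_j)² − Σ p_j q_j (q_j − p_j) ]
               / [ n r (r−1) (Σ p_j q_j)² ],

used both for the Wald 95% CI and the one-sided z-test of κ = 0. The CI is
**not truncated at 1**, mirroring the untruncated-Wald convention used for
Cohen's κ below. When every rating in the whole matrix falls in one
category, P̄ₑ = 1 and the coefficient is undefined: the code raises
`UndefinedStatisticError` rather than returning NaN.

**Cohen's κ** is computed from the 2×2 confusion matrix: p₀ = (TP+TN)/n,
pₑ = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)]/n², κ_C = (p₀ − pₑ)/(1 − pₑ). The
CI uses SE = √(p₀(1−p₀)/(n(1−pₑ)²)); with the benchmark counts
(TP=27, FP=2, FN=1, TN=49) this reproduces κ = 0.9177 and
CI [0.8263, 1.0090] exactly, which is why this SE variant (among the
several in the literature) is the one frozen here. The p-value is a
one-sided z-test with null SE₀ = √(pₑ/(n(1−pₑ))); at the benchmark counts
z ≈ 7.5, so the sidedness is immaterial to "p < 0.001".

**Majority vote** requires > r/2 agreeing raters; with an even panel a tie
raises unless an explicit tie label is configured. Disagreement count is
the number of non-unanimous rows.

## Synthetic-data generator

The generator emulates the *structure* of a smile-annotation study, not
facial dynamics. Defaults (units in brackets):

| parameter | default | meaning |
|---|---|---|
| n_segments | 158 | clips per dataset |
| duration_s × fps | 5 s × 10 fps | 50 frames per clip |
| n_participants | 9 | round-robin assignment |
| p_smile | 0.354 | per-clip Bernoulli smile probability |
| smile_amplitude | (0.60, 0.95) | mouthSmile peak range, smile clips |
| neutral_amplitude | (0.00, 0.30) | mouthSmile range, neutral clips |
| asymmetry_prob | 0.2 | smile expresses on one side only |
| jitter_sd | 0.02 | frame-level Gaussian jitter |
| cheek_attenuation | 0.42 | cheekSquint = 0.42 · mouthSmile + noise |
| cheek_noise_sd | 0.16 | cheekSquint frame noise |
| n_raters / flip_prob | 5 / 0.016 | independent per-rater label flips |

Smile clips carry a trapezoidal pulse (0.5 s rise, ≥ 1 s plateau, 0.5 s
fall, onset and plateau length drawn uniformly) with per-side peaks from
the smile range; after jitter the plateau is clipped back into the smile
range, so the disjointness of the two amplitude ranges — and hence perfect
separability of the mouthSmile peak feature — holds for every seed, not
just in expectation. The prevalence 0.354 extrapolates a 28-positive /
79-segment test-half composition to the whole dataset and is configurable.

The cheekSquint channels are attenuated, noisier copies of the same event:
informative but imperfect. Attenuation 0.42 with noise sd 0.16 was fixed
once by a Monte-Carlo sweep so that a cheekSquint-only classifier attains a
mean training AUC ≈ 0.966 (spread roughly 0.93–0.99 across seeds), placing
it clearly below the perfect mouthSmile classifier.

Rater errors are independent across raters and segments. With flip
probability ε, pairwise agreement is 1 − 2ε(1−ε) and the expected Fleiss'
κ ≈ 1 − 2ε(1−ε)/(1 − P̄ₑ); at ε = 0.016 and prevalence 0.354 this gives
κ ≈ 0.93, and the Monte-Carlo mean over 200 seeded panels lies within
±0.05 of 0.91 (asserted in the acceptance suite). A majority of five then
overturns the truth only when ≥ 3 raters err on one clip, so the consensus
rarely differs from the generator's ground truth.

**What passing tests do and do not show.** The generator's clips are
clean: disjoint amplitude ranges, no occlusions, no head-pose artifacts,
no borderline expressions, and rater errors independent of clip content.
Perfect training AUC and perfect test metrics on simulator defaults
therefore validate the *machinery* (feature path, sweep, split,
statistics), not the difficulty of real video; on real recordings the
amplitude ranges overlap and all downstream numbers degrade accordingly.

## Numerical and degenerate-input conventions

* AUC numerators in integer arithmetic (exact); all other statistics in
  double precision.
* Youden tie-break: smallest threshold. All-equal scores give J ≡ 0 and
  return θ = 0.
* Single-class truth in an ROC, empty confusion margins in
  sensitivity/specificity, and pₑ = 1 in either kappa raise
  `UndefinedStatisticError` / `ValidationError` rather than returning NaN.
* Frames CSV round-trips byte-identically at 6-decimal precision; the
  run-all report derives every stage seed from one `SeedSequence`, so a
  repeated run with the same seed is byte-identical.

## Problem sizes

Default analyses run at the full study geometry (158 segments × 50 frames,
5 raters). The repeated-seed checks in the acceptance suite use 100 seeds
(threshold recovery, split integrity) and 200 seeds (rater-panel
calibration, AUC/concordance equivalence), which complete in well under a
minute each on one CPU.

## Known limitations

* Binary categories only; no weighted kappa, no > 2-category panels.
* One bilateral pair per classifier; no multi-AU fusion and no temporal
  localisation of the smile within a clip.
* The Fleiss CI formula choice cannot be checked against the benchmark
  study (its rating matrix is unpublished); it is documented, not
  calibrated.
* The trained threshold and training AUCs depend on the training data and
  are reproducible only in distribution, via the simulator.
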