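# Methods

This note documents the models, estimators and numerical choices behind
`phonovib`, what the synthetic generator does and does not emulate, and the
known limitations.

## Synthetic vocal-fold oscillation model

Each fold's contour displacement is

    D_s(p, t) = A_{s,k} · g(p) · f(φ(t) − τ_s; edges_s(p)),    s ∈ {L, R}

* `φ(t)` is a continuous cycle coordinate advancing by one per cycle, with
  per-cycle periods `T_k = T₀ (1 + η_k)`, `η_k ~ N(0, σ_T²)` i.i.d.
* `A_k = exp(ε_k)`, `ε_k ~ N(0, σ_A²)` i.i.d., common to both folds; the
  right fold carries an additional constant amplitude ratio.
* `g(p) = sin(π (p + ½)/P)` is a half-sine spatial envelope (maximum at
  mid-fold, near-zero at the tips).
* `f` is a trapezoidal pulse: closed phase, linear rise, plateau, linear
  fall. The rise/flat/fall proportions are solved from the open quotient
  (default 0.6), the speed-quotient target SQ = closing/opening (default
  1.2) and the plateau-fraction target PQ (default 0.25), so that the
  90%-of-peak landmarks of the rendered pulse reproduce those targets
  exactly. Plateau fractions below 0.1 degenerate to a triangle (a linear
  rise/fall alone spends 10% of its ramps above the 90% level).
* The open-phase onset/offset at position `p` shift by
  `τ_open·h(p)` / `τ_close·h(p)` cycle fractions, with
  `h(p) = |p − mid| / (P/2)`. This produces the anterior–posterior
  "zipper" pattern; the contour angles respond monotonically to the
  delays, with τ = 0 giving exactly 90°.
* The right fold's phase is shifted by the left–right phase shift (cycle
  fractions, right minus left).

**Perturbation calibration.** For i.i.d. `N(0, σ²)` values,
`E|X_k − X_{k−1}| = 2σ/√π`. Hence

    σ_T = (Jit%/100) · √π / 2          (period, linear scale)
    σ_A = MShim · √π · ln 10 / 40      (log-amplitude scale)

The lognormal amplitude form makes the dB-shimmer relation exact, not just
first-order; the period stays linear because Jit(%) is defined on the
linear scale. Pulses start at the cycle boundary (onset at phase 0), so
intervals between successive pulse onsets equal the generated period
sequence exactly. This matters: a landmark at interior cycle phase `a`
measures `(1−a)T_k + aT_{k+1}`, shrinking measured jitter by the factor
`√(1 − 3a(1−a))` — placing the landmark at `a = 0` removes the bias.

**Noise.** Broadband white Gaussian noise is added to the two partial
GAWs (not to the displacement matrices — the harmonics-to-noise ratio is a
property of the GAW spectrum, and segmentation noise manifests there),
with variance calibrated so the expected clean-AC-energy to noise-energy
ratio of the total GAW equals the dB target. Noisy GAWs may dip slightly
below zero; clipping is avoided deliberately, because rectifying the noise
in the closed phase would both remove ~half its energy there and add a
periodic mean component that masquerades as harmonic energy, biasing the
calibration.

**What the generator does not emulate.** Real segmentation noise is
spatially and temporally correlated, not white; perturbations in
pathological voices need not be i.i.d. Gaussian; the spatial envelope and
pulse shape are stylized; there is no vocal-tract acoustics and no
biomechanical (mass–spring) model. Passing recovery tests therefore shows
estimator correctness under the model's assumptions, not clinical
validity on real recordings.

## Cycle detection

Maximum- (or minimum-)based cycles are local extrema of the total GAW with
prominence ≥ 0.10 × signal range (the "sufficiently distinct" rule;
configurable) and spacing constrained from below. Because broadband noise
creates spurious prominent extrema between true pulses, the minimum
spacing is derived from a coarse spectral period estimate (spectral
argmax in the plausible 50–1000 Hz band with a subharmonic check), not
from the f0 upper bound alone. Boundaries are integer frame indices;
cycles are half-open `[start, next_start)`; the trailing partial cycle is
discarded; detection is invariant to affine rescaling of the signal.

## Sub-frame landmarks

At 4000 frames/s a cycle spans 13–40 frames, so integer landmarks quantize
|ΔT| by ~0.3–0.5 frames — enough to inflate Jit(%) by 10–20% at clinical
levels. The per-cycle series therefore uses interpolated landmarks:

* **period**: the pulse onset, extrapolated from the 20%- and 60%-of-peak
  crossings of the rising edge down to the baseline (exact for a linear
  edge); periods are onset differences;
* **durations**: opening = baseline→90% (rising), plateau = the ≥90% span,
  closing = 90%→baseline (falling), all via linear interpolation between
  samples; SQ = closing/opening (note: much literature uses the inverse
  convention), PQ = plateau/open duration, OQ = open duration/period;
* **peak instant** (for phase shifts): midpoint of the ≥90% span, robust
  for plateau-topped pulses where the sample argmax is arbitrary;
* **amplitude**: the value at the cycle's defining peak. The max over a
  peak-to-peak window also sees the rise toward the *next* peak, which
  correlates consecutive amplitudes and halves measured shimmer.

`cycle_series(..., refine=False)` reverts periods to integer boundary
spacing for comparison.

## Harmonics-to-noise ratio (SNR_K)

The signal is truncated to the detected-cycle span, mean-removed, Hann
windowed and transformed. Harmonic energy is the energy in main-lobe
(±2 bin) bands around k·F0 (k = 1..8, below Nyquist), where the
fundamental bin is located by spectral argmax in the plausible-period
range with parabolic sub-bin refinement, and the broadband noise floor
under the bands (estimated from the non-harmonic bins) is subtracted.
The value is `10 log₁₀(E_harm/(E_total − E_harm))`, capped at ±60 dB.
The registry's `SNR_K [Mean]` uses the full segment; `SNR_K [Std]` is the
spread over 16-cycle blocks (NaN below 32 cycles).

Two properties to be aware of:

* on noise injected into a strictly periodic signal, the estimator is
  unbiased to within ~0.1 dB (the acceptance test recovers an 11.2 dB
  injection within ±0.5 dB over 50 recordings);
* cycle-to-cycle jitter broadens the harmonic lines, moving energy out of
  the bands: at 1.5% jitter a 15 dB noise injection reads ≈ 13 dB. This
  is not an estimator defect — a harmonics-to-total-energy measure
  genuinely conflates aperiodicity with additive noise, which is exactly
  why it discriminates irregular voices.

Similarly, additive noise inflates the perturbation measures (landmark
crossings are noise-corrupted), and left–right timing asymmetries smear
the summed waveform's edges, biasing jitter slightly low; tight recovery
holds for the low-noise, symmetric case.

## Registry

Exactly 91 parameters: 41 from GAW_T, 18 left–right symmetry, 32 PVG.
Only the four phase-shift entries (PhA/PhAI mean/std) use minimum-based
cycles — peaks must be interior to the analysis window. Perturbation
families follow the standard voice-perturbation literature: k-point
quotients `100·mean|X − MA_k(X)|/mean X` (k = 3, 5, 11; k-point members
need ≥ k+1 cycles, else not-a-value), MShim `mean|20 log₁₀(A_{k+1}/A_k)|`,
perturbation factors `100·mean(|ΔX|/X_{k−1})`. RAP_K and PPQ3 coincide by
definition (as in the literature); both sit in the jitter redundancy
group. Exact definitions not fixed by any published formula table are
marked `source='reconstruction'` in the registry and isolated there so a
definition can be corrected without touching code. Sample statistics use
ddof = 1 throughout.

## Phonovibrogram contour angles

Within each pulse-aligned cycle window, the opening onset (closing
offset) per contour position is the first (last) of three consecutive
frames above `eps_frac = 0.05` × that position's own maximum displacement;
positions below 2% of the fold maximum are absent. The per-position
threshold makes the 90° anchor exact: a front that opens simultaneously
along the fold crosses simultaneously regardless of the spatial amplitude
envelope. For each fold half (anterior = indices ≥ P/2, the midpoint
assigned anterior) the edge front is fit by least squares against
`u = |p − mid|/(P/2)` (≥ 3 valid positions required), and

    angle = atan2(Δu, Δt_tip→mid) in degrees,

with time in cycle fractions. Zero time spread gives exactly 90°; a tip
leading by a quarter cycle gives `atan2(1, 0.25) ≈ 75.96°`. CAS = CA_L/CA_R
(signed ratio) and CASI = min/max (bounded index), per phase-region, with
means/stds over cycles. The normalization is a fixed convention chosen so
that typical clinical magnitudes (80–110°, CAS ≈ 1, CASI ≈ 0.9) are
representable; whether the original tooling fits by least squares or
two-point extremes is not published, so least squares was chosen for
noise robustness.

## Redundancy pruning and age screen

Pairwise Pearson correlations are pooled over all subjects (no group
split); constant columns are flagged and excluded. The |r| ≥ 0.9 graph
("very high" by the usual interpretation scale) is partitioned into
connected components, and within each component redundancy groups form by
greedy cover around representatives — the first member of the priority
list (MShim, Jit(%), EPF, PhAI[Mean], AmSI[Std], PhAI[Std], SpAI[Std],
CASI^CA[Std]), else the most central member. Greedy cover (rather than
one representative per component) guarantees the ledger invariant that
every discarded parameter correlates at |r| ≥ 0.9 with the representative
kept in its place, even when a component contains a correlation chain.
Three manual removals (TP[Std]→F0[Std], DyRS[Mean]→AmS[Mean],
DyRSI[Mean]→AmSI[Mean]) cover pairs known to be redundant in clinical
data while correlating just below threshold; they are applied by name,
not by lowering the threshold. Pruning is idempotent.

The age screen reports, per parameter, Pearson r against subject age, the
two-sided p-value, a Fisher-z 95% CI (clamped to contain r in the
degenerate |r| → 1 case), and a negligible flag at |r| ≤ 0.3. It is
advisory: nothing is removed.

## Boosted stumps

All three algorithms share an exhaustive stump search over every feature
and every midpoint of adjacent distinct values, with ties broken to the
lowest feature index, then the lowest threshold (bit-reproducible).
Class imbalance is absorbed by uniform-prior observation weights
`1/(2·n_class)`.

* **AdaBoost** (discrete): stump minimizes weighted misclassification;
  stage weight `α = lr · ½ ln((1−err)/err)`; training stops early if no
  stump beats chance.
* **LogitBoost**: Newton steps on the binomial deviance; working response
  `z = (y* − p)/(p(1−p))` clipped to ±4, weights `p(1−p)` (times the
  prior weights), probabilities clipped to [1e−10, 1−1e−10], stage
  contribution `lr · ½ · stump`. The training log-loss is monotonically
  non-increasing (tested).
* **RUSBoost**: AdaBoost whose per-round stump is fit on a seeded random
  undersample of the majority class down to minority size; the error and
  weight update use the full sample. Under balanced classes it behaves
  like AdaBoost in expectation (tested within 0.05 AUC).

Feature importance is the per-feature sum of split-gain records (criterion
reduction versus the no-split root) divided by the number of stumps,
reported max-normalized — the mean-risk-change measure that per-feature
importance conventions in tree-ensemble tooling use, restricted to
depth-1 trees. Evaluation uses repeated stratified k-fold CV with fresh
seeded partitions per repeat; AUC is computed per test fold by the
Mann–Whitney rank formulation (fold-averaged, since pooling versus
averaging is an open choice and averaging matches per-partition
reporting); ACC/sensitivity/specificity use score threshold 0, i.e.
probability ½ under the uniform prior, with sensitivity = disordered
correctly identified.

One estimator-granularity effect worth knowing: a stump ensemble on a
single feature produces a step-function score, so test points beyond the
outermost training threshold tie, and tie-averaged AUC can sit visibly
below 1 even for well-separated classes. Adding features breaks ties and
can nudge fold-averaged AUC up by chance; selection tests on constructed
cohorts therefore use group separations large enough (≈5 within-group SDs)
that class overlap — not tie behavior — is negligible, because what they
test is the selection rule, not the classifier's resolution of
overlapping classes.

## Selection pipeline

The protocol's visual "knee" choices are formalized as explicit tolerance
rules: the ensemble-size sweep picks the smallest size within 0.005 AUC of
the curve maximum; stepwise selection ranks parameters by feature
importance from a full-feature fit and picks the smallest nested model
within 0.005 AUC of the best; the combination step evaluates the union,
each sex's set, the PVG-only and GAW-only members, user subsets and
optionally a greedy backward pass, and returns the smallest candidate
whose worst-sex AUC is within 0.01 of the best. Sexes are always modeled
separately. Every report is regenerable byte-for-byte from the config and
its seeds.

## Cohort feature sampler

`sample_feature_table` draws subject-level tables for the 12
final-subset parameters from per-group Gaussian marginals (the published
group means/SDs for healthy/dysphonic female/male cohorts), clipped to
registry domains (symmetry indices to [0, 1.5], Std-type parameters at 0,
phase shift to [−0.5, 0.5]). Only marginal statistics are published, so
parameters are sampled independently — a documented limitation: real
parameter correlations (and hence realistic pruning behavior on these 12
columns) are not emulated. Synthetic ages are uniform, 20–40 years for
healthy and 25–65 for disordered groups, mimicking the usual clinical age
imbalance without modeling it.

## Problem sizes

Default test and acceptance runs use desk-scale sizes chosen as the
smallest that make the statistical checks stable: 100-recording cohorts
with 200 cycles per recording for redundancy and recovery (50 seeds for
mean-recovery checks), 60-subject tables with 5-fold × 2-repeat CV and
60-stump ensembles for the pipeline. All sizes are configurable upward.
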