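# Methods

## The analysis problem

The package targets case/control gait studies in which a depth sensor
records the 3D positions of 25 skeletal joints at 30 Hz while each
participant walks naturally back and forth for about two minutes on a
~6 m path. The scientific questions are (a) how much case/control
variance each family of gait features explains, and (b) how well those
features support diagnostic classification. The pipeline is organized
around one analysis unit per participant: a low-pass-filtered,
spine-relative excerpt spanning exactly two gait cycles taken from the
middle face-toward pass of the walk.

## Preprocessing model

**Coordinate transform.** All joints are re-expressed relative to the
per-frame spine-joint position, removing whole-body translation. The
sensor-frame spine Z track is retained alongside the transformed data:
it is the only place walking speed remains measurable, since the spine is
identically at the origin afterwards.

**Pass splitting.** With the sensor's axis convention (X left, Y up,
Z outward), walking toward the sensor strictly decreases spine Z. Passes
are maximal runs of the sign of the smoothed spine-Z velocity (uniform
smoothing over ~1/3 s before differencing); runs shorter than a minimum
pass duration (default 1.0 s — the splitting rule and threshold are this
package's own operationalization, since only the face-toward/back-toward
dichotomy is standard) are merged into their longer neighbor. Of k
face-toward passes the ⌈k/2⌉-th is analyzed; for even k the earlier of
the two central passes is taken, for determinism.

**Gait-cycle segmentation.** A gait cycle starts at left-foot toe-off,
operationalized as a local minimum of the Gaussian-filtered left-toe
height followed by a rise (checked 0.2 s later), with a 0.5 s refractory
period and a prominence threshold of 25% of the trajectory's range to
reject residual noise wiggles. The segment runs from the first to the
third of the three consecutive toe-off events nearest the middle of the
selected pass, so it contains exactly two cycles.

**Filtering.** Every one of the 75 joint-axis channels is convolved with
the fixed binomial kernel (1/16)[1, 4, 6, 4, 1] (unit DC gain; ~1.6%
attenuation at a typical 0.85 Hz cadence, ~50% at 7.5 Hz). Boundaries use
edge replication, which preserves DC gain at the segment ends; the
boundary policy is configurable. Toe-off detection runs on a filtered
copy of the left-toe channel, while the stored segment is filtered once,
after cropping — this avoids double filtering while keeping detection
smooth.

## Feature banks

* **Spatiotemporal (10)** — per cycle, then averaged over the two cycles:
  body sway (max |x_shoulderL − x_shoulderR|), left/right arm swing
  (peak-to-peak wrist Z), vertical head movement (peak-to-peak head Y),
  head posture (mean angle between the vertical and the neck→clavicle
  line in the Y–Z plane, radians; degree conversion available), left/right
  stride (peak-to-peak foot Z), left/right toe clearance, walking speed
  (|Δ sensor spine Z| / elapsed time, m/s).
  Toe clearance is implemented as the *maximum spine-relative foot
  height* — a negative number around −0.7 m, matching the published
  summary table's sign, which is impossible for a "maximum change"
  reading; a peak-to-peak mode is provided for the literal reading.
  Stride uses the Z axis alone (not the X–Z norm).
* **Time-domain (300)** — sample mean, SD (n−1 denominator), skewness
  g₁ = m₃/m₂^1.5 and excess kurtosis g₂ = m₄/m₂² − 3 (central moments
  with 1/n) of each channel. Zero-variance and numerically degenerate
  (near-constant) channels define skewness and kurtosis as 0, which keeps
  every bank finite on synthetic data whose spine channel is exactly
  constant.
* **Frequency-domain (825)** — per channel, from the full DFT: the DC
  component F₀/n (the signal mean) plus mean, variance, SD, skewness and
  kurtosis of the amplitude sequence |F_k| and of the principal-value
  phase sequence arg F_k ∈ (−π, π], k = 1..n−1 (two-sided spectrum,
  matching the transform's stated index range). Both variance and SD are
  included deliberately. Phases of near-zero-amplitude bins are included
  by default; a configurable amplitude floor can exclude them.

## Synthetic cohort generator

The generator is the package's test bed, not a biomechanical simulator.
A participant is a canonical standing skeleton carried by a spine
trajectory that runs a constant-speed triangle wave in sensor Z (toward
passes decreasing), with sinusoidal oscillators at the cadence
1/cycle-duration: antiphase left/right wrist-Z arm swing, antiphase
foot-Z strides, a foot-lift oscillation whose spine-relative maximum is
the (negative) toe clearance, a head bob, and a constant neck tilt equal
to the head-posture angle. Sensor imperfections are white Gaussian noise
(SD 5 mm) and a 12 Hz jitter component (3 mm) on every channel,
magnitudes chosen to match typical consumer depth-sensor joint noise.

Per-participant parameters are drawn from truncated normals whose group
means/SDs default to the published case/control spatiotemporal table
(e.g. left-arm swing 0.27 ± 0.11 m cases vs 0.31 ± 0.12 m controls; head
posture 1.23 ± 0.10 vs 1.27 ± 0.06, treated as radians — the published
unit label is ambiguous). Cycle duration is sampled at 1.185 ± 0.13 s
(half the published two-cycle segment statistics) truncated to
[0.95, 1.55] s so measured two-cycle segments stay inside the published
1.73–3.43 s range even at the extremes of timing variability.

Three *waveform-shape latents* differ by group and carry the
signal-domain separability (they can be disabled with
`shape_effects=False`):

* `harmonic_ratio` (cases 0.22 ± 0.08, controls 0.10 ± 0.08) — cos-phase
  second-harmonic distortion of the arm oscillators, renormalized to
  preserve peak-to-peak amplitude; it skews the waveform's sample
  distribution and adds a second spectral line.
* `asymmetry` (0.18 ± 0.10 vs 0.06 ± 0.10) — the same distortion applied
  to the leg oscillators.
* `tempo_variability` (0.30 ± 0.06 vs 0.06 ± 0.06 rad) — slow phase
  modulation of the shared gait clock at 0.3 Hz, emulating the elevated
  stride-time variability of depressed gait; it spreads spectral lines
  (a frequency-domain signature) while leaving sample moments nearly
  unchanged.

The magnitudes were calibrated once so that, on default cohorts, the
signal-level banks are strictly more informative than the stride-level
bank and the time+frequency combination is at least as good as either
alone — the qualitative ordering the pipeline is designed to expose —
and then frozen. What passing tests on this cohort establish is that the
*pipeline* (segmentation, features, inference, classification) behaves
correctly and preserves known group structure; they establish nothing
about real patients. The generator omits, among other things: turning
dynamics at path ends, occlusion and tracking dropouts, double-support
foot kinematics, posture drift, and any correlation structure between
kinematic parameters.

## Inference

Group comparisons are pooled-variance two-sample t-tests
(df = n₁ + n₂ − 2). The signal banks are z-scored per feature
(zero-variance features dropped with a warning) and reduced by PCA,
keeping the smallest component count whose cumulative explained variance
reaches 95%; component signs are fixed by making each component's
largest-magnitude loading positive.

Stepwise forward logistic regression adds, at each step, the candidate
with the smallest likelihood-ratio p-value, while that p-value is below
α = 0.05, refitting after each entry (Wald entry is available by
configuration). Fitting is Newton–Raphson to tolerance 1e−8 (≤100
iterations); perfect separation falls back to a lightly ridge-penalized
fit, flagged in the result. The final model reports per-term β, SE,
Wald = (β/SE)², OR = exp(β), raw Wald p-values, and Holm-corrected
p-values over the final model's terms (Bonferroni optional) — selection
operates on raw p-values, with correction applied post hoc for
reporting, since that is the only reading under which reported models
can retain terms with corrected p > 0.05. Nagelkerke's
R² = [1 − exp(2(ll₀ − ll₁)/n)] / [1 − exp(2·ll₀/n)] is clipped to [0, 1].

A known behavior worth stating: with ~100+ principal-component
candidates at n ≈ 250, forward selection at α = 0.05 performs no
multiplicity control over candidates and will overfit toward separation
when the latent group signal is strong; on default synthetic cohorts the
signal-bank Nagelkerke R² therefore approaches 100%, whereas the
stride-level bank stays near 15–20%. Only the ordering between banks is
meaningful.

## Classification

The classifier is a linear-kernel SVM (C = 1.0 by default) inside a
pipeline that z-scores features using training-fold statistics only.
Evaluation is stratified 10-fold cross-validation with sensitivity
(recall of cases), specificity (recall of controls) and per-fold AUC from
decision scores (midrank ties), averaged across folds; ROC points for
plotting come from pooled out-of-fold scores. All seven nonempty
feature-bank combinations share one fold assignment for comparability.

Sequential backward selection starts from the full feature set and
greedily removes the feature whose removal maximizes mean CV accuracy,
accepting a removal only if the evaluator does not drop (ties favor the
smaller set). SBS runs once on the pooled data by default (a nested,
per-fold variant is the obvious extension); because it costs O(p²)
CV-SVM fits it is practical only for small feature sets, and the
full-bank pipeline runs default to no selection.

## Numerical and degenerate-input policies

* Filter requires ≥5 samples; segments require ≥3 toe-off events, else a
  segmentation error naming the cause.
* Moment statistics require ≥4 samples; zero-variance series → (mean, 0,
  0, 0).
* t-test with both SDs zero: t = 0 for equal means.
* PCA retention index found on cumulative ratios with a 1e−12 guard
  against ties at the threshold.
* Stepwise selection is fully deterministic given its input; cohort
  generation, noise, and fold shuffling all derive from one integer seed.

## Problem sizes

Tests and the acceptance script run the full default cohort (247
participants, 120 s recordings) once for the distribution-level checks —
about a minute of compute — and reduced cohorts (24–120 participants,
40–60 s walks) for mechanism-level checks, which keeps the whole suite
within a few minutes while exercising every stage at full scale at least
once.
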