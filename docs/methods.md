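# Methods

## Problem setting

Wrist-worn accelerometers can monitor upper-limb function passively during
daily life. In Huntington's disease the informative unit is the
goal-directed movement (GDM) — a reach/grasp-like segment — whose
kinematics degrade with disease severity: movements become slower, more
jerky (chorea and overshoot flip the sign of acceleration more often), and
sustained long movements become rarer. gdmkin implements the full analysis
chain for such data and, because no public recording set exists for this
population, ships a simulator that produces labelled cohorts with exactly
the statistical structure the analysis is designed to detect.

## Simulator

**Movement kernel.** A GDM of duration T ≤ 3 s is a minimum-jerk
point-to-point reach along a random 3-D direction: position
x(τ) = D(10τ³ − 15τ⁴ + 6τ⁵), τ = t/T, so acceleration is
(D/T²)(60τ − 180τ² + 120τ³) with a single interior zero crossing. Longer
GDMs are chains of 1–3 s sub-reaches, each with its own direction and an
amplitude proportional to its duration, which keeps peak speed roughly
constant along the chain and — importantly — keeps the velocity spectrum
above the pipeline's 0.1 Hz high-pass edge. (Modelling a 15 s GDM as one
slow reach would put its velocity content below 0.1 Hz and the
preprocessing itself would erase the group contrast; sustained real
movements are likewise composed of sub-movements.)

**Severity couplings.** A latent severity s ∈ [0, 1] (0 = healthy) drives
every contrast, with defaults:

| parameter | default | role |
| --- | --- | --- |
| reach amplitude | 0.4 · (1 − 0.5 s) m | lowers peak/median velocity with severity |
| jerk noise RMS | 0.12 · s m/s², band 2–10 Hz | chorea/tremor surrogate; inflates zero-crossings |
| GDM rate | 100 − 10 s per hour | daily totals near 1100–1200 per 12 h |
| long-GDM share | max(0.25 − 0.23 s, 0.02) | >7.5 s counts fall with severity (≈24 % → ≈9 %) |
| pause probability | 0.5 · max(0, s − 0.5) | mid-movement stillness in severe disease |

GDM durations come from a two-regime mixture (uniform 1–6 s short regime,
8–20 s long regime). The mixture is a modelling choice — nothing in the
published material constrains the duration distribution beyond the
threshold counts — so tests treat only threshold-count *directions* as
meaningful. Days interleave GDMs with low-amplitude idle noise
(0.02 m/s² RMS) and a 9.81 m/s² gravity vector whose orientation drifts at
~0.002 Hz, far below the high-pass edge. Group severity intervals default
to CTR ⊂ [0, 0.1], pHD ⊂ [0.1, 0.4], HD ⊂ [0.4, 1.0].

**Clinical scores.** Monotone maps with ordinal (rounded Gaussian) noise:
motor = 80 s^1.5 (anchored so the HD-group mean lands near the published
~46 and controls near ~1), TFC = 13 − 6.5 s^1.3, functional = 25 − 8 s^1.2,
and ten upper-limb items (finger tapping, pronate/supinate, rigidity,
dystonia, chorea × both limbs) each 4 s^1.2, clipped to their ranges.
UHDRS-UL is always the sum of the ten items, never set directly.

**Determinism.** A cohort is a function of its seed alone: each subject
draws from an independently spawned `SeedSequence`, so streams are
bit-identical across runs.

## Preprocessing

4th-order Butterworth band-pass 0.1–12 Hz applied forward–backward
(`sosfiltfilt`), so in-band components have zero phase lag and detected
boundaries stay aligned with labels; then decimation to 25 Hz (index
striding for integer ratios, polyphase otherwise — the 12 Hz cut-off is the
anti-alias guard); then cumulative trapezoidal integration to velocity and
a re-applied 0.1 Hz high-pass, since integration turns any residual
near-DC content into unbounded drift. The residual mean left by the filter
edge padding is subtracted so velocity is exactly zero-mean. Velocity is
reported in integral units of the filtered acceleration; absolute
magnitudes are device-convention dependent and are not comparable across
instruments — effect sizes are.

Edge handling: odd-symmetric padding with length capped at the signal
length; signals shorter than ~3 filter lengths are rejected. A 0.1 Hz
high-pass has a ~10 s time constant, so oracle tests that check amplitudes
use 120 s signals and measure their central third.

Wear compliance is worn-samples / expected-samples per day; when no wear
mask exists, non-wear is inferred as runs ≥ 30 min with per-axis rolling
SD below 0.01 m/s².

## Segmentation

Non-overlapping 3-s windows (stride = window length keeps daily counts
well-defined without de-duplication); a window is positive when ≥ 1.5 s of
it is GDM. Two interchangeable detectors: an oracle that reads the
simulator's ground-truth intervals, and an envelope heuristic (smoothed
acceleration magnitude over a threshold, default 0.05 m/s²). The study's
learned detector is intentionally not re-implemented — no architecture or
weights are published — but anything honouring the window contract can be
dropped in. Episodes are maximal runs of positive windows; with the
default grid durations are multiples of 3 s and the 4.5/7.5/…/16.5 s
thresholds fall strictly between multiples, so threshold counts are
unambiguous.

## Features

Computed per positive 3-s window by default (a config flag switches to
per-episode; the windowed variant is taken as primary because the window
is the detection unit). For each of velocity and acceleration magnitude:
min, median, max, RMS; Shannon entropy (nats) of a 128-bin fixed-range
histogram (caps 2.0 m/s² for acceleration, 0.5 integral units for
velocity, chosen from the simulator's dynamic range; out-of-range samples
land in the top bin). Zero-crossing features are per-axis, then averaged:
strict sign changes with zero samples attached to the preceding run (no
epsilon threshold), mean constant-sign run length in samples, and plug-in
Shannon entropy of the empirical run-length distribution with unit-sample
bins. Exact identities (count + 1 = runs; runs × mean length = window
samples) are enforced by tests.

Aggregation: daily median over windows (robust to outlier windows), then
unweighted mean across days; counts are summed within a day and averaged
across days. Days with zero GDM windows are excluded with a warning;
subjects with no valid day are dropped.

## Statistics

Student (pooled-variance) t-tests rather than Welch: back-computing from
the published effect sizes and group sizes (d = −1.01 at n = 16/16 gives
pooled-t p ≈ 0.0075 against a printed 0.008) shows the source used pooled
variance. Cohen's d uses the pooled SD and is computable from raw samples
or printed summaries; effects are always first-listed minus second-listed
group. (In the published table the pHD-vs-CTR column's signs appear
inverted relative to that convention for several rows; this package never
inverts.) FDR is Benjamini–Hochberg at α = 0.05 within each contrast.
Correlations against clinical scores are Spearman (the scores are
ordinal), with all groups pooled to span the full health spectrum.

## Models

Maximal-correlation selection keeps the k = 5 features with the largest
|Spearman ρ| against the target (class rank CTR=0 < pHD=1 < HD=2 for
classification), ties broken by feature name. Features are z-standardised
per training fold (elasticnet is scale-sensitive). Classifier: multinomial
logistic regression with elasticnet penalty (saga), l1_ratio 0.5; penalty
strength chosen from a small grid {0.01, 0.1, 1.0} by an inner stratified
CV on the training fold (the published work does not state its tuning
protocol; the grid is config-exposed and can be collapsed to a single
value). Regressor: linear elasticnet, same selection and tuning.
Evaluation is leave-one-subject-out with all of a subject's visits in its
test fold; selection, standardisation and tuning are re-run inside every
fold (leakage is checked by instrumentation in the tests).

A note on the permutation null: LOSO refitting under shuffled labels has a
known pessimistic bias (holding out a subject makes its class a training
minority), of order 1/n subjects. At ≥ 30 subjects the empirical null mean
balanced accuracy sits within 0.05 of the 1/3 chance level, which is what
the tests assert; the analytic chance level of a uniformly random
classifier is exactly 1/3.

## Test and fixture sizes

Module tests run on sub-minute fixtures (≤ 10 subjects, ≤ 1 h days). The
acceptance-level synthetic checks use study-like cohorts of 16 + 7 + 16
subjects with three 2-h days per subject at 50 Hz — large enough for
stable group means and LOSO evaluation while keeping the whole suite to a
few minutes. Effect-direction checks run on the default severity
intervals; model-recovery checks run on a deliberately well-separated
fixture (CTR [0, 0.05], pHD [0.2, 0.35], HD [0.55, 0.95]), since their
purpose is to show the pipeline preserves information, not to estimate
real-world accuracy.

## What passing tests do and do not show

The simulator emulates the *directions and couplings* the analysis
targets: slower, jerkier movement and fewer long GDMs with severity, and
monotone severity-score links. It does not emulate real daily-living
accelerometry — no walking, typing, or other confounding activity, no
gesture taxonomy, no device noise floor, no gyroscope — and its GDM
detector oracle sidesteps the hardest real-world problem (detection).
Passing recovery tests therefore validate the pipeline's correctness and
information flow, not clinical performance; published real-cohort numbers
(balanced accuracy 0.67, UHDRS-UL explained variance 0.60) are not
reproducible without the original recordings and are deliberately not
asserted anywhere.

## Known limitations

- The entropy features' absolute values depend on the histogram caps and
  bin count; only within-configuration comparisons are meaningful (the
  published near-constant velocity-entropy value is not matched by
  construction, only the feature's definition).
- The heuristic detector is a threshold rule tuned for the simulator's
  noise floor; on real data it would need re-thresholding or replacement
  by a learned model.
- Velocity magnitudes are in integral units; no attempt is made to match
  the published velocity scale, whose unit convention is not recoverable.
- Repeat visits are supported by the LOSO machinery but the simulator
  generates one visit per subject.
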