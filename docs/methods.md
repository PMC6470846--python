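# Methods

## Signal model and slicing

The sensor model is a body-worn tri-axial accelerometer sampling at
100 Hz over ±8 g with 10-bit resolution, plus a skin-temperature
channel.  Quantization is mid-tread uniform: 2^bits levels spanning
[−full_scale, +full_scale), 0 g exactly representable, clipping at the
extreme levels; quantization error is bounded by half a step
(≈ 7.8 mg at 10 bit/±8 g) and the operation is idempotent.  Temperature
may be sampled sparsely and is forward-filled to the 100 Hz grid — only
its per-slice minimum is ever used, so the fill scheme cannot change a
decision as long as it is monotone between true samples.

Streams are cut into non-overlapping one-minute slices of 6000 samples,
the unit of ground-truth labelling and of classification; a trailing
remainder is dropped.  Feature windows are placed relative to the
slice's UPV and may reach into neighbouring samples of the parent
recording, so a fall straddling a slice edge still gets full windows
unless the recording itself ends.

## Feature definitions and window conventions

All windows are half-open `[start, stop)` in sample indices; "500 ms"
is 50 samples.  Windows described as running "up to the UPV" include
the UPV sample as their last sample; the impact window spans 20 samples
either side of the UPV plus the UPV itself (41 samples).  Choices made
where the prose description is ambiguous:

* **t₁** is the *longest contiguous* run with RSS_ACC in
  [−0.125, +0.125] g inside the 500 ms pre-UPV window (a quiescent
  stretch best matches "duration of the pre-fall phase"); total in-band
  time is available via `t1_mode="total"`.
* **t₂** uses the *latest* upward crossing of +0.125 g within 200 ms
  before the UPV — the final ascent of the main peak.
* **t₃** is the width of the contiguous region *containing the UPV*
  where RSS_ACC > UPV/4, not the span between first and last global
  crossings.
* **μ_ACC1 / μ_ACC2** windows are 300 ms long and *start* 1.8 s before
  and 0.5 s after the UPV respectively.
* Variances are population variances (divide by N).
* UPV ties break to the earliest sample.

A window truncated by the stream edge yields NaN and a cleared validity
flag.  A window that exists but contains no qualifying crossing yields
a **valid zero**: the measurement was made and its result is zero.
This distinction matters for classification (below): falls whose
pre-fall phase fills the whole 500 ms t₁ window legitimately measure
t₁ = 0 and must remain classifiable; only genuinely unmeasurable
features veto an alarm.

The norm-fall template used for CONV_RSS is, by default, the UPV-aligned
pointwise mean of the training falls' RSS_ACC over ±400 ms, L2-normalized
(edge-truncated segments are zero-padded).  When no training falls
exist, a stylized parametric waveform — exponential free-fall trough
into a damped-oscillation impact spike — is substituted, and templates
can also be loaded from file.  The convolution runs on the raw RSS_ACC
trace of each slice with zero-padded boundaries.

## Classifier

Bands are the min/max of each active feature over training falls,
optionally widened symmetrically by a `margin` fraction of the band
width (default 0; a deployment convenience, not part of the core rule).
Bands are closed intervals.  The decision is the conjunction: worn
(T_min strictly above 27 °C) AND every active feature finite and inside
its band.  An invalid (NaN) feature value vetoes the alarm.  Presets:
the first-generation set {UPV, CONV_RSS, σ²_RSS3}; the second-generation
default {UPV, LPV, t₁, t₂, σ²_RSS1, σ²_RSS2, σ²_ACC1, σ²_ACC2, Δμ_ACC},
i.e. the Mann-Whitney-significant features minus CONV_RSS (excluded for
compute cost) with T_min serving as the gate rather than a band; the
full 15-feature set is available via `features="all"`.

Two properties follow directly from the construction and are asserted
in the tests: training sensitivity is 100% (every training fall is
inside bands built from its own min/max), and widening any band is
monotone — it can only convert non-fall decisions to fall, never the
reverse.

## Mann-Whitney feature selection

Each band feature is tested fall vs non-fall, two-sided, α = 0.05.
The null distribution is evaluated by exhaustive enumeration of all
splits of the pooled sample (tie-exact) when the number of splits is at
most 2·10⁵; by the exact no-ties distribution for moderate sizes
without ties; and by the tie-corrected normal approximation otherwise.
T_min is never tested (it gates, it does not band); CONV_RSS is tested
and reported but flagged as excluded from deployment.

## Simulator: what it emulates and what it does not

The generator exists so that the pipeline is testable end to end
without real sensor data.  It emulates, per the fall phenomenology the
detector targets:

* **ADL background**: gravity along a fixed orientation, walking bouts
  as 2 Hz oscillation (amplitude 0.15 g × intensity, with a 0.4 cross-
  axis component), occasional sit/stand transients (Hann bumps,
  0.3–0.6 s, keeping total magnitude ≤ 1.5 g), Gaussian sensor noise
  (default σ = 0.02 g per axis).
* **Falls** as three phases: exponential magnitude decay toward free
  fall (τ = 0.15 s) over the pre-fall phase; an impact spike whose first
  sample is exactly the configured peak magnitude, ringing down as a
  damped oscillation (τ = 40 ms, 12 Hz) while the orientation slerps to
  the post-fall posture; then lying still along the new orientation.
  Pre-fall + impact span the event duration, drawn from the 0.45–0.85 s
  envelope typical of falls.
* **Temperature** as a first-order approach (τ = 120 s) toward skin
  temperature (33 °C) while worn and ambient (22 °C) otherwise, so the
  27 °C wear gate separates the plateaus; recordings without an explicit
  wear schedule start mid-wear (no warm-up transient).

Default fall-parameter distributions — the simulated study conditions —
are: impact peak U(2.5, 5.0) g, event duration U(0.45, 0.85) s, pre-fall
fraction U(0.55, 0.75), post-fall tilt U(60°, 120°) at uniform azimuth.
Falls are spliced into the background with a 100 ms linear cross-fade
and placed in distinct interior minutes; the minute containing the
impact sample is labelled "fall".  All randomness flows from one seed;
identical configurations are bit-identical.

The waveforms are stylized kinematics, **not** biomechanics: real falls
show far larger inter-individual variability in impact shape, multiple
impacts, protective responses, and soft falls that barely exceed ADL
magnitudes.  Passing pipeline tests on this generator therefore shows
that the implementation is internally correct and that the min/max rule
behaves as designed under well-separated conditions; it does not
certify field performance on real falls.

## Pipeline sizing

The reference protocol trains on three 120-minute recordings with 18
falls each (54 training falls) and evaluates on one held-out 120-minute
recording with 10 falls.  The sizing follows from a property of the
min/max conjunction: for any continuous feature dimension, a new fall
lands outside the training range with probability 2/(n+1) regardless of
the distribution, so with ~3 effective fall parameters (peak, pre-fall
duration, tilt) driving the nine correlated features, 54 training falls
give an expected held-out sensitivity near 0.9; specificity is
essentially 1 because ADL slices sit far outside several bands at once
(peak, posture change, impact variance).  The held-out misses that do
occur are falls whose parameters fall outside the training extremes —
the structural cost of a maximum-sensitivity threshold rule, visible in
the field numbers too.

## Numerical and degenerate-input choices

* A constant slice puts the UPV at sample 0 (tie-break), so its
  pre-windows truncate and flag; extraction never raises on degenerate
  input.
* Metrics with zero denominators return NaN ("undefined"), not errors.
* Chi-square uses no continuity correction; Pearson p-values come from
  the t distribution with n−2 df.
* The false-alarm rate is false positives per 10 080-slice week.  The
  companion per-subject-week normalization is provided separately; for
  published phase-2 counts the per-week rate is 0.164 (the printed
  0.17 figure mixes a per-subject denominator that is not stated, so it
  is documented rather than reproduced).
* Model files are JSON (generation, gate, bands, active features,
  provenance); feature tables and recordings are plain CSV.

## Known limitations

Slice-level evaluation conflates event detection with labelling
granularity (a fall and a false alarm in the same minute are
indistinguishable); the simulator makes no claim of clinical realism;
thresholds are cohort-level, not person-specific; and the wear gate can
misfire in ambient temperatures above 27 °C, which the temperature
model here does not attempt to produce.
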