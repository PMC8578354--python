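# Methods

This note documents the models, rules and numerical choices implemented in
`wristcast`, the parameters that matter, and what the synthetic-data
experiments do and do not demonstrate.

## Signal quality indices

All three indices are computed per contiguous minute of data and lie in
[0, 1]; trailing partial minutes are dropped because downstream segments are
strictly 60 s.

**EDA.** The trace is reduced to per-second means; the relative change
r_t = (m_t − m_{t−1}) / max(m_{t−1}, 10⁻⁶ µS) marks second *t* as artifact
when r_t reaches +20% or −10%. The thresholds are treated as inclusive
boundaries with a 10⁻¹² numerical tolerance, so an exactly-20% step is
itself artifact; this makes the printed threshold the boundary value and
avoids float fragility at the boundary. The per-minute SQI is the fraction
of clean seconds; the binary `good` flag requires every second clean. The
first second of a block has no predecessor and is clean by definition.

**BVP.** Normalized spectral entropy of each 1-min segment, averaged over
non-overlapping 4-s windows: each window is mean-removed, the DC bin is
dropped, the periodogram is normalized to a probability distribution and its
Shannon entropy divided by log(#bins), which cancels the log base and maps
to [0, 1]. A minute is good quality iff its entropy is *strictly* below 0.9.
An all-zero window is maximally uninformative and scores 1 (with a warning).
The continuous channel fed to the classifier is 1 − entropy; whether the
binary flag or the continuous value is the better input is an open
modelling question, and both are available (continuous is the default).

**ACC.** The vector magnitude √(x²+y²+z²) is analyzed in non-overlapping
4-s segments (rectangular window, mean removal only — the simplest faithful
periodogram); the per-segment index is periodogram power in [0.8, 5] Hz
divided by power in [0.8, 16] Hz (Nyquist at 32 Hz), minutes average their
segments. Band edges are inclusive at the 0.25 Hz bin resolution. An
RMS-over-axes alternative to the vector magnitude exists in the field; the
vector magnitude is used here because it is rotation invariant.

## Channel assembly

Slow channels (EDA, TEMP, HR) are upsampled to 128 Hz by linear
interpolation; ACC and BVP by polyphase antialiased upsampling. Each 60-s
segment is a 17 × 7680 tensor in a fixed order (single source of truth in
`preprocessing.CHANNELS`). Spectral channels hold the one-sided magnitude
spectrum of the mean-removed segment (3841 bins) linearly stretched to 7680
samples so all channels share one axis; scalar channels (three SQIs, local
hour 0–23) are replicated across the segment. The hour is used raw (not
sine/cosine encoded) and z-scored with everything else.

For long recordings the segments can be decimated at assembly
(`assembly_stride`); raw channels are then sampled at every stride-th grid
point (which coincides with native samples at the strides used) and spectral
channels are computed from the native-rate samples, whose bin spacing (1/60
Hz) already matches the 128 Hz spectrum. Minutes not covered by every
modality, or without an SQI value, are excluded rather than zero-filled, so
"absent" is never confused with "flat".

Normalization is per-channel z-scoring with mean/sd estimated on the
training interval only and reused verbatim on test data; zero-variance
channels get sd = 1 with a warning.

## Labels, split, balancing

A lead seizure has no predecessor within 4 h (a gap of exactly 4 h is lead).
For each lead seizure the preictal window is [onset − 75, onset − 15) min.
Minutes overlapping the set-back or the post-ictal exclusion (default 4 h
after any onset, configurable to 0 for a literal minimal reading) and the
preictal windows of clustered seizures are excluded; exclusion always wins
over preictal. Interval boundaries are half-open so no minute carries two
labels.

The chronological cutoff starts at one third of the record span and advances
to the earliest post-onset time at which at least 4 lead seizures and 240
preictal minutes precede it; at least one lead seizure must remain for
testing. Training balance caps interictal segments at 6× the preictal count
(seeded subsample) and appends noise-added preictal copies until the classes
are equal: copy = original + U[0,1)·median, the median taken per channel
within the segment (channels have different units). Copies carry an
`augmented` flag, inherit the original's timestamp, and never enter
evaluation. Augmentation happens before normalization; normalization
statistics are fitted on the un-augmented training selection.

## Classifier

A stacked LSTM: 4 layers × 128 hidden units, dropout 0.2 after every LSTM
layer, and a fully connected sigmoid head reading the final timestep. It is
implemented directly in NumPy — forward pass, full backpropagation through
time, Adam (lr 10⁻³, β = 0.9/0.999), gradient-norm clipping at 5 — in
float32, with every source of randomness (initialization, dropout masks,
shuffling) driven by explicit seeds; the analytic gradients are verified
against central finite differences in the test suite. Initialization is
uniform ±1/√H with a +1 forget-gate bias offset.

Sequence length is controlled by temporal decimation: the 7680-sample
segment enters the recurrence every `temporal_stride`-th sample (library
default 16 → 480 steps). Pipeline experiments in the test suite use
assembly-level decimation to 30 steps (one sample per 2 s), which keeps a
full multi-seed train/evaluate suite within desk-scale compute; the planted
signatures studied are minute-scale mean shifts, which survive any of these
decimations. Loss (binary cross-entropy), optimizer, epochs and batch size
are all configurable; training aborts with diagnostics on non-finite loss.

## Forecast aggregation and metrics

Per-minute probabilities are averaged within clock-aligned 5-min bins; each
clock hour is scored with the maximum of its (up to 12) group means. Hours
with fewer than 45 scored minutes are dropped; an hour is preictal if it
contains any preictal minute (the most sensitive reading; majority-overlap
is configurable), interictal if it contains an interictal minute and no
preictal one, and otherwise takes part in neither class. AUC is computed
over hourly scores (ties count one half; verified against a brute-force
pair-count oracle).

The operating threshold is the training-forecast hourly-score quantile whose
exceedance matches a target time in warning (default 7 h/day, inside the
clinically plausible range); test scores never influence it. A lead seizure
counts as predicted when a warned hour overlaps its preictal window; the
alert lead is measured from the first warned moment within
[onset − 75 min, onset], so it is capped at 75 min by construction.

## Chance predictor and surrogates

The chance model assumes warning episodes start as a Poisson process (rate
λ_w) with mean duration d; an episode overlaps the 60-min detection horizon
τ iff it starts within τ + d of it, so the per-seizure chance hit
probability is c = 1 − exp(−λ_w (τ + d)). λ_w is calibrated from the
observed warning fraction w via w = 1 − exp(−λ_w d), with d measured from
the actual contiguous warned-hour episodes. The two-sided p-value doubles
the smaller Binomial(N, c) tail (including the observed count) and caps at
1; degenerate warning fractions (0 or 1) are handled in closed form. This
exposure correction matters: ignoring the episode duration understates c for
block-shaped warnings and produces anti-conservative p-values.

Surrogate seizure times permute the inter-onset intervals and anchor the
sequence uniformly inside the evaluated span, preserving the onset count and
interval multiset; hour labels are re-derived per replicate and the fixed
forecast re-scored. Type-I error of the whole chain (aggregation, threshold
calibration, alarm scoring, p-value) is measured in the test suite on
independent null forecasts: 45-day smoothed-noise probability streams give
the binomial enough resolution (≈50 lead seizures per replicate) for the
rejection rate to sit near the nominal 5%.

## Synthetic data

The generator emulates: HR with circadian swing, OU variability and
activity-driven elevation; BVP as a harmonic pulse waveform at the
instantaneous HR (placing clean minutes in the low-entropy regime) plus
sensor noise; EDA as a tonic OU level plus Poisson phasic responses with a
fast-rise/4-s-decay kernel; TEMP with circadian swing and slow drift; ACC as
gravity plus rest noise and daytime bouts of ~2 Hz oscillation. Seizure
onsets follow a circadian-modulated Poisson process with self-exciting
clustered follow-ups inside 4 h. The optional preictal signature (HR rise in
bpm, SCR-rate multiplier, TEMP drift) is injected exactly in the label
window [−75, −15) min with 60-s cosine ramps at the edges. Artifact
injection adds motion bursts (broadband ACC noise, corrupted BVP), EDA
steps exceeding the quality thresholds, and flat segments, with ground-truth
intervals returned. Identical config and seed reproduce recordings
bit-exactly.

What passing the synthetic experiments shows: the pipeline recovers a
planted minute-scale physiological signature (hourly AUC ≥ 0.75 at HR
+15 bpm / SCR ×3 over 14 days), stays at chance on null data, and its
significance machinery is calibrated. What it does not show: that real
preictal physiology resembles these mean-shift signatures, that artifacts
and missing data behave like the simulated ones, or that performance on
private ambulatory patient data is reproduced — per-patient clinical results
are out of scope by design. The simulated seizure times in the recovery
experiment are uniform over the day (circadian concentration 0) so that
forecast skill is attributable to the planted physiological signature rather
than to the time-of-day channel.

## Known limitations

* The LSTM consumes decimated sequences by default; full-resolution
  (7680-step) training is supported but slow on one CPU.
* The chance-model calibration reconstructs a Poisson episode-overlap
  argument; it is isolated in `ChanceModel` so an alternative calibration
  can be swapped in.
* Surrogates are not circadian-matched; on strongly circadian seizure data
  they form a slightly liberal null.
* The threshold policy (target time in warning on training forecasts) is one
  of several defensible operating-point choices; it is a config knob, not a
  claim.
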