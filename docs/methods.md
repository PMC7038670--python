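# Methods

This note documents the models, defaults and numerical choices behind
`piezobp`, and what the synthetic validation does and does not demonstrate
about real recordings.

## Measurement principle and its central assumption

The tracker reconstructs beat-to-beat SBP/DBP as the cumulative sum of
pressure changes inferred from inter-beat voltage changes, anchored at one
cuff reading. The accumulation telescopes — SBP(k) depends only on the k-th
and first peak voltages — so the method is exact precisely when the mapping
from arterial pressure to detected voltage is linear and stationary. Three
things can break stationarity: sensor clipping (flagged, never silently
corrected), coupling changes between sensor and skin (out of scope, resting
conditions assumed), and baseline drift in the voltages (see *Known
limitations*).

## Synthetic data generator

The generator produces the study conditions the pipeline is validated under.
Defaults emulate a 30-minute resting protocol: 72 bpm, anchor 109/61 mmHg,
beat-to-beat SBP/DBP random-walk steps of SD 0.5 mmHg (independent walks,
reflected at 70–190 / 40–100 mmHg, DBP additionally capped at SBP − 10 mmHg
so pulse pressure never collapses), respiratory wander as a 0.25 Hz sinusoid
with amplitude 10% of the anchor pulse span (4.8 mmHg), and white sensor
noise with SD 2% of the transduced span (1.92 mV). Sampling is 500 Hz —
fine enough to place pulse peaks within 2 ms.

Each beat is a fixed template on the beat phase, linearly rescaled so the
sampled per-beat maximum/minimum equal that beat's true SBP/DBP exactly; the
rescaling makes the ground-truth contract exact on the grid rather than
approximate. The template is two Gaussian bumps (systolic peak at phase 0.18,
dicrotic shoulder at 0.42) plus a linearly decaying *diastolic runoff* term
(5% of the pulsatile amplitude). The runoff emulates the monotone diastolic
pressure decay and serves a structural purpose: it places each beat's
minimum uniquely at the end-diastolic foot that terminates the cycle. With a
flat foot instead, the minimum between two systolic peaks falls into
whichever neighboring beat happens to have lower DBP, and valley values mix
adjacent beats whenever DBP drifts. The runoff margin (~2.4 mmHg at the
default pulse span) makes misassignment require a single-beat DBP step
larger than ~4.8 standard deviations.

What the generator does **not** emulate: pulse-shape changes with blood
pressure or vascular tone (the template is fixed; only its scale varies),
motion artifacts, sensor-coupling drift, heart-rate variability (constant
rate by default), and arrhythmia. Tests passing on this generator therefore
demonstrate the correctness of the signal chain and the accumulation
algebra, not robustness to morphology variation or movement.

## Analog front-end

Modeled twice and cross-checked: a closed-form magnitude cascade (first-order
high-pass 0.03 Hz for AC coupling; Butterworth high-pass 0.05 Hz, order 2;
gain 49.4 kΩ/R_G + 1; Butterworth low-pass 35 Hz, order 2), and a causal
time-domain realization via bilinear-transformed digital stages at the
trace's sampling rate. Orders default to 2 because the corresponding analog
stages are Sallen-Key topologies with two RC products each. Causal filtering
is the default (it mimics hardware, including its phase lag); each stage is
initialized at the step steady state of the first sample, i.e. as if the
circuit had settled on a constant input before the recording began, which
suppresses the multi-minute startup transient the 0.03 Hz stage would
otherwise inject. A `zero_phase` switch (forward–backward filtering) exists
for feature-time studies; note it applies each magnitude twice. Pipelines
additionally pad the simulated recording with constant-BP warm-up beats
(30 s lead-in, 5 s lead-out) and crop after filtering, so the anchored first
beat is measured by a settled chain.

Bode sweeps are log-spaced (default 2000 points over 10⁻³–10³ Hz); cutoffs
are the half-power crossings (midband − 10·log₁₀2 dB, i.e. 3.0103 dB) found
by linear interpolation in (log f, dB). Using true half power rather than a
rounded 3.00 dB makes an isolated Butterworth stage report its design cutoff
exactly. For the default cascade the computed band is ≈0.0575–35.0 Hz with
midband 59.90 dB: the lower crossing sits ~15% above the 0.05 Hz design
value because the 0.03 Hz AC-coupling stage and the second-order high-pass
each contribute attenuation near the corner; the hardware design documents
0.05 and 35.12 Hz, and the ~0.3% gap at the upper edge presumably reflects
component values not reproduced here. The implementation reports its
computed crossings rather than tuning stage parameters to match the
documented hardware figures.

## Preprocessing

Order is fixed: detrend, then wavelet denoise. Both are length- and
units-preserving, and both can be disabled (`detrend_method: none`,
`denoise: false`) — the noiseless chain-inversion tests use that, since
detrending a drift-free signal only removes real signal.

**Detrending.** The default estimator is a zero-phase Butterworth high-pass
(order 3, forward–backward, cutoff 1/`detrend_window` Hz, default window 2 s
→ 0.5 Hz), with reflection padding spanning three windows and even symmetry
so the edge baseline follows the local mean rather than the endpoint value.
At the default settings a 0.25 Hz respiratory wander is attenuated ~17×
(94%) while the cardiac fundamental at 72 bpm loses <1% — both properties
are tested. Moving-median, moving-mean and polynomial estimators are also
provided for exploration, but they are not the default for a quantitative
reason: a sliding window of length T captures a sinusoid of frequency f only
by a sinc-like factor (≈64% at f = 0.5/T), so no window choice removes
band-edge wander by 90% while preserving pulse amplitudes; on pulse-shaped
input they additionally leak a beat-rate ripple of a few mmHg.

**Denoising.** Standard wavelet shrinkage: db4, decomposition level
⌊log₂(fs/8)⌋ (5 at 500 Hz), universal threshold σ√(2 ln N) with σ estimated
from the median absolute deviation of the finest detail scale, soft
thresholding of detail coefficients only, symmetric boundary extension,
reconstruction trimmed to the input length. The vendor routine this stands
in for is unspecified; the recipe is the common default and every piece is
overridable.

## Feature detection

Two thresholds at fixed fractions (0.6 / 0.4) of a rolling dynamic-range
estimate (window 5 s) provide hysteresis: a peak search arms above the upper
threshold and commits the running maximum when the signal falls below the
lower one; a valley search runs until the next upper crossing. Range-relative
thresholds make detection exactly invariant to constant offsets and tolerant
of residual drift; the rolling window adapts them over long records. A
0.25 s refractory period (240 bpm ceiling) merges double-fires by keeping
the taller peak and discarding the failed separating valley. Ties at an
extremum resolve to the earliest sample. A trace whose dynamic range is
below a configurable floor yields empty annotations with a warning; NaNs are
an error. Beats are (peak, following valley) pairs — the valley terminates
the cycle it belongs to — and a trailing unpaired extremum is dropped with a
log note.

## Tracker

Voltage deltas are adjacent differences of the paired peak (SBP) and valley
(DBP) voltages; conversion divides by gain and sensitivity (volts at the
output are ×1000 to sensor-referred millivolts). Beat timestamps are peak
(systolic) times. The first tracked beat equals the cuff anchor exactly.
Physiologically impossible beats (SBP ≤ DBP) are counted and logged, never
clipped, and the first-to-last valley-voltage drift is reported in mmHg as a
quality metric, because any baseline drift in the voltages integrates
directly into the cumulative sum.

## Evaluation

References pair to the nearest tracked beat within a window (default 2 s);
unmatched references are counted and dropped, and zero pairs is an error.
MAE is the mean absolute error. The default SD variant (`signed`)
measures *signed* errors about the MAE with an n−1 denominator — the
dispersion statistic used in the validation protocol this package mirrors;
it is nonstandard, not invariant under flipping error signs, so an
`absolute` variant (ordinary SD of absolute errors) is provided and both can
be reported. Which of the two produced the bundled per-subject table cannot
be determined from its values alone, so
the table is carried as data (`piezobp/data/cohort_table.csv`, 30 subjects
with per-subject MAE/SD for SBP and DBP) and `summarize_cohort` reproduces
its four column means.

## Known limitations

The dominant one is structural: **an AC-coupled chain cannot observe slow
drift of the absolute pressure level.** The 0.03/0.05 Hz high-pass stages
remove, irreversibly, any additive baseline component slower than roughly
20 s — including genuine drift of mean arterial pressure. What survives is
the pulsatile component referenced to its local mean, so the tracked error
at beat k is −(c̄·ΔSBP_k + (1−c̄)·ΔDBP_k), where Δ denotes true drift since
the anchor and c̄ ≈ 0.24 is the template's duty-cycle mean. Tracked *pulse
pressure* follows truth closely (tested), and under stationary BP the full
chain meets MAE ≤ 5 / SD ≤ 8 comfortably (tested on a 5-minute run with
wander and noise). Under the default drifting-BP study conditions, however,
the random walk carries the mean level tens of mmHg from the anchor over 30
minutes, and the tracked-vs-truth MAE/SD are then dominated by that
unobservable drift — for most seeds they exceed the validation bounds. This
is a property of the measurement principle (and of any device that
accumulates passband changes without re-anchoring), not of the
implementation; real resting subjects with near-stationary BP correspond to
the small-drift regime. Re-calibration schedules that would bound the error
are deliberately out of scope.

Smaller limitations: detrending assumes the heart rate stays well above the
detrend cutoff (at 48 bpm the default window starts to bite ~6% of the pulse
span; shorten the window or raise the order if needed); the refractory merge
assumes no more than one spurious crossing pair per beat; evaluation pairing
assumes reference timestamps share the recording clock.
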