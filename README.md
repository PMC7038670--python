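# piezobp

Beat-to-beat blood-pressure tracking from piezoelectric pressure pulse waves.

## The problem

Cuff (oscillometric) blood-pressure measurement is the clinical standard but
gives one reading per inflation; arterial cannulation is continuous but
invasive. A wrist-worn piezoelectric sensor over the radial artery offers a
middle path: the sensor converts the arterial pressure pulse wave (PPW)
directly into voltage with a fixed pressure sensitivity, so *changes* in
systolic and diastolic pressure appear as changes in the per-beat voltage
peaks and valleys. Anchoring one cuff reading and accumulating those changes
yields a continuous beat-to-beat SBP/DBP record with no regression model and
no repeated calibration.

`piezobp` implements that measurement chain end to end as testable software,
for people who want to study the approach quantitatively: a synthetic PPW
generator with known ground truth, a model of the sensor and its analog
front-end, the digital cleanup and feature detection, the cumulative tracker,
and device-validation statistics.

## The model

With a sensor sensitivity *S* (mV/mmHg, default 2) and front-end gain *G*
(dimensionless, default 989 from the gain law *G* = 49.4 kΩ/*R*<sub>G</sub> + 1
at *R*<sub>G</sub> = 50 Ω), a change ΔV (volts at the amplifier output)
between the same feature point of adjacent beats converts to pressure as

    ΔP [mmHg] = ΔV · 1000 / G / S        (0.5 mmHg per sensor-referred mV)

and the tracked series is the cumulative sum anchored at the initial cuff
reading:

    SBP(k) = SBP_init + Σ_{j<k} ΔP_peak(j)
    DBP(k) = DBP_init + Σ_{j<k} ΔP_valley(j)

The analog front-end is a first-order AC-coupling high-pass (0.03 Hz), a
second-order Butterworth high-pass (0.05 Hz), the instrumentation-amplifier
gain, and a second-order Butterworth low-pass (35 Hz) — a 0.05–35 Hz band
with ≈59.9 dB midband amplification. Accuracy against timed reference cuff
readings x<sub>i</sub> is summarized by

    MAE = (1/n) Σ |y_i − x_i|
    SD  = sqrt( Σ (y_i − x_i − MAE)² / (n−1) )

with the usual validation bounds MAE ≤ 5 mmHg and SD ≤ 8 mmHg. (That SD
formula measures signed errors about the mean *absolute* error; the package
also offers the ordinary SD of absolute errors — see `docs/methods.md`.)

## Worked example

`piezobp demo` simulates 12 beats anchored at a 109/61 mmHg cuff reading
(noise-free, flat-gain front-end so the conversion law can be checked against
the simulator's truth) and prints:

```
beat  time_s  true SBP/DBP    tracked SBP/DBP  (mmHg)
   1    0.15   109.0/ 61.0     109.0/ 61.0
   2    0.99   109.3/ 61.6     109.3/ 61.6
   3    1.82   109.4/ 60.2     109.4/ 60.2
   ...
  12    9.32   110.7/ 58.8     110.7/ 58.8
max |tracked - true|: SBP 0.0000 mmHg, DBP 0.0000 mmHg
```

The first beat is the cuff anchor by construction; every later beat is
reconstructed purely from inter-beat voltage changes, and in this noiseless
configuration the conversion law inverts the chain exactly.

The full study conditions (30 minutes at 72 bpm, drifting BP, respiratory
baseline wander, sensor noise, causal analog chain, 30 reference readings at
1-minute intervals) run with:

```bash
piezobp simulate --seed 1 --outdir run1
# beats tracked: 2160
# SBP  MAE   4.31  SD   7.40  mmHg
# DBP  MAE   4.35  SD   7.72  mmHg
```

Those MAE/SD values compare the tracked series against the simulator's true
beat values; because the AC-coupled chain cannot observe slow drift of the
mean arterial level, they are dominated by how far the simulated BP wandered
from the anchor (see `docs/methods.md` for this limitation).

Other subcommands: `piezobp freqresp` (Bode sweep of the front-end with
midband and −3 dB cutoffs), `piezobp process` (run the software stages on a
recorded trace), `piezobp evaluate` (score a tracked series against reference
readings).

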