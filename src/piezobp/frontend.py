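"""Analog front-end model: AC-coupling, instrumentation-amplifier gain, and
Butterworth band-limiting.

The chain is modeled twice, and the two views are cross-checked in the tests:

* as a closed-form magnitude response (for Bode sweeps and -3 dB cutoffs), and
* as a causal time-domain transform (bilinear-transformed digital equivalents
  of each analog stage) applied to a sensor-voltage trace.

The default specification reproduces the measurement hardware: a first-order
AC-coupling high-pass at 0.03 Hz, a second-order Butterworth high-pass at
0.05 Hz, an instrumentation amplifier whose gain is set by an external
resistor (gain = 49.4 kOhm / R_G + 1; 989 for R_G = 50 Ohm), and a
second-order Butterworth low-pass at 35 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .trace import SignalTrace

#: AD620-style gain-set numerator, ohms
GAIN_NUMERATOR_OHMS = 49.4e3


def gain_from_rg(rg: float) -> float:
    """Instrumentation-amplifier gain from the external gain resistor.

    ``gain = 49.4 kOhm / R_G + 1``; R_G = 50 Ohm gives 989.
    """
    if not rg > 0:
        raise ValueError("gain resistor must be positive")
    return GAIN_NUMERATOR_OHMS / rg + 1.0


def cutoff_from_components(r: float, c: float) -> float:
    """First-order RC cutoff ``fc = 1 / (2 pi R C)`` in Hz.

    For the second-order Sallen-Key stages the same form applies with the
    geometric mean of the two RC products.
    """
    if not (r > 0 and c > 0):
        raise ValueError("R and C must be positive")
    return 1.0 / (2.0 * np.pi * r * c)


@dataclass
class FrontEndSpec:
    """Gain and cutoff parameters of the analog chain.

    A cutoff of 0 (or None) disables the corresponding stage, which is how
    the tests isolate single stages and how ``bypass`` pipelines run.
    """

    rg: float = 50.0
    gain: float | None = None        # derived from rg when omitted
    fc_ac: float = 0.03              # first-order AC-coupling HP, Hz
    fc_hpf: float = 0.05             # Butterworth HP, Hz
    fc_lpf: float = 35.0             # Butterworth LP, Hz
    order_hpf: int = 2
    order_lpf: int = 2

    def __post_init__(self) -> None:
        if self.gain is None:
            self.gain = gain_from_rg(self.rg)
        if not self.gain >= 1:
            raise ValueError("gain must be at least 1")
        if self.order_hpf < 1 or self.order_lpf < 1:
            raise ValueError("filter orders must be at least 1")
        for name in ("fc_ac", "fc_hpf", "fc_lpf"):
            v = getattr(self, name)
            if v is None:
                setattr(self, name, 0.0)
            elif v < 0:
                raise ValueError(f"{name} must be non-negative")
        active = [f for f in (self.fc_ac, self.fc_hpf, self.fc_lpf) if f > 0]
        if active != sorted(active):
            raise ValueError("cutoffs must be ordered fc_ac < fc_hpf < fc_lpf")


@dataclass
class FrequencyResponse:
    """Result of a log-spaced magnitude sweep of the cascade."""

    freqs: np.ndarray
    magnitude_db: np.ndarray
    midband_db: float
    f_low_3db: float
    f_high_3db: float


def transfer_magnitude(spec: FrontEndSpec, f: float | np.ndarray) -> float | np.ndarray:
    """Cascade magnitude |H(f)| (dimensionless) at frequency f in Hz.

    Product of the stage magnitudes: first-order HP, n-th order Butterworth
    HP (``1/sqrt(1+(fc/f)^(2n))``), the amplifier gain, and n-th order
    Butterworth LP (``1/sqrt(1+(f/fc)^(2n))``). Disabled stages contribute 1.
    """
    farr = np.asarray(f, dtype=np.float64)
    if np.any(farr <= 0):
        raise ValueError("frequency must be positive")
    mag = np.full_like(farr, float(spec.gain))
    if spec.fc_ac > 0:
        mag /= np.sqrt(1.0 + (spec.fc_ac / farr) ** 2)
    if spec.fc_hpf > 0:
        mag /= np.sqrt(1.0 + (spec.fc_hpf / farr) ** (2 * spec.order_hpf))
    if spec.fc_lpf > 0:
        mag /= np.sqrt(1.0 + (farr / spec.fc_lpf) ** (2 * spec.order_lpf))
    return mag if isinstance(f, np.ndarray) else float(mag)


#: half-power level in dB; the Butterworth design cutoff sits exactly here
_HALF_POWER_DB = 10.0 * np.log10(2.0)


def _crossing(logf: np.ndarray, rel_db: np.ndarray, i: int, j: int) -> float:
    """Interpolate the -3 dB crossing between sweep points i and j in log-f."""
    x0, x1 = logf[i], logf[j]
    y0, y1 = rel_db[i], rel_db[j]
    if y1 == y0:
        return float(10 ** x0)
    x = x0 + (-_HALF_POWER_DB - y0) * (x1 - x0) / (y1 - y0)
    return float(10 ** x)


def frequency_response(
    spec: FrontEndSpec,
    f_min: float = 1e-3,
    f_max: float = 1e3,
    n_points: int = 2000,
) -> FrequencyResponse:
    """Log-spaced Bode sweep with interpolated half-power cutoffs.

    The midband level is the sweep maximum; the lower/upper cutoffs are the
    frequencies where the magnitude crosses ``midband - 3 dB`` (half power),
    found by linear interpolation in (log f, dB). A missing crossing (stage
    disabled, sweep too narrow) is reported as NaN.
    """
    if not (0 < f_min < f_max):
        raise ValueError("sweep bounds must satisfy 0 < f_min < f_max")
    if n_points < 100:
        raise ValueError("n_points must be at least 100")
    freqs = np.logspace(np.log10(f_min), np.log10(f_max), n_points)
    mag_db = 20.0 * np.log10(transfer_magnitude(spec, freqs))
    k = int(np.argmax(mag_db))
    midband = float(mag_db[k])
    rel = mag_db - midband
    logf = np.log10(freqs)

    f_low = np.nan
    below = np.flatnonzero(rel[: k + 1] < -_HALF_POWER_DB)
    if below.size:
        i = int(below[-1])
        f_low = _crossing(logf, rel, i, i + 1)

    f_high = np.nan
    above = np.flatnonzero(rel[k:] < -_HALF_POWER_DB)
    if above.size:
        j = k + int(above[0])
        f_high = _crossing(logf, rel, j - 1, j)

    return FrequencyResponse(freqs, mag_db, midband, f_low, f_high)


def _sos_stages(spec: FrontEndSpec, fs: float) -> list[np.ndarray]:
    """Bilinear-transformed digital equivalents of the analog stages, in order."""
    stages = []
    if spec.fc_ac > 0:
        stages.append(sps.butter(1, spec.fc_ac, btype="highpass", fs=fs, output="sos"))
    if spec.fc_hpf > 0:
        stages.append(sps.butter(spec.order_hpf, spec.fc_hpf, btype="highpass", fs=fs, output="sos"))
    if spec.fc_lpf > 0:
        stages.append(sps.butter(spec.order_lpf, spec.fc_lpf, btype="lowpass", fs=fs, output="sos"))
    return stages


def apply_frontend(
    trace: SignalTrace,
    spec: FrontEndSpec | None = None,
    bypass: bool = False,
    zero_phase: bool = False,
) -> SignalTrace:
    """Run a sensor-voltage trace (mV) through the front-end; output in volts.

    Stages apply in the analog order AC-coupling -> HP -> gain -> LP. Causal
    filtering (the default) mimics the physical circuit; each causal stage is
    initialized at the step steady state of the first sample, i.e. as if the
    sensor had been attached and the circuit settled before recording started.
    ``zero_phase`` switches to forward-backward filtering (no phase lag, each
    stage's magnitude applied twice). ``bypass`` skips all filters and applies
    the flat gain only, which is the mode the chain-inversion tests use.
    """
    spec = spec or FrontEndSpec()
    if trace.units != "mV":
        raise ValueError(f"apply_frontend expects a sensor trace in mV, got {trace.units}")
    x = trace.values.copy()
    if not bypass:
        if spec.fc_lpf > 0 and trace.fs <= 2 * spec.fc_lpf:
            raise ValueError("sampling rate too low for the low-pass cutoff")
        for sos in _sos_stages(spec, trace.fs):
            if zero_phase:
                x = sps.sosfiltfilt(sos, x)
            else:
                zi = sps.sosfilt_zi(sos) * x[0]
                x, _ = sps.sosfilt(sos, x, zi=zi)
    out = x * spec.gain / 1000.0  # mV at the input, volts at the output
    return trace.with_values(out, units="V", gain=float(spec.gain), bypass=bool(bypass))
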