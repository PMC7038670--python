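"""Synthetic radial-artery pressure pulse waves and their transduction.

The generator produces the study conditions the rest of the pipeline is
validated against: a beat-to-beat ground-truth SBP/DBP trajectory, a pressure
pulse wave (PPW) whose per-beat maximum/minimum equal the true SBP/DBP,
slow respiratory baseline wander, the piezoelectric pressure-to-voltage
transduction, and additive measurement noise.

Beat boundaries follow the valley-to-valley convention: each beat interval
starts at its diastolic foot, and the per-beat extrema contract is enforced on
the sampled grid, so the brute-force per-beat scan used as an oracle in the
tests recovers the ground-truth arrays exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trace import SignalTrace

#: physiological reflection bounds for the random-walk trajectory, mmHg
DEFAULT_SBP_BOUNDS = (70.0, 190.0)
DEFAULT_DBP_BOUNDS = (40.0, 100.0)

#: smallest pulse pressure the generator will emit, mmHg
MIN_PULSE_PRESSURE = 10.0


@dataclass
class GroundTruthBP:
    """True beat-by-beat blood pressure of a simulated recording.

    ``sbp_true[k]`` / ``dbp_true[k]`` are the per-beat arterial maxima/minima
    in mmHg; ``beat_times[k]`` is the start (diastolic foot) of beat ``k`` in
    seconds from recording start.
    """

    beat_times: np.ndarray
    sbp_true: np.ndarray
    dbp_true: np.ndarray
    heart_rate: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=np.float64)
        self.sbp_true = np.asarray(self.sbp_true, dtype=np.float64)
        self.dbp_true = np.asarray(self.dbp_true, dtype=np.float64)
        self.heart_rate = np.asarray(self.heart_rate, dtype=np.float64)
        n = self.beat_times.size
        if not (self.sbp_true.size == self.dbp_true.size == self.heart_rate.size == n):
            raise ValueError("ground-truth arrays must share one length")
        if n == 0:
            raise ValueError("ground truth must contain at least one beat")
        for name, arr in (("beat_times", self.beat_times), ("sbp_true", self.sbp_true),
                          ("dbp_true", self.dbp_true)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
        if n > 1 and not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat_times must be strictly increasing")
        if not np.all(self.sbp_true > self.dbp_true):
            raise ValueError("every beat must satisfy SBP > DBP")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    @property
    def periods(self) -> np.ndarray:
        """Duration of each beat in seconds (last beat uses its own 60/HR)."""
        if self.n_beats == 1:
            return np.array([60.0 / self.heart_rate[0]])
        d = np.diff(self.beat_times)
        return np.append(d, 60.0 / self.heart_rate[-1])


@dataclass
class SensorSpec:
    """Piezoelectric sensor transfer characteristics.

    The default models a PVDF medical pulse sensor with 2 mV/mmHg sensitivity
    over a -50..3000 mmHg rated range; outside the range the output clips.
    """

    sensitivity: float = 2.0      # mV per mmHg
    pressure_min: float = -50.0   # mmHg
    pressure_max: float = 3000.0  # mmHg

    def __post_init__(self) -> None:
        if not self.sensitivity > 0:
            raise ValueError("sensitivity must be positive")
        if not self.pressure_min < self.pressure_max:
            raise ValueError("pressure_min must be below pressure_max")


@dataclass
class PulseMorphology:
    """Pulse template on the beat phase: Gaussian bumps plus diastolic runoff.

    The default pairs a narrow systolic peak with a broader dicrotic
    shoulder; bumps are evaluated with periodic wrap-around so the pulsatile
    part is smooth across the beat boundary. ``foot_lift`` adds a linearly
    decaying runoff term, emulating the diastolic pressure decay, so each
    beat attains its minimum once, at the end-diastolic foot that terminates
    the cycle, rather than on an ambiguous flat segment spanning two beats.
    Each beat is then linearly rescaled so its sampled extrema land exactly
    on that beat's SBP/DBP.
    """

    centers: tuple[float, ...] = (0.18, 0.42)
    widths: tuple[float, ...] = (0.055, 0.12)
    amplitudes: tuple[float, ...] = (1.0, 0.38)
    foot_lift: float = 0.05

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.widths) == len(self.amplitudes)):
            raise ValueError("morphology tuples must share one length")
        if len(self.centers) == 0:
            raise ValueError("morphology needs at least one bump")
        if any(w <= 0 for w in self.widths):
            raise ValueError("degenerate morphology: bump widths must be positive")
        if self.foot_lift < 0:
            raise ValueError("foot_lift must be non-negative")

    def template(self, phase: np.ndarray) -> np.ndarray:
        """Evaluate the template at beat phase in [0, 1)."""
        out = self.foot_lift * (1.0 - phase)
        for c, w, a in zip(self.centers, self.widths, self.amplitudes):
            for wrap in (-1.0, 0.0, 1.0):
                out = out + a * np.exp(-0.5 * ((phase + wrap - c) / w) ** 2)
        return out


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at both bounds."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def simulate_bp_trajectory(
    n_beats: int,
    init_sbp: float,
    init_dbp: float,
    sbp_step_sd: float = 0.5,
    dbp_step_sd: float = 0.5,
    heart_rate: float = 72.0,
    seed: int | None = None,
    sbp_bounds: tuple[float, float] = DEFAULT_SBP_BOUNDS,
    dbp_bounds: tuple[float, float] = DEFAULT_DBP_BOUNDS,
) -> GroundTruthBP:
    """Bounded Gaussian random walk for beat-to-beat SBP/DBP.

    Beat 1 is exactly ``(init_sbp, init_dbp)`` (the cuff anchor); later beats
    take independent Gaussian steps and reflect at the physiological bounds.
    DBP is additionally capped at SBP minus a minimum pulse pressure so the
    SBP > DBP invariant can never be violated by the two independent walks.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be at least 1")
    if not init_sbp > init_dbp:
        raise ValueError("init_sbp must exceed init_dbp")
    if sbp_step_sd < 0 or dbp_step_sd < 0:
        raise ValueError("step standard deviations must be non-negative")
    if not heart_rate > 0:
        raise ValueError("heart_rate must be positive")

    rng = np.random.default_rng(seed)
    sbp_steps = rng.normal(0.0, sbp_step_sd, size=n_beats - 1) if sbp_step_sd > 0 else np.zeros(n_beats - 1)
    dbp_steps = rng.normal(0.0, dbp_step_sd, size=n_beats - 1) if dbp_step_sd > 0 else np.zeros(n_beats - 1)

    sbp = _reflect(init_sbp + np.concatenate(([0.0], np.cumsum(sbp_steps))), *sbp_bounds)
    dbp = _reflect(init_dbp + np.concatenate(([0.0], np.cumsum(dbp_steps))), *dbp_bounds)
    dbp = np.minimum(dbp, sbp - MIN_PULSE_PRESSURE)

    beat_times = np.arange(n_beats) * 60.0 / heart_rate
    return GroundTruthBP(beat_times, sbp, dbp, np.full(n_beats, float(heart_rate)))


def synthesize_pressure_waveform(
    gt: GroundTruthBP,
    fs: float = 500.0,
    morphology: PulseMorphology | None = None,
) -> SignalTrace:
    """Realize the continuous PPW (mmHg) from a beat-by-beat trajectory.

    Each beat interval is filled with the morphology template on its local
    phase and rescaled so the sampled per-beat maximum equals that beat's
    SBP and the minimum its DBP. The contract is exact on the sample grid.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz to resolve pulse peaks")
    morphology = morphology or PulseMorphology()

    periods = gt.periods
    t0 = gt.beat_times[0]
    total = gt.beat_times[-1] + periods[-1] - t0
    n = int(round(total * fs))
    t = t0 + np.arange(n) / fs

    # beat index of every sample; tiny epsilon keeps the sample that lands on
    # a beat start inside that beat
    idx = np.searchsorted(gt.beat_times, t + 1e-12, side="right") - 1
    idx = np.clip(idx, 0, gt.n_beats - 1)
    phase = (t - gt.beat_times[idx]) / periods[idx]
    raw = morphology.template(np.clip(phase, 0.0, 1.0))

    starts = np.searchsorted(idx, np.arange(gt.n_beats), side="left")
    if np.any(np.diff(np.append(starts, n)) < 2):
        raise ValueError("fs too low: some beat contains fewer than two samples")
    bmax = np.maximum.reduceat(raw, starts)
    bmin = np.minimum.reduceat(raw, starts)
    if np.any(bmax - bmin <= 0):
        raise ValueError("degenerate morphology: template is flat within a beat")

    scale = (gt.sbp_true[idx] - gt.dbp_true[idx]) / (bmax[idx] - bmin[idx])
    values = gt.dbp_true[idx] + (raw - bmin[idx]) * scale
    return SignalTrace(values, fs=fs, units="mmHg", t0=float(t0),
                       meta={"n_beats": int(gt.n_beats)})


def extend_ground_truth(gt: GroundTruthBP, lead_time: float, tail_time: float) -> GroundTruthBP:
    """Pad a trajectory with constant-BP beats before and after.

    The lead-in replicates beat 1 backwards in time (negative beat times) and
    the lead-out replicates the last beat forwards. Pipelines use this to let
    the causal front-end and the zero-phase detrender settle outside the
    recording proper, mimicking a sensor that was attached before the cuff
    anchor was taken; the padding is cropped again after filtering.
    """
    if lead_time < 0 or tail_time < 0:
        raise ValueError("lead/tail times must be non-negative")
    p_first = 60.0 / gt.heart_rate[0]
    p_last = 60.0 / gt.heart_rate[-1]
    n_lead = int(np.ceil(lead_time / p_first))
    n_tail = int(np.ceil(tail_time / p_last))
    lead_t = gt.beat_times[0] - p_first * np.arange(n_lead, 0, -1)
    tail_t = gt.beat_times[-1] + gt.periods[-1] + p_last * np.arange(n_tail)
    return GroundTruthBP(
        np.concatenate((lead_t, gt.beat_times, tail_t)),
        np.concatenate((np.full(n_lead, gt.sbp_true[0]), gt.sbp_true,
                        np.full(n_tail, gt.sbp_true[-1]))),
        np.concatenate((np.full(n_lead, gt.dbp_true[0]), gt.dbp_true,
                        np.full(n_tail, gt.dbp_true[-1]))),
        np.concatenate((np.full(n_lead, gt.heart_rate[0]), gt.heart_rate,
                        np.full(n_tail, gt.heart_rate[-1]))),
    )


def add_baseline_wander(
    trace: SignalTrace,
    amplitude: float,
    resp_freq: float = 0.25,
    seed: int | None = None,
    drift_amplitude: float = 0.0,
) -> SignalTrace:
    """Superimpose respiratory baseline wander (sinusoid, trace units).

    ``seed`` randomizes the respiration phase; with ``seed=None`` the phase is
    zero. ``drift_amplitude`` optionally adds a smooth random low-frequency
    drift (sum of three incommensurate sinusoids below ``resp_freq``).
    """
    if amplitude < 0:
        raise ValueError("wander amplitude must be non-negative")
    if not 0 < resp_freq < 1:
        raise ValueError("resp_freq must lie in (0, 1) Hz")
    if amplitude == 0 and drift_amplitude == 0:
        return trace.with_values(trace.values)

    rng = np.random.default_rng(seed)
    t = trace.times
    phase = rng.uniform(0, 2 * np.pi) if seed is not None else 0.0
    wander = amplitude * np.sin(2 * np.pi * resp_freq * t + phase)
    if drift_amplitude > 0:
        for frac in (0.11, 0.23, 0.37):
            wander += (drift_amplitude / 3.0) * np.sin(
                2 * np.pi * frac * resp_freq * t + rng.uniform(0, 2 * np.pi))
    return trace.with_values(trace.values + wander)


def transduce(trace: SignalTrace, spec: SensorSpec | None = None) -> SignalTrace:
    """Piezoelectric transduction: pressure (mmHg) -> sensor voltage (mV).

    Linear with slope ``sensitivity`` inside the rated pressure range;
    pressures outside it clip to the boundary. The number of clipped samples
    is recorded under ``meta["n_clipped"]`` and triggers a warning.
    """
    spec = spec or SensorSpec()
    if trace.units != "mmHg":
        raise ValueError(f"transduce expects a pressure trace in mmHg, got {trace.units}")
    clipped = np.clip(trace.values, spec.pressure_min, spec.pressure_max)
    n_clipped = int(np.count_nonzero(clipped != trace.values))
    if n_clipped:
        warnings.warn(f"{n_clipped} samples outside the sensor range were clipped",
                      stacklevel=2)
    return trace.with_values(clipped * spec.sensitivity, units="mV", n_clipped=n_clipped)


def add_noise(trace: SignalTrace, noise_sd: float, seed: int | None = None) -> SignalTrace:
    """Additive zero-mean Gaussian noise in the trace's own units."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return trace.with_values(trace.values)
    rng = np.random.default_rng(seed)
    return trace.with_values(trace.values + rng.normal(0.0, noise_sd, size=len(trace)))
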