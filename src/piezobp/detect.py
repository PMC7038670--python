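"""Threshold-based extraction of systolic peaks and diastolic valleys.

Detection uses two range-relative thresholds with hysteresis: a peak search
arms when the signal rises above the upper threshold and commits the running
maximum when it falls below the lower one; a valley search then runs until
the next upper crossing. Thresholds are fractions of a rolling dynamic-range
estimate, which makes the detector invariant to constant offsets and robust
to residual slow drift. A refractory period suppresses double-fires faster
than any physiological heart rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .trace import SignalTrace

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """Threshold detector tunables.

    Fractions are of the local dynamic range estimated over
    ``adaptive_window`` seconds; ``refractory`` (seconds) is the minimum
    peak-to-peak spacing (0.25 s allows up to 240 bpm); ``min_range`` is the
    dynamic-range floor below which the trace is declared flat.
    """

    peak_threshold_frac: float = 0.6
    valley_threshold_frac: float = 0.4
    refractory: float = 0.25
    adaptive_window: float = 5.0
    min_range: float = 1e-9

    def __post_init__(self) -> None:
        if not 0 < self.valley_threshold_frac < self.peak_threshold_frac < 1:
            raise ValueError("need 0 < valley_threshold_frac < peak_threshold_frac < 1")
        if not self.refractory > 0:
            raise ValueError("refractory must be positive")
        if not self.adaptive_window > 0:
            raise ValueError("adaptive_window must be positive")


@dataclass
class BeatAnnotations:
    """Per-beat feature points: peak (systolic) and valley (diastolic).

    Values carry the units of the trace they were detected on (volts for the
    amplified chain). Peaks and valleys strictly alternate in time and their
    counts differ by at most one.
    """

    peak_times: np.ndarray
    peak_values: np.ndarray
    valley_times: np.ndarray
    valley_values: np.ndarray
    units: str = "V"

    def __post_init__(self) -> None:
        for name in ("peak_times", "peak_values", "valley_times", "valley_values"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.peak_times.size != self.peak_values.size:
            raise ValueError("peak arrays must share one length")
        if self.valley_times.size != self.valley_values.size:
            raise ValueError("valley arrays must share one length")
        if abs(self.n_peaks - self.n_valleys) > 1:
            raise ValueError("peak and valley counts differ by more than one")
        merged = np.concatenate((self.peak_times, self.valley_times))
        kinds = np.concatenate((np.ones(self.n_peaks), np.zeros(self.n_valleys)))
        order = np.argsort(merged)
        if np.any(np.abs(np.diff(kinds[order])) != 1):
            raise ValueError("peaks and valleys must strictly alternate in time")

    @property
    def n_peaks(self) -> int:
        return self.peak_times.size

    @property
    def n_valleys(self) -> int:
        return self.valley_times.size

    @property
    def is_empty(self) -> bool:
        return self.n_peaks == 0 and self.n_valleys == 0


def _empty(units: str) -> BeatAnnotations:
    z = np.empty(0)
    return BeatAnnotations(z, z, z, z, units=units)


def detect_features(trace: SignalTrace, cfg: DetectionConfig | None = None) -> BeatAnnotations:
    """Detect alternating peaks and valleys in a processed PPW trace.

    Each peak is the maximum sample between its flanking threshold crossings
    (ties broken toward the earliest sample); each valley is the minimum
    between consecutive peaks. A flat trace yields empty annotations with a
    warning; NaNs are an error.
    """
    cfg = cfg or DetectionConfig()
    v = trace.values
    if v.size < 2 * cfg.refractory * trace.fs:
        raise ValueError("trace shorter than two refractory periods")
    if not np.all(np.isfinite(v)):
        raise ValueError("trace contains non-finite samples")

    win = max(3, int(round(cfg.adaptive_window * trace.fs)) | 1)
    hi = maximum_filter1d(v, size=win, mode="reflect")
    lo = minimum_filter1d(v, size=win, mode="reflect")
    if float(np.max(hi) - np.min(lo)) < cfg.min_range:
        warnings.warn("trace dynamic range below the configured floor; no beats detected",
                      stacklevel=2)
        return _empty(trace.units)
    rng = hi - lo
    thr_hi = lo + cfg.peak_threshold_frac * rng
    thr_lo = lo + cfg.valley_threshold_frac * rng

    # run-length encode the threshold state: +1 above upper, -1 below lower
    state = np.zeros(v.size, dtype=np.int8)
    state[v >= thr_hi] = 1
    state[v <= thr_lo] = -1
    nz = np.flatnonzero(state)
    if nz.size == 0:
        warnings.warn("no threshold crossings found; no beats detected", stacklevel=2)
        return _empty(trace.units)
    svals = state[nz]
    keep = np.flatnonzero(np.r_[True, svals[1:] != svals[:-1]])
    run_vals = svals[keep]
    run_starts = nz[keep]
    run_ends = np.append(run_starts[1:], v.size)  # region extends to next opposite run

    # candidate extrema, alternating by construction
    cand: list[tuple[int, int, float]] = []  # (kind, index, value); kind +1 peak
    for val, a, b in zip(run_vals, run_starts, run_ends):
        seg = v[a:b]
        i = a + (int(np.argmax(seg)) if val > 0 else int(np.argmin(seg)))
        cand.append((int(val), i, float(v[i])))

    # refractory merge: a peak too close to the previous accepted peak either
    # replaces it (if taller) or is dropped; the valley between them goes too
    ref_n = cfg.refractory * trace.fs
    out: list[tuple[int, int, float]] = []
    for kind, i, val in cand:
        if kind == 1 and out:
            prev_peaks = [k for k in range(len(out)) if out[k][0] == 1]
            if prev_peaks and i - out[prev_peaks[-1]][1] < ref_n:
                j = prev_peaks[-1]
                if val > out[j][2]:
                    del out[j:]            # drop weaker peak and trailing valley
                else:
                    continue               # drop this candidate (and keep valley merged)
        if out and out[-1][0] == kind:
            # merging left two same-kind extrema adjacent; keep the better one
            if (kind == 1 and val > out[-1][2]) or (kind == -1 and val < out[-1][2]):
                out[-1] = (kind, i, val)
            continue
        out.append((kind, i, val))

    peaks = [(i, val) for kind, i, val in out if kind == 1]
    valleys = [(i, val) for kind, i, val in out if kind == -1]
    t = trace.times
    return BeatAnnotations(
        peak_times=t[[i for i, _ in peaks]] if peaks else np.empty(0),
        peak_values=[val for _, val in peaks],
        valley_times=t[[i for i, _ in valleys]] if valleys else np.empty(0),
        valley_values=[val for _, val in valleys],
        units=trace.units,
    )


@dataclass
class BeatPairs:
    """Index pairs (k-th peak, first valley after it) defining beat k."""

    peak_indices: np.ndarray
    valley_indices: np.ndarray
    n_dropped: int = 0

    @property
    def n_beats(self) -> int:
        return self.peak_indices.size


def pair_beats(ann: BeatAnnotations) -> BeatPairs:
    """Match each peak with the valley that follows it.

    A trailing peak with no subsequent valley (trace ended mid-beat) is
    dropped with a log note. Requires the alternation invariant, which
    :class:`BeatAnnotations` enforces on construction.
    """
    if ann.is_empty:
        return BeatPairs(np.empty(0, dtype=int), np.empty(0, dtype=int))
    vidx = np.searchsorted(ann.valley_times, ann.peak_times, side="right")
    ok = vidx < ann.n_valleys
    n_dropped = int(np.count_nonzero(~ok))
    if n_dropped:
        logger.info("pair_beats: dropped %d trailing peak(s) without a following valley",
                    n_dropped)
    return BeatPairs(np.flatnonzero(ok), vidx[ok], n_dropped)
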