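"""Cumulative beat-to-beat blood-pressure tracker.

The measurement principle: anchor the first beat at a cuff reading, then add
up pressure changes inferred from inter-beat voltage changes,

    SBP(k) = SBP_init + sum_{j<k} dV_peak(j)   * 1000 / gain / sensitivity
    DBP(k) = DBP_init + sum_{j<k} dV_valley(j) * 1000 / gain / sensitivity

where dV are adjacent-beat differences of the detected peak/valley voltages
(volts at the amplifier output; the factor 1000 refers them back to
millivolts at the sensor) and sensitivity is the sensor's mV/mmHg slope.
With gain 989 and sensitivity 2 mV/mmHg a 1 mV sensor-referred change is
0.5 mmHg. The accumulation telescopes, so tracking is exact whenever the
chain from pressure to detected voltage is linear and drift-free; residual
baseline drift in the voltages integrates directly into BP error, which the
tracker surfaces as a quality metric rather than silently correcting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .detect import BeatAnnotations, pair_beats

logger = logging.getLogger(__name__)


@dataclass
class TrackerConfig:
    """Anchor values and the voltage-to-pressure conversion constants."""

    init_sbp: float
    init_dbp: float
    gain: float = 989.0
    sensitivity: float = 2.0       # mV per mmHg
    input_units: str = "V"         # "V" (amplified) or "mV" (sensor-referred)

    def __post_init__(self) -> None:
        if not self.init_sbp > self.init_dbp:
            raise ValueError("init_sbp must exceed init_dbp")
        if not self.gain >= 1:
            raise ValueError("gain must be at least 1")
        if not self.sensitivity > 0:
            raise ValueError("sensitivity must be positive")
        if self.input_units not in ("V", "mV"):
            raise ValueError("input_units must be 'V' or 'mV'")


@dataclass
class BPSeries:
    """Beat-indexed SBP/DBP anchored at the initial cuff values."""

    beat_times: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    delta_sbp: np.ndarray
    delta_dbp: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("beat_times", "sbp", "dbp", "delta_sbp", "delta_dbp"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = self.beat_times.size
        if not (self.sbp.size == self.dbp.size == n):
            raise ValueError("beat_times, sbp and dbp must share one length")
        if self.delta_sbp.size != max(n - 1, 0) or self.delta_dbp.size != max(n - 1, 0):
            raise ValueError("delta arrays must have one entry per beat transition")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


def voltage_deltas(values: np.ndarray) -> np.ndarray:
    """Adjacent differences ``values[k+1] - values[k]`` (length n-1)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 1:
        raise ValueError("need at least one value")
    return np.diff(values)


def delta_to_mmhg(delta_v: float | np.ndarray, cfg: TrackerConfig) -> float | np.ndarray:
    """Convert a voltage change to a pressure change in mmHg.

    For amplified output volts: ``dmmHg = dV * 1000 / gain / sensitivity``.
    For sensor-referred millivolts the gain and the volt-to-millivolt factor
    drop out and only the sensitivity divides.
    """
    arr = np.asarray(delta_v, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("voltage change must be finite")
    if cfg.input_units == "V":
        out = arr * 1000.0 / cfg.gain / cfg.sensitivity
    else:
        out = arr / cfg.sensitivity
    return out if isinstance(delta_v, np.ndarray) else float(out)


def track_bp(ann: BeatAnnotations, cfg: TrackerConfig) -> BPSeries:
    """Accumulate per-beat pressure changes onto the cuff anchor.

    Beat timestamps are the systolic peak times. Beats are the (peak,
    following valley) pairs from :func:`piezobp.detect.pair_beats`. The
    result's first beat equals the anchor exactly. Physiologically impossible
    beats (SBP <= DBP) are counted and logged, never clipped; the first-to-
    last valley voltage drift is recorded as a quality metric because any
    baseline drift in the voltages integrates into the cumulative sum.
    """
    if ann.is_empty:
        raise ValueError("cannot track blood pressure from empty annotations")
    pairs = pair_beats(ann)
    if pairs.n_beats == 0:
        raise ValueError("no complete (peak, valley) beats to track")

    peak_v = ann.peak_values[pairs.peak_indices]
    valley_v = ann.valley_values[pairs.valley_indices]
    d_sbp = delta_to_mmhg(voltage_deltas(peak_v), cfg) if peak_v.size > 1 else np.empty(0)
    d_dbp = delta_to_mmhg(voltage_deltas(valley_v), cfg) if valley_v.size > 1 else np.empty(0)
    sbp = cfg.init_sbp + np.concatenate(([0.0], np.cumsum(d_sbp)))
    dbp = cfg.init_dbp + np.concatenate(([0.0], np.cumsum(d_dbp)))

    n_impossible = int(np.count_nonzero(sbp <= dbp))
    if n_impossible:
        logger.warning("track_bp: %d beat(s) with SBP <= DBP; inspect drift quality",
                       n_impossible)
    valley_drift_mmhg = float(delta_to_mmhg(float(valley_v[-1] - valley_v[0]), cfg))
    return BPSeries(
        beat_times=ann.peak_times[pairs.peak_indices],
        sbp=sbp,
        dbp=dbp,
        delta_sbp=d_sbp,
        delta_dbp=d_dbp,
        meta={
            "init_sbp": cfg.init_sbp,
            "init_dbp": cfg.init_dbp,
            "gain": cfg.gain,
            "sensitivity": cfg.sensitivity,
            "n_impossible": n_impossible,
            "valley_drift_mmhg": valley_drift_mmhg,
            "n_dropped_peaks": pairs.n_dropped,
        },
    )
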