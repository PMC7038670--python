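"""Accuracy evaluation against reference cuff measurements.

Device-validation style statistics between tracked values ``y_i`` and
reference values ``x_i`` over ``n`` paired measurements:

    MAE = (1/n) * sum |y_i - x_i|
    SD  = sqrt( sum (y_i - x_i - MAE)^2 / (n - 1) )

The SD formula above ("signed" variant) measures the spread of the
*signed* errors about the mean *absolute* error. That is nonstandard — it is
not invariant under flipping the sign of the errors when MAE > 0 — so an
"absolute" variant (|y_i - x_i| replacing the signed difference) is offered
alongside it. The signed form is the default. The usual device-validation
bounds are MAE within 5 mmHg and SD within 8 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .tracker import BPSeries

SD_VARIANTS = ("signed", "absolute")

#: packaged 30-subject cohort accuracy table (per-subject MAE/SD columns)
COHORT_TABLE_RESOURCE = "cohort_table.csv"


@dataclass
class ReferenceSeries:
    """Timestamped reference cuff readings."""

    times: np.ndarray
    sbp_ref: np.ndarray
    dbp_ref: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.sbp_ref = np.asarray(self.sbp_ref, dtype=np.float64)
        self.dbp_ref = np.asarray(self.dbp_ref, dtype=np.float64)
        if not (self.times.size == self.sbp_ref.size == self.dbp_ref.size):
            raise ValueError("reference arrays must share one length")
        if self.times.size == 0:
            raise ValueError("reference series is empty")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("reference times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class PairedMeasurements:
    """Tracked-vs-reference pairs after nearest-beat matching."""

    times: np.ndarray       # reference timestamps of the kept pairs
    y_sbp: np.ndarray       # tracked
    x_sbp: np.ndarray       # reference
    y_dbp: np.ndarray
    x_dbp: np.ndarray
    gaps: np.ndarray        # |t_ref - t_beat| in seconds
    n_dropped: int

    @property
    def n(self) -> int:
        return self.times.size


@dataclass
class EvalResult:
    """MAE/SD for one quantity (SBP or DBP) plus pairing metadata."""

    n: int
    mae: float
    sd: float
    sd_variant: str
    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        if self.mae < 0 or self.sd < 0:
            raise ValueError("mae and sd must be non-negative")


def pair_reference(bp: BPSeries, ref: ReferenceSeries, max_gap: float = 2.0) -> PairedMeasurements:
    """Match each reference reading to the nearest tracked beat.

    References farther than ``max_gap`` seconds from any beat are dropped
    (counted); zero surviving pairs is an error.
    """
    if not max_gap > 0:
        raise ValueError("max_gap must be positive")
    if bp.n_beats == 0:
        raise ValueError("BP series is empty")
    pos = np.searchsorted(bp.beat_times, ref.times)
    left = np.clip(pos - 1, 0, bp.n_beats - 1)
    right = np.clip(pos, 0, bp.n_beats - 1)
    use_right = np.abs(bp.beat_times[right] - ref.times) < np.abs(bp.beat_times[left] - ref.times)
    nearest = np.where(use_right, right, left)
    gaps = np.abs(bp.beat_times[nearest] - ref.times)
    keep = gaps <= max_gap
    n_dropped = int(np.count_nonzero(~keep))
    if not np.any(keep):
        raise ValueError("no reference reading lies within max_gap of a tracked beat")
    k = nearest[keep]
    return PairedMeasurements(
        times=ref.times[keep],
        y_sbp=bp.sbp[k], x_sbp=ref.sbp_ref[keep],
        y_dbp=bp.dbp[k], x_dbp=ref.dbp_ref[keep],
        gaps=gaps[keep], n_dropped=n_dropped,
    )


def mae(y: np.ndarray, x: np.ndarray) -> float:
    """Mean absolute error between paired series."""
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y.size == 0 or y.size != x.size:
        raise ValueError("need equally sized, non-empty paired series")
    return float(np.mean(np.abs(y - x)))


def sd_about_mae(y: np.ndarray, x: np.ndarray, variant: str = "signed") -> float:
    """Dispersion of the paired errors about the MAE (n-1 denominator).

    ``signed`` uses the signed differences;
    ``absolute`` substitutes |y - x|, giving the ordinary sample SD of the
    absolute errors. The two diverge whenever errors change sign.
    """
    if variant not in SD_VARIANTS:
        raise ValueError(f"variant must be one of {SD_VARIANTS}")
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y.size != x.size:
        raise ValueError("paired series must share one length")
    if y.size < 2:
        raise ValueError("sd requires at least two pairs")
    m = mae(y, x)
    err = np.abs(y - x) if variant == "absolute" else y - x
    return float(np.sqrt(np.sum((err - m) ** 2) / (y.size - 1)))


def _result(y: np.ndarray, x: np.ndarray, t: np.ndarray, variant: str) -> EvalResult:
    pairs = pd.DataFrame({"time_s": t, "y_mmhg": y, "x_mmhg": x})
    return EvalResult(n=int(y.size), mae=mae(y, x), sd=sd_about_mae(y, x, variant),
                      sd_variant=variant, pairs=pairs)


def evaluate_series(
    bp: BPSeries,
    ref: ReferenceSeries,
    max_gap: float = 2.0,
    sd_variant: str = "signed",
) -> dict[str, EvalResult]:
    """Pair and score a tracked series: ``{"sbp": ..., "dbp": ...}``."""
    p = pair_reference(bp, ref, max_gap)
    return {
        "sbp": _result(p.y_sbp, p.x_sbp, p.times, sd_variant),
        "dbp": _result(p.y_dbp, p.x_dbp, p.times, sd_variant),
    }


def load_cohort_table() -> pd.DataFrame:
    """Bundled 30-subject cohort accuracy table (per-subject MAE/SD, mmHg)."""
    with resources.files("piezobp.data").joinpath(COHORT_TABLE_RESOURCE).open() as fh:
        return pd.read_csv(fh)


def summarize_cohort(table: pd.DataFrame) -> dict[str, float]:
    """Unweighted cohort means of the per-subject MAE and SD columns.

    Expects columns ``sbp_mae, sbp_sd, dbp_mae, dbp_sd`` (one row per
    subject), as produced by per-subject :class:`EvalResult` exports or the
    bundled cohort table.
    """
    if len(table) == 0:
        raise ValueError("cohort table is empty")
    required = ("sbp_mae", "sbp_sd", "dbp_mae", "dbp_sd")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    return {c: float(table[c].mean()) for c in required}
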