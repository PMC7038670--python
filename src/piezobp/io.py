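"""CSV readers/writers for traces, ground truth, beat tables and reports.

Traces are two-column CSV (``time_s,value``) with a single leading comment
line carrying the units, sampling rate and start time. All floats are
written with 17 significant digits so a write/read round trip is
bit-identical for float64.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import BeatAnnotations
from .evaluate import EvalResult, ReferenceSeries
from .synthetic import GroundTruthBP
from .tracker import BPSeries

_FLOAT_FMT = "%.17g"
_TRACE_MAGIC = "# piezobp-trace"


def write_trace(trace, path: str | Path) -> None:
    """Write a trace with its units/fs metadata in a header comment."""
    path = Path(path)
    header = f"{_TRACE_MAGIC} units={trace.units} fs={trace.fs!r} t0={trace.t0!r}\n"
    data = np.column_stack((trace.times, trace.values))
    with path.open("w") as fh:
        fh.write(header)
        fh.write("time_s,value\n")
        np.savetxt(fh, data, fmt=_FLOAT_FMT, delimiter=",")


def read_trace(path: str | Path):
    """Read a trace written by :func:`write_trace` (or compatible CSV)."""
    from .trace import SignalTrace

    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith(_TRACE_MAGIC):
            raise ValueError(f"{path}: line 1: missing trace metadata header "
                             f"('{_TRACE_MAGIC} units=... fs=...')")
        meta = dict(tok.split("=", 1) for tok in first[len(_TRACE_MAGIC):].split())
        try:
            fs = float(meta["fs"])
            t0 = float(meta.get("t0", "0"))
            units = meta["units"]
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: line 1: bad metadata header: {exc}") from exc
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except Exception as exc:  # pandas errors carry the offending line
            raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: line 2: expected columns time_s,value")
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +3: header comment, column row, 1-based
            raise ValueError(f"{path}: line {int(bad.idxmax()) + 3}: non-numeric {col}")
    times = df["time_s"].to_numpy(dtype=np.float64)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        k = int(np.flatnonzero(np.diff(times) <= 0)[0])
        raise ValueError(f"{path}: line {k + 4}: time column not strictly increasing")
    return SignalTrace(df["value"].to_numpy(dtype=np.float64), fs=fs, units=units, t0=t0)


def write_ground_truth(gt: GroundTruthBP, path: str | Path) -> None:
    pd.DataFrame({
        "beat_index": np.arange(gt.n_beats),
        "beat_time_s": gt.beat_times,
        "sbp_mmhg": gt.sbp_true,
        "dbp_mmhg": gt.dbp_true,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_beat_table(ann: BeatAnnotations, path: str | Path) -> None:
    """Beat table of paired feature points (one row per complete beat)."""
    from .detect import pair_beats

    pairs = pair_beats(ann)
    pd.DataFrame({
        "beat_index": np.arange(pairs.n_beats),
        "peak_time_s": ann.peak_times[pairs.peak_indices],
        "peak_v": ann.peak_values[pairs.peak_indices],
        "valley_time_s": ann.valley_times[pairs.valley_indices],
        "valley_v": ann.valley_values[pairs.valley_indices],
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_bp_series(bp: BPSeries, path: str | Path, sidecar: str | Path | None = None) -> None:
    """BP series CSV plus an optional JSON sidecar with run metadata."""
    pd.DataFrame({
        "beat_index": np.arange(bp.n_beats),
        "beat_time_s": bp.beat_times,
        "sbp_mmhg": bp.sbp,
        "dbp_mmhg": bp.dbp,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if sidecar is not None:
        Path(sidecar).write_text(json.dumps(bp.meta, indent=2, sort_keys=True) + "\n")


def read_reference(path: str | Path) -> ReferenceSeries:
    """Read a reference cuff series CSV: ``time_s,sbp_mmhg,dbp_mmhg``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    for col in ("time_s", "sbp_mmhg", "dbp_mmhg"):
        if col not in df.columns:
            raise ValueError(f"{path}: expected columns time_s,sbp_mmhg,dbp_mmhg")
    return ReferenceSeries(df["time_s"].to_numpy(), df["sbp_mmhg"].to_numpy(),
                           df["dbp_mmhg"].to_numpy())


def write_reference(ref: ReferenceSeries, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": ref.times,
        "sbp_mmhg": ref.sbp_ref,
        "dbp_mmhg": ref.dbp_ref,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_eval_report(results: dict[str, EvalResult], path: str | Path,
                      extra: dict | None = None) -> None:
    """Evaluation report JSON with MAE/SD for SBP and DBP."""
    sbp, dbp = results["sbp"], results["dbp"]
    report = {
        "n": sbp.n,
        "mae_sbp": sbp.mae, "sd_sbp": sbp.sd,
        "mae_dbp": dbp.mae, "sd_dbp": dbp.sd,
        "sd_variant": sbp.sd_variant,
    }
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
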