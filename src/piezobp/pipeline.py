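"""End-to-end orchestration: simulate -> front-end -> preprocess -> detect ->
track -> evaluate.

The synthetic path runs the full measurement chain on generated data and
scores the tracked series against the simulator's own ground truth; the
external path (:func:`process_trace`) applies the software stages to a
user-supplied voltage trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .config import PipelineConfig
from .detect import BeatAnnotations, detect_features
from .evaluate import EvalResult, ReferenceSeries, evaluate_series
from .frontend import apply_frontend
from .preprocess import preprocess
from .synthetic import (GroundTruthBP, add_baseline_wander, add_noise,
                        extend_ground_truth, simulate_bp_trajectory,
                        synthesize_pressure_waveform, transduce)
from .trace import SignalTrace
from .tracker import BPSeries, TrackerConfig, track_bp

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""


@dataclass
class PipelineResult:
    """Everything a run produced, stage by stage."""

    config: PipelineConfig
    gt: GroundTruthBP | None
    pressure: SignalTrace | None
    sensor: SignalTrace | None
    amplified: SignalTrace | None
    processed: SignalTrace
    annotations: BeatAnnotations
    bp: BPSeries
    reference: ReferenceSeries | None
    evaluation: dict[str, EvalResult] | None
    metadata: dict[str, Any] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}': {exc}") from exc
        return wrapped
    return deco


def true_reference(gt: GroundTruthBP, interval: float) -> ReferenceSeries:
    """Sample the ground truth at regular intervals, like timed cuff readings.

    Each mark takes the true SBP/DBP of the beat whose interval contains it.
    """
    t_end = gt.beat_times[-1] + gt.periods[-1]
    marks = np.arange(interval, t_end + 1e-9, interval)
    if marks.size == 0:
        raise ValueError("recording shorter than one reference interval")
    j = np.clip(np.searchsorted(gt.beat_times, marks, side="right") - 1, 0, gt.n_beats - 1)
    return ReferenceSeries(marks, gt.sbp_true[j], gt.dbp_true[j])


def run_pipeline(
    cfg: PipelineConfig,
    keep_intermediates: bool = False,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full synthetic measurement chain under one configuration.

    The generated recording is padded with constant-BP warm-up beats so the
    causal analog stages settle before the anchored recording starts; the
    padding is cropped after preprocessing, ahead of feature detection.
    """
    seeds = cfg.stage_seeds()
    synth = cfg.synth
    n_beats = synth.resolved_n_beats()

    gt = _stage("simulate")(simulate_bp_trajectory)(
        n_beats, synth.init_sbp, synth.init_dbp, synth.sbp_step_sd,
        synth.dbp_step_sd, synth.heart_rate, seed=seeds["trajectory"])
    logger.info("simulate: %d beats at %.1f bpm", gt.n_beats, synth.heart_rate)

    ext = extend_ground_truth(gt, synth.settle_time, synth.tail_time)
    pressure = _stage("synthesize")(synthesize_pressure_waveform)(ext, cfg.fs)
    pressure = _stage("wander")(add_baseline_wander)(
        pressure, synth.resolved_wander_amplitude(), synth.wander_freq,
        seed=seeds["wander"])

    sensor = _stage("transduce")(transduce)(pressure, cfg.sensor)
    sensor = _stage("noise")(add_noise)(
        sensor, synth.resolved_noise_sd(cfg.sensor.sensitivity), seed=seeds["noise"])
    if sensor.meta.get("n_clipped"):
        logger.warning("transduce: %d clipped samples", sensor.meta["n_clipped"])

    amplified = _stage("frontend")(apply_frontend)(
        sensor, cfg.frontend, bypass=cfg.frontend_bypass,
        zero_phase=cfg.frontend_zero_phase)

    processed = _stage("preprocess")(preprocess)(amplified, cfg.preprocess)
    core_end = gt.beat_times[-1] + gt.periods[-1]
    processed_core = processed.crop(0.0, core_end)
    logger.info("preprocess: cropped to %d samples (%.1f s)",
                len(processed_core), processed_core.duration)

    ann = _stage("detect")(detect_features)(processed_core, cfg.detection)
    logger.info("detect: %d peaks, %d valleys", ann.n_peaks, ann.n_valleys)

    tracker_cfg = TrackerConfig(
        init_sbp=synth.init_sbp, init_dbp=synth.init_dbp,
        gain=float(cfg.frontend.gain), sensitivity=cfg.sensor.sensitivity)
    bp = _stage("track")(track_bp)(ann, tracker_cfg)
    logger.info("track: %d beats, valley drift %.3f mmHg",
                bp.n_beats, bp.meta["valley_drift_mmhg"])

    reference = _stage("reference")(true_reference)(gt, cfg.evaluation.ref_interval)
    evaluation = _stage("evaluate")(evaluate_series)(
        bp, reference, cfg.evaluation.max_gap, cfg.evaluation.sd_variant)

    result = PipelineResult(
        config=cfg, gt=gt, pressure=pressure, sensor=sensor, amplified=amplified,
        processed=processed_core, annotations=ann, bp=bp, reference=reference,
        evaluation=evaluation,
        metadata={"config_digest": cfg.digest(), "seed": cfg.seed,
                  "stage_seeds": seeds, "version": __version__},
    )
    if outdir is not None:
        _persist(result, Path(outdir), keep_intermediates)
    return result


def process_trace(
    trace: SignalTrace,
    cfg: PipelineConfig,
    init_sbp: float,
    init_dbp: float,
    reference: ReferenceSeries | None = None,
) -> PipelineResult:
    """Software stages only, for an externally recorded voltage trace."""
    processed = _stage("preprocess")(preprocess)(trace, cfg.preprocess)
    ann = _stage("detect")(detect_features)(processed, cfg.detection)
    tracker_cfg = TrackerConfig(init_sbp=init_sbp, init_dbp=init_dbp,
                                gain=float(cfg.frontend.gain),
                                sensitivity=cfg.sensor.sensitivity,
                                input_units="V" if trace.units == "V" else "mV")
    bp = _stage("track")(track_bp)(ann, tracker_cfg)
    evaluation = None
    if reference is not None:
        evaluation = _stage("evaluate")(evaluate_series)(
            bp, reference, cfg.evaluation.max_gap, cfg.evaluation.sd_variant)
    return PipelineResult(
        config=cfg, gt=None, pressure=None, sensor=None, amplified=None,
        processed=processed, annotations=ann, bp=bp, reference=reference,
        evaluation=evaluation,
        metadata={"config_digest": cfg.digest(), "seed": cfg.seed,
                  "version": __version__},
    )


def _persist(result: PipelineResult, outdir: Path, keep_intermediates: bool) -> None:
    from . import io

    outdir.mkdir(parents=True, exist_ok=True)
    if result.gt is not None:
        io.write_ground_truth(result.gt, outdir / "ground_truth.csv")
    io.write_beat_table(result.annotations, outdir / "beat_table.csv")
    io.write_bp_series(result.bp, outdir / "bp_series.csv", outdir / "bp_series.json")
    if result.reference is not None:
        io.write_reference(result.reference, outdir / "reference.csv")
    if result.evaluation is not None:
        io.write_eval_report(result.evaluation, outdir / "evaluation.json",
                             extra=result.metadata)
    if keep_intermediates:
        for name in ("pressure", "sensor", "amplified", "processed"):
            tr = getattr(result, name)
            if tr is not None:
                io.write_trace(tr, outdir / f"trace_{name}.csv")
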