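"""Pipeline configuration: one object, one seed, per-stage blocks.

A single global seed fans out deterministically to the stochastic stages
(trajectory walk, wander phase, measurement noise) through a fixed
SeedSequence split, so a (config, seed) pair fully determines every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .detect import DetectionConfig
from .frontend import FrontEndSpec
from .preprocess import PreprocessConfig
from .synthetic import SensorSpec


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant before execution."""


@dataclass
class SynthConfig:
    """Study conditions for the synthetic recording.

    Defaults emulate the validation protocol: a 30-minute resting recording
    at 72 bpm anchored at a 109/61 mmHg cuff reading, beat-to-beat random
    walk steps of 0.5 mmHg, respiratory wander at 0.25 Hz with amplitude 10%
    of the pulse span, and sensor noise with SD 2% of the transduced pulse
    span. ``None`` for the wander amplitude / noise SD selects those
    span-relative defaults at run time.
    """

    duration: float = 1800.0            # seconds; used when n_beats is None
    n_beats: int | None = None
    init_sbp: float = 109.0             # mmHg, cuff anchor
    init_dbp: float = 61.0
    sbp_step_sd: float = 0.5            # mmHg per beat
    dbp_step_sd: float = 0.5
    heart_rate: float = 72.0            # bpm
    wander_amplitude: float | None = None   # mmHg; None -> 10% of pulse span
    wander_freq: float = 0.25           # Hz
    noise_sd: float | None = None       # mV; None -> 2% of transduced span
    settle_time: float = 30.0           # lead-in discarded after filtering, s
    tail_time: float = 5.0              # lead-out discarded after filtering, s

    def __post_init__(self) -> None:
        if not self.init_sbp > self.init_dbp:
            raise ConfigError("init_sbp must exceed init_dbp")
        if self.n_beats is None and not self.duration > 0:
            raise ConfigError("duration must be positive when n_beats is not given")
        if self.n_beats is not None and self.n_beats < 1:
            raise ConfigError("n_beats must be at least 1")
        if self.sbp_step_sd < 0 or self.dbp_step_sd < 0:
            raise ConfigError("step SDs must be non-negative")
        if not self.heart_rate > 0:
            raise ConfigError("heart_rate must be positive")
        if self.settle_time < 0 or self.tail_time < 0:
            raise ConfigError("settle_time and tail_time must be non-negative")

    @property
    def pulse_span(self) -> float:
        """Anchor pulse pressure in mmHg, the span the relative levels use."""
        return self.init_sbp - self.init_dbp

    def resolved_n_beats(self) -> int:
        if self.n_beats is not None:
            return self.n_beats
        return max(1, int(round(self.duration * self.heart_rate / 60.0)))

    def resolved_wander_amplitude(self) -> float:
        if self.wander_amplitude is not None:
            return self.wander_amplitude
        return 0.10 * self.pulse_span

    def resolved_noise_sd(self, sensitivity: float) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return 0.02 * self.pulse_span * sensitivity


@dataclass
class EvalConfig:
    max_gap: float = 2.0                # s, nearest-beat pairing window
    sd_variant: str = "signed"
    ref_interval: float = 60.0          # s between synthetic reference readings

    def __post_init__(self) -> None:
        if not self.max_gap > 0:
            raise ConfigError("max_gap must be positive")
        if not self.ref_interval > 0:
            raise ConfigError("ref_interval must be positive")


@dataclass
class PipelineConfig:
    """Aggregated configuration for the simulate->...->evaluate chain."""

    fs: float = 500.0
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    sensor: SensorSpec = field(default_factory=SensorSpec)
    frontend: FrontEndSpec = field(default_factory=FrontEndSpec)
    frontend_bypass: bool = False
    frontend_zero_phase: bool = False
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ConfigError("fs must be positive")

    # -- seed fan-out ------------------------------------------------------
    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the global seed."""
        state = np.random.SeedSequence(self.seed).generate_state(3, dtype=np.uint64)
        names = ("trajectory", "wander", "noise")
        return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for block in d.values():
            if isinstance(block, dict):
                for k, v in block.items():
                    if isinstance(v, tuple):
                        block[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        blocks = {
            "synth": SynthConfig, "sensor": SensorSpec, "frontend": FrontEndSpec,
            "preprocess": PreprocessConfig, "detection": DetectionConfig,
            "evaluation": EvalConfig,
        }
        kwargs: dict = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if f.name in blocks and isinstance(v, dict):
                try:
                    kwargs[f.name] = blocks[f.name](**v)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"invalid '{f.name}' block: {exc}") from exc
            else:
                kwargs[f.name] = v
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run metadata."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
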