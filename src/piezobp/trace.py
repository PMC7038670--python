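"""Uniformly sampled signal container used throughout the pipeline.

Every stage of the measurement chain (pressure waveform -> sensor voltage ->
amplified voltage -> processed voltage) is carried as a :class:`SignalTrace`,
which pins down the three things that matter when converting between stages:
the sample values, the sampling rate, and the physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: physical units a trace may carry
VALID_UNITS = ("mmHg", "mV", "V")


@dataclass
class SignalTrace:
    """A uniformly sampled series with units.

    Parameters
    ----------
    values : ndarray
        Sample amplitudes. Stored as float64.
    fs : float
        Sampling rate in Hz. Sample ``i`` sits at time ``t0 + i / fs``.
    units : str
        One of ``"mmHg"``, ``"mV"``, ``"V"``.
    t0 : float
        Time of the first sample, in seconds.
    meta : dict
        Free-form provenance (clip counts, applied gain, ...). Propagated by
        transforms; never required for correctness.
    """

    values: np.ndarray
    fs: float
    units: str
    t0: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.values.size / self.fs

    def with_values(self, values: np.ndarray, units: str | None = None, **meta: Any) -> "SignalTrace":
        """Copy of this trace with new sample values (and optionally units).

        Length-preserving transforms should go through this so that ``fs``,
        ``t0`` and accumulated ``meta`` are propagated.
        """
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       units=self.units if units is None else units, meta=new_meta)

    def crop(self, t_start: float | None = None, t_stop: float | None = None) -> "SignalTrace":
        """Slice the trace to ``t_start <= t < t_stop`` (inclusive of start)."""
        t = self.times
        lo = 0 if t_start is None else int(np.searchsorted(t, t_start - 1e-12))
        hi = len(t) if t_stop is None else int(np.searchsorted(t, t_stop - 1e-12))
        return replace(self, values=self.values[lo:hi].copy(), t0=float(t[lo]) if lo < len(t) else self.t0,
                       meta=dict(self.meta))
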