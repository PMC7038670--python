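import numpy as np
import pytest

from piezobp import simulate_bp_trajectory, synthesize_pressure_waveform


def per_beat_extrema(trace, gt):
    """Brute-force oracle: scan each beat interval for its max/min sample."""
    t = trace.times
    bounds = np.append(gt.beat_times, gt.beat_times[-1] + gt.periods[-1])
    maxima, minima = [], []
    for k in range(gt.n_beats):
        lo = np.searchsorted(t, bounds[k] - 1e-12)
        hi = np.searchsorted(t, bounds[k + 1] - 1e-12)
        seg = trace.values[lo:hi]
        maxima.append(seg.max())
        minima.append(seg.min())
    return np.array(maxima), np.array(minima)


@pytest.fixture
def gt12():
    """12 beats at 72 bpm anchored at 109/61 with mild beat-to-beat variation."""
    return simulate_bp_trajectory(12, 109.0, 61.0, 0.5, 0.5, 72.0, seed=7)


@pytest.fixture
def wave12(gt12):
    return synthesize_pressure_waveform(gt12, fs=500.0)
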