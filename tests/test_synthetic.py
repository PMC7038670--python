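"""Ground-truth trajectories, waveform synthesis, transduction and noise."""

import numpy as np
import pytest

from piezobp import (GroundTruthBP, PulseMorphology, SensorSpec, SignalTrace,
                     add_baseline_wander, add_noise, extend_ground_truth,
                     simulate_bp_trajectory, synthesize_pressure_waveform,
                     transduce)
from conftest import per_beat_extrema


class TestTrajectory:
    def test_zero_variance_walk_is_constant(self):
        gt = simulate_bp_trajectory(12, 109, 61, 0.0, 0.0, 72, seed=1)
        assert np.all(gt.sbp_true == 109.0)
        assert np.all(gt.dbp_true == 61.0)
        assert gt.n_beats == 12

    def test_first_beat_is_the_anchor(self):
        gt = simulate_bp_trajectory(1, 120, 80, 3.0, 3.0, 60, seed=42)
        assert gt.sbp_true[0] == 120.0 and gt.dbp_true[0] == 80.0

    def test_step_sd_matches_request(self):
        # Monte-Carlo check of the walk's step distribution
        gt = simulate_bp_trajectory(1000, 109, 61, 0.5, 0.5, 72, seed=7)
        steps = np.diff(gt.sbp_true)
        assert np.std(steps, ddof=1) == pytest.approx(0.5, rel=0.10)

    def test_reflecting_bounds_and_pressure_order(self):
        gt = simulate_bp_trajectory(5000, 109, 61, 3.0, 3.0, 72, seed=3)
        assert gt.sbp_true.min() >= 70 and gt.sbp_true.max() <= 190
        assert gt.dbp_true.max() <= 100
        assert np.all(gt.sbp_true > gt.dbp_true)

    def test_beat_times_follow_heart_rate(self):
        gt = simulate_bp_trajectory(10, 109, 61, 0, 0, 75, seed=0)
        assert np.allclose(np.diff(gt.beat_times), 60.0 / 75.0)

    def test_reproducible_for_fixed_seed(self):
        a = simulate_bp_trajectory(50, 109, 61, 1, 1, 72, seed=5)
        b = simulate_bp_trajectory(50, 109, 61, 1, 1, 72, seed=5)
        assert np.array_equal(a.sbp_true, b.sbp_true)
        assert np.array_equal(a.dbp_true, b.dbp_true)

    @pytest.mark.parametrize("kwargs", [
        dict(n_beats=0), dict(init_sbp=80, init_dbp=90), dict(sbp_step_sd=-1),
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        args = dict(n_beats=5, init_sbp=109, init_dbp=61,
                    sbp_step_sd=0.5, dbp_step_sd=0.5)
        args.update(kwargs)
        with pytest.raises(ValueError):
            simulate_bp_trajectory(**args)


class TestWaveform:
    def test_constant_bp_extrema_exact(self):
        gt = simulate_bp_trajectory(6, 109, 61, 0, 0, 72, seed=1)
        tr = synthesize_pressure_waveform(gt, fs=500)
        assert tr.values.max() == pytest.approx(109.0, abs=1e-12)
        assert tr.values.min() == pytest.approx(61.0, abs=1e-12)
        assert tr.units == "mmHg"

    def test_single_beat_global_extrema(self):
        gt = simulate_bp_trajectory(1, 120, 80, 0, 0, 72, seed=1)
        tr = synthesize_pressure_waveform(gt, fs=500)
        assert tr.values.max() == pytest.approx(120.0, abs=1e-9)
        assert tr.values.min() == pytest.approx(80.0, abs=1e-9)

    def test_per_beat_extrema_match_ground_truth(self, gt12, wave12):
        # oracle: independent brute-force scan over each beat interval
        maxima, minima = per_beat_extrema(wave12, gt12)
        np.testing.assert_allclose(maxima, gt12.sbp_true, atol=1e-9)
        np.testing.assert_allclose(minima, gt12.dbp_true, atol=1e-9)

    def test_minimum_sits_at_the_terminating_foot(self, gt12, wave12):
        # diastolic runoff puts each beat's minimum in late diastole
        t = wave12.times
        bounds = np.append(gt12.beat_times, gt12.beat_times[-1] + gt12.periods[-1])
        for k in range(gt12.n_beats):
            lo = np.searchsorted(t, bounds[k])
            hi = np.searchsorted(t, bounds[k + 1] - 1e-12)
            imin = lo + np.argmin(wave12.values[lo:hi])
            phase = (t[imin] - bounds[k]) / (bounds[k + 1] - bounds[k])
            assert phase > 0.8

    def test_low_fs_rejected(self, gt12):
        with pytest.raises(ValueError):
            synthesize_pressure_waveform(gt12, fs=50)

    def test_degenerate_morphology_rejected(self, gt12):
        with pytest.raises(ValueError):
            synthesize_pressure_waveform(
                gt12, 500, PulseMorphology(widths=(0.0, 0.1)))

    def test_extension_pads_constant_beats(self, gt12):
        ext = extend_ground_truth(gt12, lead_time=5.0, tail_time=2.0)
        n_lead = ext.n_beats - gt12.n_beats - int(np.ceil(2.0 / (60 / 72)))
        assert ext.beat_times[0] < 0
        assert np.all(ext.sbp_true[:n_lead] == gt12.sbp_true[0])
        assert np.allclose(ext.beat_times[n_lead:n_lead + gt12.n_beats], gt12.beat_times)


class TestWanderNoiseTransduce:
    def test_zero_amplitude_wander_is_identity(self, wave12):
        out = add_baseline_wander(wave12, 0.0, 0.25, seed=9)
        assert np.array_equal(out.values, wave12.values)

    def test_sinusoid_range_on_dc_input(self):
        tr = SignalTrace(np.full(8000, 5.0), fs=100, units="mmHg")
        out = add_baseline_wander(tr, amplitude=1.0, resp_freq=0.25)
        assert out.values.max() - out.values.min() == pytest.approx(2.0, rel=1e-3)

    def test_wander_rejects_negative_amplitude(self, wave12):
        with pytest.raises(ValueError):
            add_baseline_wander(wave12, -1.0)

    def test_transduction_is_linear_with_sensitivity_slope(self):
        tr = SignalTrace(np.array([0.0, 1.0, 100.0]), fs=10, units="mmHg")
        out = transduce(tr, SensorSpec(sensitivity=2.0))
        assert out.units == "mV"
        np.testing.assert_allclose(out.values, [0.0, 2.0, 200.0])
        assert out.meta["n_clipped"] == 0

    def test_transduction_clips_outside_rated_range(self):
        tr = SignalTrace(np.array([5000.0, 100.0, -80.0]), fs=10, units="mmHg")
        with pytest.warns(UserWarning, match="clipped"):
            out = transduce(tr, SensorSpec(2.0, -50.0, 3000.0))
        np.testing.assert_allclose(out.values, [6000.0, 200.0, -100.0])
        assert out.meta["n_clipped"] == 2

    def test_transduce_requires_pressure_units(self):
        tr = SignalTrace(np.zeros(4), fs=10, units="mV")
        with pytest.raises(ValueError):
            transduce(tr, SensorSpec())

    def test_noise_sd_and_determinism(self):
        tr = SignalTrace(np.zeros(200_000), fs=500, units="mV")
        a = add_noise(tr, 1.0, seed=11)
        b = add_noise(tr, 1.0, seed=11)
        assert np.std(a.values) == pytest.approx(1.0, rel=0.02)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(add_noise(tr, 0.0, seed=1).values, tr.values)


class TestInvariantValidation:
    def test_ground_truth_rejects_sbp_below_dbp(self):
        with pytest.raises(ValueError):
            GroundTruthBP([0.0], [80.0], [90.0], [72.0])

    def test_ground_truth_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            GroundTruthBP([0.0, -1.0], [109, 110], [61, 62], [72, 72])
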