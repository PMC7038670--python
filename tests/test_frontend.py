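"""Analog front-end: gain law, cutoffs, Bode sweep, time-domain equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piezobp import (FrontEndSpec, SignalTrace, apply_frontend,
                     cutoff_from_components, frequency_response, gain_from_rg,
                     transfer_magnitude)


class TestGainAndCutoffs:
    @pytest.mark.parametrize("rg,expected", [
        (50.0, 989.0),            # the hardware design point
        (49_400.0, 2.0),
        (1e12, pytest.approx(1.0, abs=1e-6)),   # large-resistor limit
    ])
    def test_gain_law(self, rg, expected):
        assert gain_from_rg(rg) == expected

    def test_gain_rejects_nonpositive_resistor(self):
        with pytest.raises(ValueError):
            gain_from_rg(0.0)

    @given(st.floats(min_value=1.0, max_value=1e6),
           st.floats(min_value=1.0, max_value=1e6))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_gain_strictly_decreasing_in_rg(self, rg, delta):
        assert gain_from_rg(rg + delta) < gain_from_rg(rg)

    @pytest.mark.parametrize("r,c,expected", [
        (1.0 / (2 * np.pi), 1.0, pytest.approx(1.0, rel=1e-12)),
        (1.0, 1.0, pytest.approx(1 / (2 * np.pi), rel=1e-12)),
        (5.3e6, 1e-6, pytest.approx(0.0300, abs=2e-4)),  # AC-coupling design value
    ])
    def test_rc_cutoff(self, r, c, expected):
        assert cutoff_from_components(r, c) == expected


class TestTransferMagnitude:
    def test_isolated_lowpass_at_cutoff_is_half_power(self):
        spec = FrontEndSpec(rg=1e15, fc_ac=0.0, fc_hpf=0.0, fc_lpf=35.0)
        assert transfer_magnitude(spec, 35.0) == pytest.approx(2 ** -0.5, rel=1e-9)

    def test_default_midband_is_roughly_the_gain(self):
        mag = transfer_magnitude(FrontEndSpec(), 1.0)
        assert 20 * np.log10(mag) == pytest.approx(59.9, abs=0.05)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_magnitude_never_exceeds_gain(self, f):
        spec = FrontEndSpec()
        assert transfer_magnitude(spec, f) <= spec.gain


def _random_specs():
    return st.builds(
        FrontEndSpec,
        rg=st.floats(min_value=5.0, max_value=49_400.0),
        fc_ac=st.floats(min_value=0.005, max_value=0.05),
        fc_hpf=st.floats(min_value=0.06, max_value=1.0),
        fc_lpf=st.floats(min_value=5.0, max_value=100.0),
        order_hpf=st.integers(min_value=1, max_value=4),
        order_lpf=st.integers(min_value=1, max_value=4),
    )


class TestFrequencyResponse:
    def test_default_sweep_reproduces_design_values(self):
        fr = frequency_response(FrontEndSpec(), 1e-3, 1e3, 2000)
        assert fr.midband_db == pytest.approx(59.9, abs=0.1)
        assert 0.05 <= fr.f_low_3db <= 0.06
        assert fr.f_high_3db == pytest.approx(35.0, rel=0.01)

    def test_isolated_butterworth_upper_cutoff_is_exact(self):
        spec = FrontEndSpec(rg=1e15, fc_ac=0.0, fc_hpf=0.0, fc_lpf=35.0)
        fr = frequency_response(spec, 1e-2, 1e3, 4000)
        assert fr.f_high_3db == pytest.approx(35.0, rel=1e-3)
        assert np.isnan(fr.f_low_3db)  # no lower roll-off to cross

    def test_doubling_gain_shifts_midband_not_cutoffs(self):
        lo = frequency_response(FrontEndSpec(rg=100.0))
        hi = frequency_response(FrontEndSpec(gain=2 * gain_from_rg(100.0)))
        assert hi.midband_db - lo.midband_db == pytest.approx(20 * np.log10(2), abs=1e-6)
        assert hi.f_low_3db == pytest.approx(lo.f_low_3db, rel=1e-9)
        assert hi.f_high_3db == pytest.approx(lo.f_high_3db, rel=1e-9)

    @given(_random_specs())
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_sweep_invariants(self, spec):
        fr = frequency_response(spec, 1e-4, 1e4, 2000)
        assert fr.midband_db == np.max(fr.magnitude_db)
        assert fr.f_low_3db < fr.f_high_3db
        for f in (fr.f_low_3db, fr.f_high_3db):
            mag_db = 20 * np.log10(transfer_magnitude(spec, f))
            assert mag_db == pytest.approx(fr.midband_db - 10 * np.log10(2), abs=0.02)

    def test_invalid_sweep_rejected(self):
        with pytest.raises(ValueError):
            frequency_response(FrontEndSpec(), 1.0, 0.1)


def _steady_amplitude(trace, skip_s):
    v = trace.values[int(skip_s * trace.fs):]
    return np.sqrt(2.0) * np.std(v)


class TestTimeDomain:
    def test_midband_sinusoid_amplified_by_gain(self):
        fs = 500.0
        t = np.arange(int(90 * fs)) / fs
        tr = SignalTrace(np.sin(2 * np.pi * 1.0 * t), fs=fs, units="mV")
        out = apply_frontend(tr, FrontEndSpec())
        assert out.units == "V"
        assert _steady_amplitude(out, 60) == pytest.approx(0.989, rel=0.01)

    @pytest.mark.parametrize("f", [0.1, 1.0, 5.0, 20.0])
    def test_agreement_with_transfer_magnitude(self, f):
        spec = FrontEndSpec()
        fs = 500.0
        dur = max(120.0, 30.0 / f)
        t = np.arange(int(dur * fs)) / fs
        out = apply_frontend(SignalTrace(np.sin(2 * np.pi * f * t), fs=fs, units="mV"), spec)
        expected_v = transfer_magnitude(spec, f) / 1000.0
        assert _steady_amplitude(out, dur / 2) == pytest.approx(expected_v, rel=0.01)

    def test_dc_input_decays_to_zero(self):
        fs = 200.0
        tr = SignalTrace(np.ones(int(300 * fs)), fs=fs, units="mV")
        out = apply_frontend(tr, FrontEndSpec())
        # AC-coupling removes DC; after several time constants nothing is left
        assert np.max(np.abs(out.values[-int(10 * fs):])) < 1e-3 * 0.989

    def test_bypass_is_exact_flat_gain(self, wave12):
        from piezobp import transduce
        mv = transduce(wave12)
        out = apply_frontend(mv, FrontEndSpec(), bypass=True)
        np.testing.assert_allclose(out.values, mv.values * 989.0 / 1000.0, rtol=1e-14)

    def test_low_fs_rejected(self):
        tr = SignalTrace(np.zeros(100), fs=50.0, units="mV")
        with pytest.raises(ValueError):
            apply_frontend(tr, FrontEndSpec(fc_lpf=35.0))

    def test_wrong_units_rejected(self, wave12):
        with pytest.raises(ValueError):
            apply_frontend(wave12, FrontEndSpec())
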