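"""Beer-Lambert conversion and filter-bank design/application."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import signal

from fnirskit.errors import ConfigurationError, ProcessingError
from fnirskit.haemodynamics import (
    BeerLambertConfig,
    apply_filter,
    attenuation_change,
    design_baseline_highpass,
    design_lowpass,
    design_notch,
    mbll,
)


class TestAttenuationChange:
    def test_trace_at_baseline_gives_zero(self):
        assert np.allclose(attenuation_change(np.full(10, 2.0), 2.0), 0.0)

    def test_tenfold_drop_gives_unity(self):
        assert np.allclose(attenuation_change(np.full(10, 0.2), 2.0), 1.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        trace = rng.uniform(0.5, 2.0, 100)
        baseline = trace.mean()
        np.testing.assert_allclose(
            attenuation_change(trace, baseline), np.log10(baseline / trace)
        )

    def test_non_positive_sample_names_index(self):
        trace = np.array([1.0, 1.0, -0.5, 1.0])
        with pytest.raises(ProcessingError, match="sample 2"):
            attenuation_change(trace, 1.0)


class TestMbll:
    def test_zero_attenuation_maps_to_zero(self):
        hbr, hbo = mbll(np.zeros(5), np.zeros(5))
        assert np.allclose(hbr, 0) and np.allclose(hbo, 0)

    def test_forward_backward_round_trip(self):
        # forward matrix product (attenuation from known concentrations)
        # is the oracle; inversion must recover them to 1e-10 relative
        rng = np.random.default_rng(1)
        config = BeerLambertConfig()
        dc = rng.standard_normal((2, 200)) * 1e-3  # (Hb, HbO2)
        dA = config.extinction @ dc
        dA760 = dA[0] * config.dpf[0] * config.distance
        dA850 = dA[1] * config.dpf[1] * config.distance
        hbr, hbo = mbll(dA760, dA850, config)
        np.testing.assert_allclose(hbr, dc[0], rtol=1e-10, atol=1e-16)
        np.testing.assert_allclose(hbo, dc[1], rtol=1e-10, atol=1e-16)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ConfigurationError):
            BeerLambertConfig(extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))

    @given(
        a=st.floats(-5, 5), b=st.floats(-5, 5),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        dA1 = rng.standard_normal((2, 20)) * 0.01
        dA2 = rng.standard_normal((2, 20)) * 0.01
        combo = np.array(mbll(a * dA1[0] + b * dA2[0], a * dA1[1] + b * dA2[1]))
        parts = a * np.array(mbll(dA1[0], dA1[1])) + b * np.array(mbll(dA2[0], dA2[1]))
        np.testing.assert_allclose(combo, parts, atol=1e-12)


class TestNotchDesign:
    def test_attenuation_at_50hz(self):
        spec = design_notch(256)
        grid = np.arange(45, 55, 0.001)
        mags = spec.magnitude_db(grid)
        assert mags[np.abs(grid - 50.0).argmin()] < -30

    def test_minimum_sits_at_50hz(self):
        spec = design_notch(256)
        grid = np.arange(40, 60, 0.001)
        assert grid[spec.magnitude_db(grid).argmin()] == pytest.approx(50.0, abs=0.01)

    def test_bandwidth_is_1_43hz(self):
        spec = design_notch(256)
        grid = np.arange(45, 55, 0.0005)
        mags = spec.magnitude_db(grid)
        below = grid[mags < -3.0103]
        assert below[-1] - below[0] == pytest.approx(1.43, abs=0.02)

    def test_unity_gain_away_from_notch(self):
        spec = design_notch(256)
        gain = np.abs(spec.response(np.array([10.0])))[0]
        assert abs(gain - 1.0) < 0.01

    def test_low_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            design_notch(90.0)


class TestBaselineHighpass:
    def test_order_is_six(self):
        assert design_baseline_highpass(3.91).order == 6

    def test_edge_drop_within_passband_ripple(self):
        spec = design_baseline_highpass(3.91)
        assert spec.magnitude_db(np.array([0.005]))[0] >= -1.0 - 1e-6

    def test_dc_blocked(self):
        spec = design_baseline_highpass(3.91)
        assert np.abs(spec.response(np.array([0.0])))[0] < 1e-9

    def test_stopband_reaches_30db(self):
        spec = design_baseline_highpass(3.91)
        assert spec.magnitude_db(np.array([0.002]))[0] < -30


class TestLowpass:
    def test_order_is_eight(self):
        assert design_lowpass(3.91, 0.5).order == 8

    def test_edge_drop_within_passband_ripple(self):
        spec = design_lowpass(3.91, 0.5)
        assert spec.magnitude_db(np.array([0.5]))[0] >= -3.0 - 1e-6

    def test_dc_gain_unity(self):
        spec = design_lowpass(3.91, 0.5)
        assert np.abs(spec.response(np.array([0.0])))[0] == pytest.approx(1.0, abs=1e-9)

    def test_stopband_reaches_30db(self):
        spec = design_lowpass(3.91, 0.5)
        assert spec.magnitude_db(np.array([1.2]))[0] < -30

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            design_lowpass(3.91, 2.5)


class TestApplyFilter:
    def test_zeros_in_zeros_out(self):
        spec = design_lowpass(3.91, 0.5)
        assert np.allclose(apply_filter(np.zeros(100), spec), 0.0)

    def test_slow_drift_removed_by_baseline_highpass(self):
        rate = 3.91
        t = np.arange(int(1200 * rate)) / rate
        drift = np.sin(2 * np.pi * 0.001 * t)
        spec = design_baseline_highpass(rate)
        out = apply_filter(drift, spec)
        # skip the filter's start-up transient before comparing variances
        tail = slice(len(out) // 2, None)
        assert np.var(out[tail]) < 0.10 * np.var(drift[tail])

    @pytest.mark.parametrize("factory", [
        lambda: design_notch(256),
        lambda: design_baseline_highpass(3.91),
        lambda: design_lowpass(3.91, 0.5),
    ])
    def test_impulse_response_decays(self, factory):
        spec = factory()
        impulse = np.zeros(200_000)
        impulse[0] = 1.0
        out = signal.sosfilt(spec.sos, impulse)
        assert np.max(np.abs(out[-1000:])) < 1e-6

    def test_too_short_signal_rejected(self):
        spec = design_lowpass(3.91, 0.5)
        with pytest.raises(ProcessingError):
            apply_filter(np.zeros(10), spec)

    def test_ten_minute_trace_mean_removed(self):
        # mean-referenced trace with a slow drift, as the conversion stage
        # produces: after the baseline high-pass the residual mean is tiny
        rate = 3.91
        rng = np.random.default_rng(3)
        n = int(600 * rate)
        t = np.arange(n) / rate
        trace = 0.5 * np.sin(2 * np.pi * 0.002 * t) + rng.standard_normal(n)
        trace -= trace.mean()
        out = apply_filter(trace, design_baseline_highpass(rate))
        assert abs(out.mean()) < 0.01 * out.std()
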