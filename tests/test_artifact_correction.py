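"""Spectral peak search, CAR, SOBI and transfer-function correction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fnirskit.artifact_correction import (
    ArtifactDefinition,
    PowerSpectrum,
    apply_tf_correction,
    car,
    correct_block,
    find_artifact_peak,
    fit_tf_model,
    power_spectrum,
    remove_components,
    select_artifact_components,
    sobi,
)
from fnirskit.errors import ProcessingError
from fnirskit.haemodynamics import ConcentrationBlock
from fnirskit.physio import RegressorSet

RATE = 3.91


class TestPowerSpectrum:
    def test_tone_peaks_at_its_frequency(self):
        t = np.arange(int(300 * RATE)) / RATE
        rng = np.random.default_rng(0)
        trace = np.sin(2 * np.pi * 0.3 * t) + rng.normal(0, 1e-3, t.size)
        spec = power_spectrum(trace, RATE)
        peak = spec.frequencies[np.argmax(spec.power_db)]
        assert peak == pytest.approx(0.3, abs=spec.resolution)

    @pytest.mark.parametrize("seed", range(10))
    def test_white_noise_is_flat(self, seed):
        rng = np.random.default_rng(seed)
        trace = rng.standard_normal(int(1200 * RATE))
        spec = power_spectrum(trace, RATE)
        band = (spec.frequencies > 0.05) & (spec.frequencies < 1.8)
        # median power in lower vs upper half of the band differs < 3 dB
        freqs = spec.frequencies[band]
        power = spec.power_db[band]
        mid = freqs.mean()
        assert abs(np.median(power[freqs < mid]) - np.median(power[freqs > mid])) < 3

    def test_doubling_amplitude_adds_6db(self):
        t = np.arange(int(300 * RATE)) / RATE
        tone = np.sin(2 * np.pi * 0.3 * t)
        p1 = power_spectrum(tone, RATE)
        p2 = power_spectrum(2 * tone, RATE)
        assert p2.power_db.max() - p1.power_db.max() == pytest.approx(6.02, abs=0.1)

    def test_empty_signal_rejected(self):
        with pytest.raises(ProcessingError):
            power_spectrum(np.empty(0), RATE)


class TestFindArtifactPeak:
    mth = ArtifactDefinition("MTH", (0.07, 0.13))

    def test_mayer_tone_found(self):
        t = np.arange(int(600 * RATE)) / RATE
        rng = np.random.default_rng(1)
        trace = np.sin(2 * np.pi * 0.10 * t) + rng.normal(0, 0.05, t.size)
        spec = power_spectrum(trace, RATE)
        peak = find_artifact_peak(spec, self.mth)
        assert peak == pytest.approx(0.10, abs=spec.resolution)

    def test_flat_spectrum_not_found(self):
        freqs = np.linspace(0, RATE / 2, 512)
        flat = PowerSpectrum(freqs, np.zeros_like(freqs), freqs[1] - freqs[0])
        assert find_artifact_peak(flat, self.mth) is None

    def test_tie_break_prefers_lower_frequency(self):
        freqs = np.linspace(0, RATE / 2, 1000)
        power = np.zeros_like(freqs)
        in_window = (freqs >= 0.07) & (freqs <= 0.13)
        idx = np.flatnonzero(in_window)
        power[idx[2]] = power[idx[-3]] = 10.0
        spec = PowerSpectrum(freqs, power, freqs[1] - freqs[0])
        assert find_artifact_peak(spec, self.mth) == pytest.approx(freqs[idx[2]])


class TestCar:
    def test_identical_channels_cancel(self):
        data = np.tile(np.arange(5.0), (4, 1))
        out = car(ConcentrationBlock(data, data, RATE))
        assert np.allclose(out.hbo, 0) and np.allclose(out.hbr, 0)

    def test_two_channel_hand_example(self):
        hbo = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = car(ConcentrationBlock(hbo, hbo, RATE))
        np.testing.assert_allclose(out.hbo, [[-1.0, -1.0], [1.0, 1.0]])

    @given(seed=st.integers(0, 2**16), n_ch=st.integers(2, 8))
    def test_cross_channel_mean_exactly_zero(self, seed, n_ch):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n_ch, 30))
        out = car(ConcentrationBlock(data, -data, RATE))
        assert np.abs(out.hbo.mean(axis=0)).max() < 1e-12
        assert np.abs(out.hbr.mean(axis=0)).max() < 1e-12

    def test_single_channel_rejected(self):
        block = ConcentrationBlock(np.ones((1, 10)), np.ones((1, 10)), RATE)
        with pytest.raises(ProcessingError):
            car(block)


def _narrowband_sources(freqs, n_samples, rate, seed):
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / rate
    return np.vstack(
        [np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) for f in freqs]
    )


def _best_correlations(sources, recovered):
    corr = np.corrcoef(np.vstack([sources, recovered]))[: len(sources), len(sources):]
    return np.abs(corr).max(axis=1)


class TestSobi:
    def test_two_tone_mixture_recovered(self):
        sources = _narrowband_sources([0.1, 0.3], 2000, RATE, 0)
        mixing = np.array([[1.0, 0.6], [-0.4, 1.2]])
        dec = sobi(mixing @ sources)
        assert np.all(_best_correlations(sources, dec.sources) > 0.95)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n_sources", [2, 3, 4])
    def test_recovery_across_seeds(self, seed, n_sources):
        freqs = [0.08, 0.3, 0.7, 1.2][:n_sources]
        sources = _narrowband_sources(freqs, 2000, RATE, seed)
        rng = np.random.default_rng(100 + seed)
        mixing = rng.uniform(-1, 1, (n_sources, n_sources))
        mixing += n_sources * np.eye(n_sources) * np.sign(np.diag(mixing))
        dec = sobi(mixing @ sources)
        assert np.all(_best_correlations(sources, dec.sources) > 0.95)

    def test_reconstruction_is_exact(self):
        sources = _narrowband_sources([0.1, 0.3, 0.7], 1500, RATE, 2)
        mixed = np.array([[1.0, 0.3, 0.1], [0.2, 1.0, 0.4], [0.1, 0.2, 1.0]]) @ sources
        dec = sobi(mixed)
        assert np.abs(dec.reconstruct() - mixed).max() < 1e-8

    def test_uncorrelated_input_gives_near_trivial_mixing(self):
        # channels that are already independent sources: the mixing matrix
        # must come back as (a scaled permutation of) the identity
        rng = np.random.default_rng(3)
        data = _narrowband_sources([0.1, 0.3, 0.7], 5000, RATE, 3)
        data = data + rng.normal(0, 1e-3, data.shape)
        dec = sobi(data)
        A = np.abs(dec.mixing) / np.abs(dec.mixing).max(axis=0, keepdims=True)
        for col in A.T:
            assert np.sort(col)[-1] > 0.9 and np.sort(col)[-2] < 0.3

    def test_rank_deficient_covariance_advises_exclusion(self):
        trace = np.sin(np.arange(1000) / 10)
        with pytest.raises(ProcessingError, match="exclude"):
            sobi(np.vstack([trace, trace]))


class TestComponentSelection:
    def test_pure_band_tone_selected(self):
        sources = _narrowband_sources([0.1, 1.2], 2000, RATE, 4)
        mth = ArtifactDefinition("MTH", (0.07, 0.13))
        from fnirskit.artifact_correction import ICADecomposition

        dec = ICADecomposition(np.eye(2), sources, np.zeros(2))
        picked = select_artifact_components(dec, [mth], None, RATE)
        assert picked == [0]

    def test_white_components_not_selected(self):
        rng = np.random.default_rng(5)
        from fnirskit.artifact_correction import ICADecomposition

        dec = ICADecomposition(np.eye(3), rng.standard_normal((3, 4000)), np.zeros(3))
        arts = [ArtifactDefinition("MTH", (0.07, 0.13))]
        assert select_artifact_components(dec, arts, None, RATE) == []

    def test_regressor_correlation_rule(self):
        rng = np.random.default_rng(6)
        ref = rng.standard_normal(2000)  # broadband: band rule cannot fire
        from fnirskit.artifact_correction import ICADecomposition

        dec = ICADecomposition(
            np.eye(2), np.vstack([ref, rng.standard_normal(2000)]), np.zeros(2)
        )
        regs = RegressorSet({"RF": ref - ref.mean()})
        arts = [ArtifactDefinition("RF", (0.2, 0.4))]
        assert select_artifact_components(dec, arts, regs, RATE) == [0]


class TestRemoveComponents:
    def _decomposition(self):
        sources = _narrowband_sources([0.1, 0.4], 1500, RATE, 7)
        mixing = np.array([[1.0, 0.5], [0.3, 1.0]])
        return sobi(mixing @ sources), sources

    def test_empty_selection_is_identity(self):
        dec, sources = self._decomposition()
        original = dec.reconstruct()
        np.testing.assert_allclose(remove_components(dec, []), original, atol=1e-8)

    def test_removing_all_leaves_channel_means(self):
        dec, _ = self._decomposition()
        out = remove_components(dec, [0, 1])
        np.testing.assert_allclose(out, dec.means[:, None] * np.ones_like(out))

    def test_removing_artifact_source_keeps_the_other(self):
        dec, sources = self._decomposition()
        # find which recovered component matches the 0.4 Hz source
        corr = _best_correlations(sources[1:2], dec.sources)
        target = int(np.argmax([abs(np.corrcoef(sources[1], s)[0, 1]) for s in dec.sources]))
        cleaned = remove_components(dec, [target])
        r = abs(np.corrcoef(cleaned[0], sources[0])[0, 1])
        assert r > 0.95

    def test_out_of_range_index_rejected(self):
        dec, _ = self._decomposition()
        with pytest.raises(ProcessingError):
            remove_components(dec, [5])


class TestTfModel:
    def test_exact_proportionality_order_zero(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(500)
        model = fit_tf_model(2.0 * y, y, m=0)
        assert model.coefficients[0] == pytest.approx(2.0, abs=1e-9)

    def test_known_taps_recovered_under_noise(self):
        from fnirskit.synthetic import make_tf_fixture

        taps = np.array([1.0, -0.5, 0.25])
        x, y, truth = make_tf_fixture(taps, n_samples=2000, noise_sd=0.01, seed=9)
        model = fit_tf_model(x, y, m=2)
        np.testing.assert_allclose(model.coefficients, truth.taps, atol=0.02)

    def test_order_zero_equals_regression_slope(self):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(800)
        y -= y.mean()
        x = 1.7 * y + rng.normal(0, 0.1, y.size)
        model = fit_tf_model(x, y, m=0)
        slope = np.cov(x, y)[0, 1] / np.var(y, ddof=1)  # closed-form oracle
        assert model.coefficients[0] == pytest.approx(slope, abs=1e-2)

    def test_constant_regressor_rejected(self):
        with pytest.raises(ProcessingError, match="singular|constant"):
            fit_tf_model(np.arange(200.0), np.ones(200), m=1)


class TestTfCorrection:
    def test_zero_coefficients_identity(self):
        from fnirskit.artifact_correction import TFModel

        x = np.arange(50.0)
        out = apply_tf_correction(x, np.ones(50), TFModel(2, np.zeros(3)))
        np.testing.assert_array_equal(out, x)

    def test_noise_free_construction_cancels(self):
        from fnirskit.synthetic import make_tf_fixture

        taps = np.array([0.8, -0.3, 0.1, 0.05])
        x, y, _ = make_tf_fixture(taps, n_samples=1500, noise_sd=0.0, seed=11)
        model = fit_tf_model(x, y, m=3)
        out = apply_tf_correction(x, y, model)
        assert np.abs(out).max() < 1e-8

    def test_mayer_band_removed_task_band_kept(self):
        from helpers import band_power

        rng = np.random.default_rng(12)
        t = np.arange(int(600 * RATE)) / RATE
        task = np.sin(2 * np.pi * 0.02 * t)  # slow task-band signal
        mayer = np.sin(2 * np.pi * 0.1 * t + 0.3)
        x = task + 0.5 * mayer + rng.normal(0, 0.01, t.size)
        model = fit_tf_model(x, mayer, m=8)
        out = apply_tf_correction(x, mayer, model)
        band = (0.07, 0.13)
        assert band_power(out, RATE, band) < 0.10 * band_power(x, RATE, band)
        before = band_power(x, RATE, (1e-4, 0.05))
        after = band_power(out, RATE, (1e-4, 0.05))
        assert abs(after - before) / before < 0.05

    def test_never_increases_error_against_clean_signal(self):
        rng = np.random.default_rng(13)
        t = np.arange(int(600 * RATE)) / RATE
        clean = np.sin(2 * np.pi * 0.02 * t)
        artifact = np.sin(2 * np.pi * 0.1 * t)
        noise = rng.normal(0, 0.3, t.size)  # SNR ~ 0 dB vs artifact
        x = clean + artifact + noise
        model = fit_tf_model(x, artifact, m=8)
        out = apply_tf_correction(x, artifact, model)
        mse_before = np.mean((x - clean) ** 2)
        mse_after = np.mean((out - clean) ** 2)
        assert mse_after <= mse_before


class TestDispatch:
    def test_uncorrected_is_identity(self):
        rng = np.random.default_rng(14)
        block = ConcentrationBlock(
            rng.standard_normal((3, 100)), rng.standard_normal((3, 100)), RATE
        )
        out = correct_block(block, "uncorrected")
        np.testing.assert_array_equal(out.hbo, block.hbo)
        np.testing.assert_array_equal(out.hbr, block.hbr)
        assert out.hbo is not block.hbo  # a copy, not a view

    def test_unknown_method_rejected(self):
        block = ConcentrationBlock(np.ones((2, 50)), np.ones((2, 50)), RATE)
        with pytest.raises(Exception, match="unknown"):
            correct_block(block, "wavelet")
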