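"""Epoch segmentation, trial/grand/ROI averaging, exclusions, interpolation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fnirskit.epochs import (
    Condition,
    EpochSet,
    Paradigm,
    ROIDefinition,
    average_trials,
    grand_average,
    interpolate_channel,
    roi_average,
    segment_trials,
)
from fnirskit.errors import ConfigurationError, ProcessingError
from fnirskit.haemodynamics import ConcentrationBlock

RATE = 3.91


def _paradigm(pre=5.0, task=12.0, post=8.0):
    return Paradigm([Condition("A", 1), Condition("B", 2)], pre=pre, task=task, post=post)


def _block(n_channels=3, n_samples=1200, seed=0):
    rng = np.random.default_rng(seed)
    return ConcentrationBlock(
        rng.standard_normal((n_channels, n_samples)),
        rng.standard_normal((n_channels, n_samples)),
        RATE,
    )


class TestSegmentTrials:
    def test_epoch_length_matches_block_timing(self):
        # 5 s pre + (12 + 8) s from onset at 3.91 Hz:
        # round(5*3.91) + round(20*3.91) = 20 + 78 = 98 samples
        before, after = _paradigm().epoch_samples(RATE)
        assert (before, after) == (20, 78)
        block = _block()
        markers = [(200, 1)]
        epochs = segment_trials(block, markers, _paradigm(), Condition("A", 1))
        assert epochs.n_samples == 98

    def test_one_trial_per_matching_marker(self):
        block = _block(n_samples=3000)
        markers = [(100 + 110 * k, 2) for k in range(10)] + [(95, 1)]
        epochs = segment_trials(block, markers, _paradigm(), Condition("B", 2))
        assert epochs.n_trials == 10

    def test_non_matching_marker_not_segmented(self):
        block = _block()
        with pytest.raises(ProcessingError, match="marker"):
            segment_trials(block, [(100, 1)], _paradigm(), Condition("B", 2))

    def test_out_of_bounds_trial_dropped_with_warning(self):
        block = _block(n_samples=300)
        markers = [(100, 1), (290, 1)]  # second would overrun the recording
        with pytest.warns(UserWarning, match="dropped"):
            epochs = segment_trials(block, markers, _paradigm(), Condition("A", 1))
        assert epochs.n_trials == 1

    def test_epoch_content_matches_direct_slice(self):
        block = _block()
        onset = 400
        epochs = segment_trials(block, [(onset, 1)], _paradigm(), Condition("A", 1))
        np.testing.assert_array_equal(
            epochs.hbo[0], block.hbo[:, onset - 20 : onset + 78]
        )

    def test_time_axis_zero_at_onset(self):
        block = _block()
        epochs = segment_trials(block, [(400, 1)], _paradigm(), Condition("A", 1))
        assert epochs.time[epochs.pre_samples] == 0.0
        assert epochs.time[0] == pytest.approx(-20 / RATE)


class TestAverageTrials:
    def _epochs(self, data):
        data = np.asarray(data, dtype=float)
        return EpochSet(hbo=data, hbr=-data, rate=RATE, pre_samples=0, condition="A")

    def test_identical_trials_mean_equals_trial_sd_zero(self):
        trial = np.arange(12.0).reshape(3, 4)
        avg = average_trials(self._epochs(np.stack([trial] * 5)))
        np.testing.assert_array_equal(avg["hbo"], trial)
        np.testing.assert_array_equal(avg["hbo_sd"], np.zeros_like(trial))

    def test_two_trial_hand_arithmetic(self):
        trials = np.array([[[1.0, 3.0]], [[3.0, 5.0]]])  # 2 trials x 1 ch x 2
        avg = average_trials(self._epochs(trials))
        np.testing.assert_array_equal(avg["hbo"], [[2.0, 4.0]])

    def test_excluded_trial_matches_subset_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((3, 2, 5))
        epochs = self._epochs(data)
        epochs.excluded_trials.add(1)
        avg = average_trials(epochs)
        np.testing.assert_allclose(avg["hbo"], data[[0, 2]].mean(axis=0))

    def test_excluded_channel_removed_everywhere(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 3, 6))
        epochs = self._epochs(data)
        epochs.excluded_channels.add(1)
        avg = average_trials(epochs)
        assert avg["hbo"].shape == (2, 6)
        np.testing.assert_array_equal(avg["channels"], [0, 2])
        np.testing.assert_allclose(avg["hbo"], data[:, [0, 2]].mean(axis=0))

    def test_all_trials_excluded_rejected(self):
        epochs = self._epochs(np.ones((2, 1, 3)))
        epochs.excluded_trials |= {0, 1}
        with pytest.raises(ProcessingError):
            average_trials(epochs)

    def test_single_trial_sd_zero_with_warning(self):
        epochs = self._epochs(np.ones((1, 2, 3)))
        with pytest.warns(UserWarning, match="single trial"):
            avg = average_trials(epochs)
        np.testing.assert_array_equal(avg["hbo_sd"], np.zeros((2, 3)))

    def test_one_based_trial_exclusion(self):
        epochs = self._epochs(np.ones((3, 1, 2)))
        epochs.exclude_trials_1based([2])
        assert epochs.excluded_trials == {1}
        with pytest.raises(ConfigurationError):
            epochs.exclude_trials_1based([4])


class TestInterpolateChannel:
    def test_single_neighbor_copies_it(self):
        block = _block()
        out = interpolate_channel(block, 0, [2])
        np.testing.assert_array_equal(out.hbo[0], block.hbo[2])

    def test_two_constant_neighbors_average(self):
        hbo = np.vstack([np.zeros(5), np.full(5, 9.0), np.ones(5), np.full(5, 3.0)])
        block = ConcentrationBlock(hbo, hbo, RATE)
        out = interpolate_channel(block, 1, [2, 3])
        np.testing.assert_array_equal(out.hbo[1], np.full(5, 2.0))

    def test_self_neighbor_rejected(self):
        with pytest.raises(ConfigurationError):
            interpolate_channel(_block(), 1, [1, 2])

    def test_empty_neighbors_rejected(self):
        with pytest.raises(ConfigurationError):
            interpolate_channel(_block(), 0, [])


class TestGrandAverage:
    def test_single_subject_identity(self):
        mean = np.arange(6.0).reshape(2, 3)
        np.testing.assert_array_equal(grand_average([mean]), mean)

    def test_identical_subjects_identity(self):
        mean = np.arange(6.0).reshape(2, 3)
        np.testing.assert_array_equal(grand_average([mean] * 4), mean)

    def test_two_subject_hand_arithmetic(self):
        a = np.array([[0.0, 2.0]])
        b = np.array([[4.0, 6.0]])
        np.testing.assert_array_equal(grand_average([a, b]), [[2.0, 4.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ProcessingError, match="shapes"):
            grand_average([np.zeros((2, 3)), np.zeros((2, 4))])

    @given(seed=st.integers(0, 2**16))
    def test_linear_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        subjects = [rng.standard_normal((2, 4)) for _ in range(3)]
        base = grand_average(subjects)
        np.testing.assert_allclose(grand_average(subjects[::-1]), base, atol=1e-12)
        np.testing.assert_allclose(
            grand_average([2 * s for s in subjects]), 2 * base, atol=1e-12
        )


class TestRoiAverage:
    def test_single_channel_roi_identity(self):
        traces = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(
            roi_average(traces, ROIDefinition("m1", [1])), traces[1]
        )

    def test_two_channel_hand_arithmetic(self):
        traces = np.vstack([np.ones(4), np.full(4, 3.0)])
        np.testing.assert_array_equal(
            roi_average(traces, ROIDefinition("m1", [0, 1])), np.full(4, 2.0)
        )

    def test_full_roi_equals_car_reference_term(self):
        rng = np.random.default_rng(3)
        traces = rng.standard_normal((5, 7))
        roi = ROIDefinition("all", list(range(5)))
        np.testing.assert_allclose(
            roi_average(traces, roi), traces.mean(axis=0), atol=1e-12
        )

    def test_excluded_member_rejected(self):
        traces = np.zeros((3, 4))
        with pytest.raises(ProcessingError, match="excluded"):
            roi_average(traces, ROIDefinition("m1", [0, 1]), excluded={1})


class TestHrfRecovery:
    def test_segment_average_recovers_template(self, sim_config):
        # noiseless block design: averaging must reproduce the embedded HRF
        from dataclasses import replace

        from fnirskit.synthetic import simulate_streams

        cfg = replace(sim_config, noise_sd=0.0, artifacts={}, seed=21)
        _, _, truth = simulate_streams(cfg)
        block = ConcentrationBlock(truth.hbo_total, truth.hbr_total, cfg.fnirs_rate)
        paradigm = Paradigm([Condition("task", 1)], pre=cfg.pre, task=cfg.task,
                            post=cfg.post)
        markers = [(int(s), 1) for s in truth.onset_samples]
        epochs = segment_trials(block, markers, paradigm, Condition("task", 1))
        assert epochs.n_trials >= 10
        avg = average_trials(epochs)
        template = truth.clean_hbo[0, truth.onset_samples[0] - 20:
                                   truth.onset_samples[0] + 78]
        r = np.corrcoef(avg["hbo"][0], template)[0, 1]
        assert r > 0.99
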