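"""Stimulus schedules, background noise, and ERP injection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import p300tour as pt


class TestBuildStimulusSchedule:
    def test_training_block_counts(self):
        sched = pt.build_stimulus_schedule(6, 30, 187.5, target_id=0, seed=0)
        assert sched.n_events == 180
        assert int(sched.is_target.sum()) == 30
        assert np.bincount(sched.stimulus_ids).tolist() == [30] * 6

    def test_online_block_spans_expected_time(self):
        sched = pt.build_stimulus_schedule(6, 20, 187.5, target_id=3, seed=1)
        assert sched.n_events == 120
        span = sched.onsets[-1] - sched.onsets[0] + 0.1875
        assert span == pytest.approx(120 * 0.1875)

    def test_constant_isi_spacing(self):
        sched = pt.build_stimulus_schedule(6, 20, 187.5, target_id=0, seed=2)
        assert np.allclose(np.diff(sched.onsets), 0.1875)

    def test_minimal_schedule_both_orders_possible(self):
        firsts = {
            pt.build_stimulus_schedule(2, 1, 187.5, 0, seed=s).stimulus_ids[0]
            for s in range(20)
        }
        assert firsts == {0, 1}

    def test_deterministic_for_fixed_seed(self):
        a = pt.build_stimulus_schedule(6, 30, 187.5, 2, seed=7)
        b = pt.build_stimulus_schedule(6, 30, 187.5, 2, seed=7)
        assert np.array_equal(a.stimulus_ids, b.stimulus_ids)

    def test_no_immediate_repeats_across_rounds(self):
        sched = pt.build_stimulus_schedule(6, 50, 187.5, 0, seed=3)
        assert np.all(np.diff(sched.stimulus_ids) != 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"target_id": 6},
            {"target_id": -1},
            {"n_stimuli": 1},
            {"blinks_per_stimulus": 0},
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs):
        base = dict(n_stimuli=6, blinks_per_stimulus=30, isi_ms=187.5, target_id=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            pt.build_stimulus_schedule(**base, seed=0)

    @given(
        n_stimuli=st.integers(2, 8),
        blinks=st.integers(1, 12),
        target=st.integers(0, 7),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_balanced_counts_and_single_target_property(
        self, n_stimuli, blinks, target, seed
    ):
        target = target % n_stimuli
        sched = pt.build_stimulus_schedule(n_stimuli, blinks, 187.5, target, seed=seed)
        counts = np.bincount(sched.stimulus_ids, minlength=n_stimuli)
        assert counts.tolist() == [blinks] * n_stimuli
        assert set(sched.stimulus_ids[sched.is_target]) == {target}


class TestGenerateBackground:
    def test_zero_noise_is_all_zero(self):
        eeg = pt.generate_background(4, 512, 2.0, noise_scale=0, seed=0)
        assert not eeg.data.any()

    def test_shape_arithmetic(self):
        eeg = pt.generate_background(32, 2048, 10.0, noise_scale=10, seed=0)
        assert eeg.data.shape == (32, 20480)

    def test_rms_matches_noise_scale(self):
        eeg = pt.generate_background(8, 512, 20.0, noise_scale=5.0, seed=1)
        rms = np.sqrt(np.mean(eeg.data**2, axis=1))
        assert np.allclose(rms, 5.0, rtol=1e-6)

    def test_power_decreases_with_frequency(self):
        from scipy.signal import welch

        eeg = pt.generate_background(1, 512, 120.0, noise_scale=10, seed=2)
        freqs, psd = welch(eeg.data[0], fs=512, nperseg=4096)
        band = lambda lo, hi: psd[(freqs >= lo) & (freqs < hi)].mean()
        assert band(1, 5) > band(5, 15) > band(15, 40)


class TestInjectErp:
    def test_zero_amplitude_is_identity(self):
        eeg = pt.generate_background(4, 512, 5.0, noise_scale=3, seed=0)
        sched = pt.build_stimulus_schedule(2, 4, 187.5, 0, seed=0, t_start=0.5)
        out = pt.inject_erp(eeg, sched, pt.ErpTemplate(peak_amplitude=0), seed=1)
        assert np.array_equal(out.data, eeg.data)

    def test_input_not_mutated(self):
        eeg = pt.generate_background(4, 512, 5.0, noise_scale=3, seed=0)
        before = eeg.data.copy()
        sched = pt.build_stimulus_schedule(2, 4, 187.5, 0, seed=0, t_start=0.5)
        pt.inject_erp(eeg, sched, pt.ErpTemplate(), seed=1)
        assert np.array_equal(eeg.data, before)

    def test_noise_free_peak_amplitude_and_latency(self):
        eeg = pt.generate_background(3, 512, 4.0, noise_scale=0,
                                     channel_names=("A", "B", "C"))
        sched = pt.StimulusSchedule(
            onsets=[1.0], stimulus_ids=[0], block_ids=[0], is_target=[True]
        )
        tmpl = pt.ErpTemplate(
            peak_amplitude=5.0, peak_latency_ms=350.0,
            topography=np.array([1.0, 0.5, 0.0]),
            latency_jitter_sd_ms=0.0, amplitude_jitter_sd=0.0,
        )
        out = pt.inject_erp(eeg, sched, tmpl, seed=0)
        peak_idx = out.data[0].argmax()
        # the sampling grid may sit up to half a sample off the true peak
        assert out.data[0].max() == pytest.approx(5.0, rel=1e-3)
        assert out.data[1].max() == pytest.approx(2.5, rel=1e-3)
        assert not out.data[2].any()
        assert peak_idx / 512 == pytest.approx(1.35, abs=2 / 512)

    def test_average_recovers_template_latency(self):
        eeg = pt.generate_background(1, 512, 130.0, noise_scale=1.0, seed=4,
                                     channel_names=("Cz",))
        sched = pt.build_stimulus_schedule(2, 120, 500.0, 0, seed=4, t_start=1.0)
        tmpl = pt.ErpTemplate(peak_amplitude=5.0, topography=np.array([1.0]))
        out = pt.inject_erp(eeg, sched, tmpl, seed=5)
        epochs = pt.extract_epochs(out, sched, window_ms=(0.0, 500.0))
        diff = (
            epochs.data[epochs.labels == 1, 0].mean(axis=0)
            - epochs.data[epochs.labels == 0, 0].mean(axis=0)
        )
        peak_ms = epochs.times_ms[diff.argmax()]
        assert abs(peak_ms - 350.0) <= 20.0

    def test_event_beyond_recording_raises(self):
        eeg = pt.generate_background(2, 512, 1.0, noise_scale=0)
        sched = pt.StimulusSchedule(
            onsets=[0.9], stimulus_ids=[0], block_ids=[0], is_target=[True]
        )
        with pytest.raises(ValueError, match="exceeds recording end"):
            pt.inject_erp(eeg, sched, pt.ErpTemplate(latency_jitter_sd_ms=0), seed=0)


class TestSimulateSession:
    def test_training_session_epoch_counts(self, training_session):
        _, schedule, targets = training_session
        assert int(schedule.is_target.sum()) == 180
        assert int((~schedule.is_target).sum()) == 900
        assert targets.tolist() == [0, 1, 2, 3, 4, 5]

    def test_online_session_counts(self, online_session):
        _, schedule, targets = online_session
        assert schedule.n_events == 12 * 120
        assert int(schedule.is_target.sum()) == 240
        assert len(targets) == 12
        for b in schedule.blocks:
            in_block = schedule.block_ids == b
            assert int(in_block.sum()) == 120
            assert int(schedule.is_target[in_block].sum()) == 20

    def test_block_targets_match_ground_truth(self, online_session):
        _, schedule, targets = online_session
        recovered = [schedule.block_target(b) for b in schedule.blocks]
        assert recovered == targets.tolist()

    def test_same_seed_bit_reproducible(self):
        kw = dict(blinks_per_stimulus=3, n_trials=1)
        a = pt.simulate_session("online", seed=9, **kw)
        b = pt.simulate_session("online", seed=9, **kw)
        assert np.array_equal(a[0].data, b[0].data)
        assert np.array_equal(a[1].onsets, b[1].onsets)
        assert np.array_equal(a[2], b[2])

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            pt.simulate_session("resting")

    def test_average_amplitude_linear_in_peak(self):
        """Grand-average target ERP grows with slope 1 in peak_amplitude."""
        gains = []
        for peak in (2.0, 4.0):
            tmpl = pt.ErpTemplate(
                peak_amplitude=peak, latency_jitter_sd_ms=0, amplitude_jitter_sd=0
            )
            eeg, sched, _ = pt.simulate_session(
                "training", template=tmpl, noise_scale=0, seed=0,
                blinks_per_stimulus=5,
            )
            epochs = pt.extract_epochs(eeg, sched, (200.0, 600.0))
            oz = epochs.channel_names.index("Oz")
            gains.append(epochs.data[epochs.labels == 1, oz].mean(axis=0).max())
        slope = (gains[1] - gains[0]) / 2.0
        assert slope == pytest.approx(gains[0] / 2.0, rel=0.05)
        assert gains[1] / 4.0 == pytest.approx(1.0, rel=0.05)  # topo(Oz)=1
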