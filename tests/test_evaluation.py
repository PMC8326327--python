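"""Accuracy, Wolpaw ITR, blink subsampling, feature counts, Likert."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import p300tour as pt
from p300tour.evaluation import ItrParams


def results_from_flags(flags):
    return [
        pt.SelectionResult(
            votes=np.eye(6, dtype=int)[0] * 5,
            predicted=0,
            true_target=0 if ok else 1,
        )
        for ok in flags
    ]


class TestSelectionAccuracy:
    def test_eight_of_twelve_displays_66(self):
        acc = pt.selection_accuracy(results_from_flags([True] * 8 + [False] * 4))
        assert acc == pytest.approx(200 / 3)
        assert pt.display_accuracy(acc) == 66

    def test_all_and_none_correct(self):
        assert pt.selection_accuracy(results_from_flags([True] * 5)) == 100.0
        assert pt.selection_accuracy(results_from_flags([False] * 5)) == 0.0

    def test_truncation_convention(self):
        assert pt.display_accuracy(91.67) == 91
        assert pt.display_accuracy(83.33) == 83
        assert pt.display_accuracy(100.0) == 100


class TestWolpawItr:
    # Printed accuracy/time/ITR cells from two online sessions and the
    # blink-subsampling table; printed cells are reproduced to +/- 0.01
    # (two cells were printed from unrounded accuracies).
    CELLS = [
        (1.0, 30.5, 5.09),
        (0.91, 30.5, 3.82),
        (0.66, 30.5, 1.71),
        (0.9375, 11.37, 11.10),
        (0.4916, 6.62, 3.66),
        (0.7916, 30.5, 2.68),
        (0.8375, 11.37, 8.27),
        (0.6958, 6.62, 8.99),
        (0.3625, 6.62, 1.45),
        (0.3083, 6.62, 0.79),
        (0.5208, 11.37, 2.50),
        (0.9833, 23.87, 6.09),
    ]

    @pytest.mark.parametrize("acc,time_s,expected", CELLS)
    def test_reproduces_printed_cells(self, acc, time_s, expected):
        itr = pt.wolpaw_itr(n_classes=6, accuracy=acc, selection_time_s=time_s)
        assert round(itr, 2) == pytest.approx(expected, abs=0.0101)

    def test_chance_level_gives_zero_bits(self):
        assert pt.wolpaw_bits(6, 1 / 6) == pytest.approx(0.0, abs=1e-12)
        assert pt.wolpaw_itr(n_classes=6, accuracy=1 / 6, selection_time_s=11.4) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_extremes_well_defined(self):
        assert pt.wolpaw_bits(6, 1.0) == pytest.approx(np.log2(6))
        assert np.isfinite(pt.wolpaw_bits(6, 0.0))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            pt.wolpaw_itr(n_classes=6, accuracy=1.2, selection_time_s=10.0)
        with pytest.raises(ValueError):
            pt.wolpaw_itr(n_classes=6, accuracy=0.5, selection_time_s=0.0)

    @given(st.floats(1 / 6 + 1e-6, 1.0 - 1e-9), st.floats(1 / 6 + 1e-6, 1.0 - 1e-9))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_accuracy_above_chance(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert pt.wolpaw_bits(6, hi) >= pt.wolpaw_bits(6, lo) - 1e-12

    def test_inversely_proportional_to_time(self):
        a = pt.wolpaw_itr(n_classes=6, accuracy=0.9, selection_time_s=10.0)
        b = pt.wolpaw_itr(n_classes=6, accuracy=0.9, selection_time_s=20.0)
        assert a == pytest.approx(2 * b)


class TestSubsampleAccuracy:
    def test_exhaustive_draw_equals_full_replay(
        self, trained_model, online_session, online_features
    ):
        eeg, schedule, targets = online_session
        mean, sd = pt.subsample_accuracy(
            trained_model, online_features, targets, n_blinks=20, seed=0
        )
        assert sd == 0.0
        full = pt.selection_accuracy(
            pt.replay_session(trained_model, eeg, schedule, targets)
        )
        assert mean == pytest.approx(full)

    def test_perfect_labels_always_100(self, online_session):
        _, schedule, targets = online_session
        feats = pt.FeatureMatrix(
            values=schedule.is_target.astype(float)[:, None],
            feature_map=[("Oz", 350.0)],
            labels=schedule.is_target.astype(int),
            stimulus_ids=schedule.stimulus_ids,
            block_ids=schedule.block_ids,
        )
        oracle = pt.SwldaModel(selected=[0], weights=[1.0], intercept=0.0)
        for n in (1, 5, 20):
            mean, _ = pt.subsample_accuracy(oracle, feats, targets, n, seed=1)
            assert mean == 100.0

    def test_oversized_draw_rejected(self, trained_model, online_features,
                                     online_session):
        targets = online_session[2]
        with pytest.raises(ValueError, match="fewer than N"):
            pt.subsample_accuracy(trained_model, online_features, targets, 21)


class TestBlinkCurve:
    def test_rows_times_and_itr_consistency(
        self, trained_model, online_features, online_session
    ):
        targets = online_session[2]
        curve = pt.blink_curve(trained_model, online_features, targets, seed=3)
        frame = curve.to_frame()
        assert list(frame["n_blinks"]) == [1, 5, 10, 15, 20]
        assert list(frame["response_time_s"]) == [6.62, 11.37, 17.75, 23.87, 30.5]
        for n, acc, itr in zip(curve.ns, curve.mean_accuracy, curve.itr):
            expected = pt.wolpaw_itr(
                n_classes=6, accuracy=acc / 100.0,
                selection_time_s=pt.RESPONSE_TIME_S[n],
            )
            assert itr == pytest.approx(expected)

    def test_missing_response_time_rejected(
        self, trained_model, online_features, online_session
    ):
        with pytest.raises(ValueError, match="N=7"):
            pt.blink_curve(
                trained_model, online_features, online_session[2], ns=(7,)
            )


class TestChannelFeatureCounts:
    def test_counts_conserved(self, trained_model):
        counts = pt.channel_feature_counts([trained_model, trained_model])
        assert counts.sum() == 2 * trained_model.selected.size

    def test_single_channel_model(self):
        model = pt.SwldaModel(
            selected=[0, 2], weights=[1.0, 1.0], intercept=0.0,
            feature_map=[("Oz", 200.0), ("Oz", 250.0), ("Oz", 300.0)],
        )
        counts = pt.channel_feature_counts([model])
        assert counts.to_dict() == {"Oz": 2}

    def test_unknown_index_rejected(self):
        model = pt.SwldaModel(
            selected=[5], weights=[1.0], intercept=0.0,
            feature_map=[("Oz", 200.0)],
        )
        with pytest.raises(ValueError, match="outside the feature map"):
            pt.channel_feature_counts([model])

    def test_midline_ordering_on_signal_driven_cohort(self):
        """Summed counts rise front-to-back along the midline (Fz<Cz<Pz<Oz)."""
        models = []
        for subj in range(1, 7):
            eeg, sched, _ = pt.simulate_session(
                "training", seed=subj, noise_scale=4
            )
            models.append(pt.train_swlda(pt.preprocess(eeg, sched)))
        counts = pt.channel_feature_counts(models, channel_names=pt.CHANNELS_32)
        assert counts["Fz"] < counts["Cz"] < counts["Pz"] < counts["Oz"]


class TestSummarizeLikert:
    # Per-subject questionnaire rows with their printed mean +/- SD.
    ROWS = [
        ([4, 5, 5, 4, 3, 4, 5, 5, 5, 3], 4.3, 0.78),  # Expectation
        ([5, 5, 3, 5, 5, 5, 5, 3, 5, 5], 4.6, 0.80),  # Control
        ([5, 3, 4, 5, 5, 3, 5, 3, 5, 4], 4.2, 0.87),  # Follow
        ([3, 4, 3, 4, 3, 3, 4, 3, 3, 4], 3.4, 0.49),  # Length
    ]

    @pytest.mark.parametrize("scores,mean,sd", ROWS)
    def test_population_sd_reproduces_printed_rows(self, scores, mean, sd):
        m, s = pt.summarize_likert(scores)
        assert round(m, 1) == mean
        assert round(s, 2) == sd

    def test_format_matches_table_convention(self):
        m, s = pt.summarize_likert([4, 5, 5, 4, 3, 4, 5, 5, 5, 3])
        assert pt.format_likert(m, s) == "4.3 ± 0.78"

    def test_all_equal_gives_zero_sd(self):
        assert pt.summarize_likert([3, 3, 3]) == (3.0, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..5"):
            pt.summarize_likert([0, 3, 5])
        with pytest.raises(ValueError, match="1..5"):
            pt.summarize_likert([2.5, 3.0])
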