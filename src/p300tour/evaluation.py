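"""Quantitative evaluation: selection accuracy, Wolpaw ITR, blink
subsampling curves, per-channel feature counts, and Likert summaries.

The Wolpaw information transfer rate for an M-class selection with
accuracy P and selection time T seconds is

    bits/selection = log2 M + P log2 P + (1 - P) log2((1 - P) / (M - 1))
    ITR = bits/selection * 60 / T   (bits per minute)

with the convention 0 * log2 0 := 0. Selection times embed an empirical
per-N system delay and are configuration constants, not derived from the
ISI alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .decoder import decide_selection
from .swlda import SwldaModel, predict_labels
from .types import FeatureMatrix, SelectionResult

#: Selection (response) time in seconds per number of blinks N: the
#: stimulation time N x 6 x ISI plus the measured system delay.
RESPONSE_TIME_S: dict[int, float] = {1: 6.62, 5: 11.37, 10: 17.75, 15: 23.87, 20: 30.5}

#: Default subsampling grid for the blink curve.
DEFAULT_NS: tuple[int, ...] = (1, 5, 10, 15, 20)


def selection_accuracy(results: list[SelectionResult]) -> float:
    """Percent of selections whose prediction matches the instructed target."""
    if not results:
        raise ValueError("no selections to score")
    flags = [r.correct for r in results]
    if any(f is None for f in flags):
        raise ValueError("every selection needs a known true target")
    return 100.0 * sum(flags) / len(flags)


def display_accuracy(percent: float) -> int:
    """Truncate to an integer for display (66.67 -> 66, 91.67 -> 91)."""
    return int(percent + 1e-9)


@dataclass
class ItrParams:
    n_classes: int = 6
    accuracy: float = 1.0            # P, a fraction in [0, 1]
    selection_time_s: float = 30.5   # T

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.selection_time_s <= 0:
            raise ValueError("selection_time_s must be positive")


def wolpaw_bits(n_classes: int, accuracy: float) -> float:
    """Bits per selection under the Wolpaw model (0 log 0 := 0)."""
    params = ItrParams(n_classes, accuracy, 1.0)  # validate
    M, P = params.n_classes, params.accuracy
    bits = math.log2(M)
    if P > 0:
        bits += P * math.log2(P)
    if P < 1:
        bits += (1 - P) * math.log2((1 - P) / (M - 1))
    return bits


def wolpaw_itr(
    params: ItrParams | None = None,
    *,
    n_classes: int = 6,
    accuracy: float | None = None,
    selection_time_s: float | None = None,
) -> float:
    """Information transfer rate in bits/min (full precision; round for display)."""
    if params is None:
        if accuracy is None or selection_time_s is None:
            raise ValueError("accuracy and selection_time_s are required")
        params = ItrParams(n_classes, accuracy, selection_time_s)
    bits = wolpaw_bits(params.n_classes, params.accuracy)
    return bits * 60.0 / params.selection_time_s


def subsample_accuracy(
    model: SwldaModel,
    features: FeatureMatrix,
    true_targets: np.ndarray,
    n_blinks: int,
    repeats: int = 10,
    seed: int | None = None,
    n_stimuli: int = 6,
) -> tuple[float, float]:
    """Offline accuracy using N randomly drawn epochs per stimulus.

    Per repeat and per selection block, N epochs of each stimulus are drawn
    without replacement, the vote is re-run, and the accuracy over all
    blocks computed; the (mean, SD) over the repeats is returned. Drawing
    all available epochs makes every repeat identical (SD = 0).
    """
    if features.block_ids is None or features.stimulus_ids is None:
        raise ValueError("features must carry block and stimulus ids")
    rng = np.random.default_rng(seed)
    labels = predict_labels(model, features)
    blocks = np.unique(features.block_ids)
    if len(true_targets) != blocks.size:
        raise ValueError("one true target per selection block is required")

    # Pre-index epochs per (block, stimulus) once.
    groups: list[list[np.ndarray]] = []
    for b in blocks:
        in_block = features.block_ids == b
        per_stim = []
        for s in range(n_stimuli):
            idx = np.flatnonzero(in_block & (features.stimulus_ids == s))
            if idx.size < n_blinks:
                raise ValueError(
                    f"block {int(b)} stimulus {s} has {idx.size} epochs, "
                    f"fewer than N={n_blinks}"
                )
            per_stim.append(idx)
        groups.append(per_stim)

    accs = np.empty(repeats)
    for r in range(repeats):
        correct = 0
        for bi, per_stim in enumerate(groups):
            votes = np.empty(n_stimuli, dtype=int)
            for s, idx in enumerate(per_stim):
                take = (
                    idx if idx.size == n_blinks
                    else rng.choice(idx, size=n_blinks, replace=False)
                )
                votes[s] = labels[take].sum()
            if int(np.argmax(votes)) == int(true_targets[bi]):
                correct += 1
        accs[r] = 100.0 * correct / len(groups)
    return float(accs.mean()), float(accs.std())


@dataclass
class BlinkCurve:
    """Mean accuracy, its SD and ITR per number of blinks N."""

    ns: tuple[int, ...]
    mean_accuracy: np.ndarray    # percent
    sd_accuracy: np.ndarray
    itr: np.ndarray              # bits/min
    repeats: int = 10
    seed: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n_blinks": list(self.ns),
                "response_time_s": [RESPONSE_TIME_S.get(n, np.nan) for n in self.ns],
                "mean_accuracy_pct": self.mean_accuracy,
                "sd_accuracy_pct": self.sd_accuracy,
                "itr_bits_per_min": self.itr,
            }
        )


def blink_curve(
    model: SwldaModel,
    features: FeatureMatrix,
    true_targets: np.ndarray,
    ns: tuple[int, ...] = DEFAULT_NS,
    response_times: dict[int, float] | None = None,
    repeats: int = 10,
    seed: int | None = None,
    n_stimuli: int = 6,
) -> BlinkCurve:
    """Subsampled accuracy and ITR across the blink grid (ascending N)."""
    if response_times is None:
        response_times = RESPONSE_TIME_S
    missing = [n for n in ns if n not in response_times]
    if missing:
        raise ValueError(f"no response time defined for N={missing[0]}")
    ss = np.random.SeedSequence(seed)
    means, sds, itrs = [], [], []
    for n, child in zip(ns, ss.spawn(len(ns))):
        m, s = subsample_accuracy(
            model, features, true_targets, n, repeats,
            seed=np.random.default_rng(child).integers(2**31),
            n_stimuli=n_stimuli,
        )
        means.append(m)
        sds.append(s)
        itrs.append(wolpaw_itr(ItrParams(n_stimuli, m / 100.0, response_times[n])))
    return BlinkCurve(
        ns=tuple(ns),
        mean_accuracy=np.asarray(means),
        sd_accuracy=np.asarray(sds),
        itr=np.asarray(itrs),
        repeats=repeats,
        seed=seed,
    )


def channel_feature_counts(
    models: list[SwldaModel],
    feature_map: list[tuple[str, float]] | None = None,
    channel_names: tuple[str, ...] | None = None,
):
    """Histogram of selected features per channel, summed across models."""
    import pandas as pd

    counts: dict[str, int] = {}
    if channel_names is not None:
        counts = {c: 0 for c in channel_names}
    for model in models:
        fmap = model.feature_map if feature_map is None else feature_map
        if fmap is None:
            raise ValueError("model carries no feature_map and none was given")
        for idx in model.selected:
            if idx >= len(fmap):
                raise ValueError(f"selected index {int(idx)} outside the feature map")
            ch = fmap[idx][0]
            counts[ch] = counts.get(ch, 0) + 1
    return pd.Series(counts, name="n_selected_features")


def summarize_likert(scores) -> tuple[float, float]:
    """Mean and population (divide-by-n) SD of 1-5 Likert scores."""
    arr = np.asarray(list(scores))
    if arr.size == 0:
        raise ValueError("no scores")
    if not np.issubdtype(arr.dtype, np.integer) or arr.min() < 1 or arr.max() > 5:
        raise ValueError("Likert scores must be integers in 1..5")
    return float(arr.mean()), float(arr.std())  # ddof=0: population SD


def format_likert(mean: float, sd: float) -> str:
    """Render as printed in questionnaire tables, e.g. '4.3 +/- 0.78'."""
    return f"{mean:.1f} ± {sd:.2f}"
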