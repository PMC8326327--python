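"""From per-epoch hard labels to a selected stimulus, and the two-step game.

A selection sums the classifier's 0/1 labels per stimulus across all its
flashes and picks the stimulus with the most votes (ties go to the lowest
stimulus index). A trial is two consecutive selections: a continent, then a
touristic place within the displayed continent's list. Each selection is
scored independently against its instructed target id, including after a
first-step error (the game simply continues on the wrongly chosen
continent's screen).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

from .preprocess import preprocess as _preprocess
from .swlda import SwldaModel, predict_labels
from .types import (
    ContinuousEEG,
    FeatureMatrix,
    SelectionResult,
    SessionRecord,
    StimulusSchedule,
    TrialRecord,
)


def decide_selection(
    labels: np.ndarray,
    stimulus_ids: np.ndarray,
    n_stimuli: int = 6,
    true_target: int | None = None,
) -> SelectionResult:
    """Sum hard labels per stimulus and pick the argmax (lowest index on ties)."""
    labels = np.asarray(labels, dtype=int)
    stimulus_ids = np.asarray(stimulus_ids, dtype=int)
    if labels.size != stimulus_ids.size:
        raise ValueError("labels and stimulus_ids must align")
    if labels.size == 0:
        raise ValueError("no epochs to decide from")
    counts = np.bincount(stimulus_ids, minlength=n_stimuli)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise ValueError(f"stimulus {int(missing[0])} has no epochs")
    votes = np.bincount(stimulus_ids, weights=labels, minlength=n_stimuli).astype(int)
    predicted = int(np.argmax(votes))  # np.argmax takes the first maximum
    return SelectionResult(
        votes=votes,
        predicted=predicted,
        true_target=None if true_target is None else int(true_target),
        n_blinks_used=int(counts.min()),
    )


def load_catalogue(path: str | Path | None = None) -> dict[str, list[str]]:
    """The 6-continent x 6-place destination catalogue (editable via config)."""
    if path is None:
        text = resources.files("p300tour.data").joinpath("catalogue.json").read_text()
    else:
        text = Path(path).read_text()
    try:
        cat = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed catalogue config: {exc}") from exc
    if not isinstance(cat, dict) or len(cat) != 6:
        raise ValueError(f"catalogue must map exactly 6 continents, got {len(cat)}")
    for continent, places in cat.items():
        if not isinstance(places, list) or len(places) != 6:
            raise ValueError(
                f"continent {continent!r} must list exactly 6 places, "
                f"got {len(places)}"
            )
    return {str(k): [str(p) for p in v] for k, v in cat.items()}


def score_selection(
    model: SwldaModel,
    features: FeatureMatrix,
    true_target: int | None = None,
    n_stimuli: int = 6,
) -> SelectionResult:
    """Predict epoch labels for one selection block and run the vote."""
    labels = predict_labels(model, features)
    return decide_selection(labels, features.stimulus_ids, n_stimuli, true_target)


def replay_session(
    model: SwldaModel,
    eeg: ContinuousEEG,
    schedule: StimulusSchedule,
    true_targets: np.ndarray | None = None,
    **preprocess_kwargs,
) -> list[SelectionResult]:
    """Preprocess a recorded/simulated session and decide every block."""
    features = _preprocess(eeg, schedule, **preprocess_kwargs)
    labels = predict_labels(model, features)
    results = []
    for i, b in enumerate(schedule.blocks):
        m = features.block_ids == b
        tgt = None if true_targets is None else int(true_targets[i])
        results.append(
            decide_selection(labels[m], features.stimulus_ids[m],
                             schedule.n_stimuli, tgt)
        )
    return results


def play_trial(
    model: SwldaModel,
    continent_data: tuple[ContinuousEEG, StimulusSchedule],
    place_data: tuple[ContinuousEEG, StimulusSchedule],
    instructed: tuple[int, int],
    catalogue: dict[str, list[str]] | None = None,
    **preprocess_kwargs,
) -> TrialRecord:
    """Run both steps of one trial: continent selection, then place.

    The place step is played on the screen of the *predicted* continent
    (right or wrong) and scored against the instructed place id within it;
    playing the destination video is a logged no-op.
    """
    if catalogue is None:
        catalogue = load_catalogue()
    continents = list(catalogue)
    inst_cont, inst_place = int(instructed[0]), int(instructed[1])

    feats1 = _preprocess(*continent_data, **preprocess_kwargs)
    res1 = score_selection(model, feats1, true_target=inst_cont)
    shown = continents[res1.predicted]

    feats2 = _preprocess(*place_data, **preprocess_kwargs)
    res2 = score_selection(model, feats2, true_target=inst_place)

    return TrialRecord(
        continent=res1,
        place=res2,
        instructed_continent=inst_cont,
        instructed_place=inst_place,
        continent_name=shown,
        place_name=catalogue[shown][res2.predicted],
    )


def play_session(
    model: SwldaModel,
    eeg: ContinuousEEG,
    schedule: StimulusSchedule,
    true_targets: np.ndarray,
    catalogue: dict[str, list[str]] | None = None,
    **preprocess_kwargs,
) -> SessionRecord:
    """Replay one online session (6 trials x 2 selections) as the full game."""
    if catalogue is None:
        catalogue = load_catalogue()
    continents = list(catalogue)
    results = replay_session(model, eeg, schedule, true_targets, **preprocess_kwargs)
    if len(results) % 2:
        raise ValueError("online session must hold an even number of selections")
    record = SessionRecord(catalogue=catalogue)
    for i in range(0, len(results), 2):
        cont, place = results[i], results[i + 1]
        shown = continents[cont.predicted]
        record.trials.append(
            TrialRecord(
                continent=cont,
                place=place,
                instructed_continent=int(true_targets[i]),
                instructed_place=int(true_targets[i + 1]),
                continent_name=shown,
                place_name=catalogue[shown][place.predicted],
            )
        )
    return record
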