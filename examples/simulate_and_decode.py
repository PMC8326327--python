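"""Train an SWLDA decoder on a synthetic session and play the selection game.

Simulates one training session (6 blocks x 30 flashes per stimulus), trains
the stepwise decoder, then replays a simulated online session (6 trials of
continent -> place, 20 flashes per stimulus) and prints each trial's vote
outcome. The accuracy is the fraction of the 12 selections whose argmax
vote hit the instructed target.
"""

import p300tour as pt

eeg, schedule, _ = pt.simulate_session("training", seed=1)
features = pt.preprocess(eeg, schedule)
model = pt.train_swlda(features)
print(f"training: {features.n_epochs} epochs "
      f"({model.train_meta['n_target']} target), "
      f"{model.selected.size} features selected")

eeg, schedule, targets = pt.simulate_session("online", seed=1001)
record = pt.play_session(model, eeg, schedule, targets)

continents = list(record.catalogue)
for i, trial in enumerate(record.trials):
    want = continents[trial.instructed_continent]
    place = record.catalogue[want][trial.instructed_place]
    mark = "ok" if trial.both_correct else "MISS"
    print(f"trial {i + 1}: wanted {place} ({want}); "
          f"decoded {trial.place_name} ({trial.continent_name}) "
          f"votes {trial.continent.votes.tolist()} / "
          f"{trial.place.votes.tolist()}  [{mark}]")

acc = pt.selection_accuracy(record.selections)
print(f"session accuracy: {acc:.2f}% over 12 selections "
      f"(displayed as {pt.display_accuracy(acc)})")
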