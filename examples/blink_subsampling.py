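"""How many flashes per stimulus does the decoder actually need?

Draws N epochs per stimulus per selection without replacement (10 repeats),
re-runs the vote, and reports mean accuracy and ITR per N in {1,5,10,15,20}.
Accuracy rises with N while ITR typically peaks at small N because the
selection time grows linearly with the number of flashes.
"""

import p300tour as pt

eeg, schedule, _ = pt.simulate_session("training", seed=2, noise_scale=10.0)
model = pt.train_swlda(pt.preprocess(eeg, schedule))

eeg, schedule, targets = pt.simulate_session("online", seed=102, noise_scale=10.0)
features = pt.preprocess(eeg, schedule)
curve = pt.blink_curve(model, features, targets, seed=0)

print(curve.to_frame().to_string(index=False, float_format="%.2f"))
best = int(curve.itr.argmax())
print(f"\nITR peaks at N={curve.ns[best]} "
      f"({curve.itr[best]:.2f} bits/min at "
      f"{curve.mean_accuracy[best]:.1f}% accuracy)")
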