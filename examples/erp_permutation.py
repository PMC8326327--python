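"""Is the target/nontarget ERP difference at Cz statistically solid?

Averages the baseline-corrected 200-600 ms epochs per condition at Cz,
runs a per-timepoint permutation test (two-sample t statistic, 10,000
shuffles) and masks it with Benjamini-Yekutieli FDR at q = 0.05.
"""

import p300tour as pt

eeg, schedule, _ = pt.simulate_session("training", seed=1)
_, epochs = pt.preprocess(eeg, schedule, return_epochs=True)

result = pt.erp_statistics(epochs, channel="Cz", n_perm=10_000, seed=0)

n_sig = int(result.significant.sum())
print(f"{n_sig} of {result.times_ms.size} timepoints significant after BY FDR")
if n_sig:
    sig = result.times_ms[result.significant]
    print(f"significant cluster spans {sig.min():.0f}-{sig.max():.0f} ms "
          f"(template peak at 350 ms)")
peak = int(abs(result.t_values).argmax())
print(f"strongest contrast: t = {result.t_values[peak]:.2f} at "
      f"{result.times_ms[peak]:.0f} ms, "
      f"target mean {result.target_mean[peak]:+.2f} uV vs "
      f"nontarget {result.nontarget_mean[peak]:+.2f} uV")
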