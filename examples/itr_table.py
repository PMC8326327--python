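"""Wolpaw information transfer rate at the standard operating points.

For a 6-class selection, ITR combines accuracy P and selection time T:
bits/selection = log2 6 + P log2 P + (1-P) log2((1-P)/5), scaled to
bits/min. The selection times embed the measured per-N system delay.
"""

from p300tour import RESPONSE_TIME_S, wolpaw_itr

print("accuracy  time_s  bits/min")
for accuracy, time_s in [
    (1.0, 30.5), (0.91, 30.5), (0.66, 30.5),       # 20-blink online sessions
    (0.9375, 11.37), (0.4916, 6.62),               # subsampled operating points
]:
    itr = wolpaw_itr(n_classes=6, accuracy=accuracy, selection_time_s=time_s)
    print(f"{accuracy:8.4f}  {time_s:6.2f}  {itr:8.2f}")

print("\nperfect accuracy across the blink grid:")
for n, t in RESPONSE_TIME_S.items():
    itr = wolpaw_itr(n_classes=6, accuracy=1.0, selection_time_s=t)
    print(f"  N={n:2d} (T={t:5.2f}s): {itr:5.2f} bits/min")
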