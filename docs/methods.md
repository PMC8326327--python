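# Methods

## The decoding model

Each flash of one of M = 6 stimuli is followed by an EEG epoch; attending
a stimulus adds a P300 — a positive deflection peaking ~300–400 ms after
its flashes, strongest over parieto-occipital midline sites. The decoder
is classical SWLDA: the flattened channel × time amplitude matrix of the
training epochs (label 1 for target flashes, 0 otherwise) enters a
forward–backward stepwise OLS regression; a candidate feature joins when
its partial p-value is the smallest and below `p_enter`, and after every
entry any included feature whose full-model p exceeds `p_remove` is
dropped, worst first. The retained features get OLS weights (refit on the
selected set), and an epoch is labelled target when its linear score is at
or above a fixed threshold. A selection sums those hard labels per
stimulus over all its flashes and takes the argmax; ties go to the lowest
stimulus index so replays are deterministic. Trials chain two selections:
a continent, then a place within whichever continent was (rightly or
wrongly) selected; each selection is scored independently against its
instructed target.

Throughput is summarized by the Wolpaw rate,
`log2 M + P log2 P + (1−P) log2((1−P)/(M−1))` bits per selection scaled by
`60/T`, with `0 log 0 := 0`. It assumes symmetric confusions and i.i.d.
selections; it is used as a summary statistic, not a channel-capacity
claim.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| ISI | 187.5 ms | flash-onset-to-onset spacing; treated as the full inter-stimulus interval (the split into stimulus and blink time only affects graphics) |
| flashes per stimulus | 30 training / 20 online | yields 180/900 and, over two online sessions, 480/2400 target/nontarget epochs |
| band | 0.5–10 Hz | 4th-order Butterworth, applied forward–backward (zero phase); the P300 is a low-frequency component |
| epoch window | [200, 600) ms | half-open; sample counts use floor(), so 204 samples at 512 Hz and 51 at 128 Hz |
| baseline | whole-epoch mean | the window starts at +200 ms, so no pre-stimulus segment exists inside it; mean subtraction per channel per epoch is the statistic consistent with epoching-before-baseline, and it is idempotent |
| feature rate | 128 Hz | decimation precedes flattening; 32 × 51 = 1,632 features |
| `p_enter` / `p_remove` | 0.05 / 0.10 | classical SWLDA convention; note a retained feature's final p may lie in [0.05, 0.10) |
| `max_features` | 60 | standard cap bounding the 1,632-feature search |
| score threshold | 0.5 | midpoint of the {0,1} class codes; exposed because only the hard-label behaviour is fixed |
| response times | 6.62/11.37/17.75/23.87/30.5 s | per-N selection times including an empirical system delay; configuration constants, not derivable from the ISI |
| permutations / q | 10,000 / 0.05 | permutation count and BY FDR level for the ERP contrast |

Open choices resolved here: the linear rule refits OLS weights on the
selected set (reusing the stepwise coefficients is equivalent up to the
final backward pass and is available by fitting manually); 128 Hz
decimation happens before flattening (identical values either way for
sample-aligned grids); ERP statistics are computed per channel with Cz as
the default.

## The synthetic generator

`simulate_session` emulates the stimulation structure exactly — randomized
rounds (each stimulus once per round, immediate cross-round repeats
avoided), per-block targets, 2 s inter-block gaps — and the signal
approximately:

- **Background**: per-channel 1/f (pink) noise, RMS 7 µV in the broadband
  record. The level was calibrated once so that the full pipeline's
  operating curve matches the band reported for real subjects
  (single-flash selection accuracy ≈ 49%, 20-flash accuracy ≈ 97–100%).
- **Response**: a Gaussian bump (peak 5 µV, latency 350 ms, width 80 ms ≈
  4σ) added at every target flash, with per-event latency jitter (SD
  20 ms) and amplitude jitter (SD 1 µV). A zero-amplitude template is the
  explicit null condition and injects nothing.
- **Topography**: an explicit 32-channel map with a unique maximum at Oz,
  moderate frontal-midline weight and attenuated lateral/temporal sites.
  The shape matters because the common average reference subtracts the
  spatial mean: the *residual* per-channel effect is `w − mean(w)`, and
  the map was designed so the residual midline contrast is monotone
  (Fz 0.10 < Cz 0.20 < Pz 0.35 < Oz 0.65 in topography units). This makes
  the simulated cohort reproduce the qualitative findings expected of a
  P300 system — a BY-significant positive Cz cluster around the peak and
  selected-feature counts rising front-to-back along the midline.
- **Sampling rate**: sessions are synthesized at 512 Hz, the pipeline's
  post-decimation rate, since the synthetic signal is band-limited far
  below the 256 Hz Nyquist and the 2048 → 512 Hz step would be an
  identity on it. The resampler itself is exercised separately on
  synthesized sines (2048 → 512 Hz).

What the generator does **not** emulate: spatially correlated noise,
ocular/muscle artifacts, alpha rhythms, target-to-target-interval effects
on P300 amplitude, non-stationarity across a session, and inter-subject
latency/topography variability beyond fresh noise seeds. Passing tests
therefore show that the pipeline is correct and well calibrated under its
stated signal model — not that these accuracy levels transfer to any
particular recording.

## Numerical choices

- Stepwise entry scans are computed against an orthonormal basis of the
  included columns (partial t via residualized correlations); candidates
  whose residual norm vanishes (duplicates, constants) are skipped with a
  log note. Ties in the entry p-value go to the lowest column index.
- The permutation test uses the pooled-variance two-sample t per
  timepoint, label shuffles drawn as exact group-size reassignments, and
  the +1-smoothed estimator `p = (1 + #{|t*| ≥ |t|}) / (1 + n_perm)`, so
  p can never be 0. Zero-pooled-variance timepoints get p = 1 with a
  warning. The Benjamini–Yekutieli step-up (harmonic-sum factor) controls
  FDR under arbitrary dependence; the less conservative Benjamini–Hochberg
  mask is available for comparison and always contains the BY mask.
- Selection accuracy is kept at full precision; truncation to integer
  percent is display-only. Likert summaries use the population
  (divide-by-n) SD.
- Subsampling draws are without replacement per stimulus per selection;
  drawing all available epochs makes every repeat identical (SD = 0) and
  reproduces the full replay accuracy exactly.
- EDF export quantizes to 16 bits with per-channel symmetric physical
  ranges and 1 s records; recordings are padded with zeros to whole
  seconds (the simulator already rounds session durations up). Reading
  goes through MNE, which independently validates the writer.
- All randomness flows through `numpy` Generators; session-level seeds
  spawn independent child streams for schedule, noise and jitter, so any
  artifact is regenerable from its logged config and seed.

## Problem sizes used in the checks

The cohort-level checks simulate 10 subjects (training + two online
sessions each) for the default and null conditions, a 3-subject cohort at
noise 10 µV (a mid-range operating point spanning ~35% → ~90% accuracy)
for the blink-curve monotonicity check, and a 6-subject cohort at noise
4 µV (where stepwise entries are signal-driven) for the midline
feature-count profile. Null calibration of the permutation test uses 100
null datasets × 51 timepoints at 999 permutations each; the p-value
estimator's calibration does not depend on the permutation count.

## Known limitations

- OLS-on-{0,1} with a 1:5 class imbalance centers scores near the 1/6
  base rate, so the fixed 0.5 threshold trades single-epoch sensitivity
  for specificity; the vote absorbs this at realistic SNR, but very weak
  signals degrade through a low true-positive rate rather than false
  positives.
- With ~1,600 candidate features, stepwise selection on pure noise still
  fills its feature budget (the smallest of 1,600 p-values is almost
  always < 0.05); the null cohort stays at chance because those features
  carry no information, not because selection is empty.
- No artifact handling anywhere, by design: every epoch is used.
- ERP statistics correct per timepoint only; no cluster-based permutation
  correction is provided.
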