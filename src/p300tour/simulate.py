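"""Synthetic oddball EEG sessions with ground truth.

Emulates the stimulation structure of a 6-stimulus single-display P300
paradigm: randomized flash rounds at a fixed inter-stimulus interval,
training blocks of 30 flashes per stimulus per target and online selections
of 20, with a parametric P300-like bump injected at target flashes on top
of 1/f background noise. Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .types import CHANNELS_32, ContinuousEEG, ErpTemplate, StimulusSchedule

#: Anterior-posterior coordinate per 10-20 row prefix (0 = frontal pole,
#: 1 = occipital). Fallback gain map for non-standard montages.
_AP_COORD = {
    "FP": 0.00, "AF": 0.12, "F": 0.25, "FC": 0.40, "T": 0.50,
    "C": 0.55, "CP": 0.70, "P": 0.82, "PO": 0.92, "O": 1.00,
}

#: Default per-channel gain for the standard 32-channel montage: a
#: midline-focal parieto-occipital maximum (unique peak at Oz) with a
#: moderate frontal-midline contribution and attenuated lateral-frontal
#: and temporal sites, i.e. the classic P3a/P3b spatial profile rising
#: front to back along the midline (Fz < Cz < Pz < Oz).
_TOPO_32 = {
    "FP1": 0.05, "FP2": 0.05, "AF3": 0.08, "AF4": 0.08,
    "F7": 0.08, "F8": 0.08, "F3": 0.15, "F4": 0.15, "Fz": 0.25,
    "FC1": 0.20, "FC2": 0.20, "FC5": 0.15, "FC6": 0.15,
    "T7": 0.10, "T8": 0.10,
    "C3": 0.25, "C4": 0.25, "Cz": 0.55,
    "CP1": 0.35, "CP2": 0.35, "CP5": 0.30, "CP6": 0.30,
    "P7": 0.35, "P8": 0.35, "P3": 0.60, "P4": 0.60, "Pz": 0.70,
    "PO3": 0.80, "PO4": 0.80,
    "O1": 0.85, "O2": 0.85, "Oz": 1.00,
}


def _row_prefix(name: str) -> str:
    prefix = "".join(c for c in name if c.isalpha()).upper()
    for p in ("FP", "AF", "FC", "CP", "PO"):
        if prefix.startswith(p):
            return p
    return prefix[0]


def default_topography(channel_names=CHANNELS_32) -> np.ndarray:
    """Per-channel gain in [0, 1], maximal at parieto-occipital midline.

    Standard 10-20 names get the explicit P300-like map (peak at Oz);
    anything else falls back to a plain front-to-back gradient.
    """
    return np.array(
        [
            _TOPO_32.get(c, 0.15 + 0.85 * _AP_COORD.get(_row_prefix(c), 0.5))
            for c in channel_names
        ]
    )


def build_stimulus_schedule(
    n_stimuli: int = 6,
    blinks_per_stimulus: int = 30,
    isi_ms: float = 187.5,
    target_id: int = 0,
    seed: int | None = None,
    *,
    t_start: float = 0.0,
    block_id: int = 0,
    rng: np.random.Generator | None = None,
) -> StimulusSchedule:
    """One selection block of randomized flash rounds.

    Each round is a random permutation of all stimulus ids, so every
    stimulus flashes exactly ``blinks_per_stimulus`` times. Immediate
    same-stimulus repeats across round boundaries are avoided by swapping
    the first two entries of the offending round.
    """
    if n_stimuli < 2:
        raise ValueError("n_stimuli must be at least 2")
    if blinks_per_stimulus < 1:
        raise ValueError("blinks_per_stimulus must be at least 1")
    if not 0 <= target_id < n_stimuli:
        raise ValueError(f"target_id {target_id} outside [0, {n_stimuli})")
    if isi_ms <= 0:
        raise ValueError("isi_ms must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    order = np.empty(n_stimuli * blinks_per_stimulus, dtype=int)
    prev_last = -1
    for r in range(blinks_per_stimulus):
        perm = rng.permutation(n_stimuli)
        if perm[0] == prev_last:
            perm[[0, 1]] = perm[[1, 0]]
        order[r * n_stimuli : (r + 1) * n_stimuli] = perm
        prev_last = perm[-1]

    onsets = t_start + np.arange(order.size) * (isi_ms / 1000.0)
    return StimulusSchedule(
        onsets=onsets,
        stimulus_ids=order,
        block_ids=np.full(order.size, block_id),
        is_target=order == target_id,
        isi_ms=isi_ms,
        n_stimuli=n_stimuli,
        blinks_per_stimulus=blinks_per_stimulus,
    )


def generate_background(
    n_channels: int = 32,
    sfreq: float = 512.0,
    duration: float = 10.0,
    noise_scale: float = 7.0,
    seed: int | None = None,
    *,
    channel_names: tuple[str, ...] | None = None,
    rng: np.random.Generator | None = None,
) -> ContinuousEEG:
    """Zero-mean 1/f-weighted (pink) noise, RMS ``noise_scale`` uV per channel."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    if channel_names is None:
        channel_names = (
            CHANNELS_32 if n_channels == 32 else tuple(f"CH{i}" for i in range(n_channels))
        )
    n = int(round(duration * sfreq))
    if noise_scale == 0:
        return ContinuousEEG(np.zeros((n_channels, n)), sfreq, channel_names)
    if rng is None:
        rng = np.random.default_rng(seed)

    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    f0 = freqs[1] if freqs.size > 1 else 1.0
    amp = 1.0 / np.sqrt(np.maximum(freqs, f0))  # power ~ 1/f
    amp[0] = 0.0  # no DC
    data = np.fft.irfft(spec * amp, n=n, axis=1)
    data -= data.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(data**2, axis=1, keepdims=True))
    data *= noise_scale / rms
    return ContinuousEEG(data, sfreq, channel_names)


def inject_erp(
    eeg: ContinuousEEG,
    schedule: StimulusSchedule,
    template: ErpTemplate,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> ContinuousEEG:
    """Add the template bump at every target event; nontargets untouched.

    Peak latency and amplitude are jittered per event. The input record is
    not mutated. Raises if any event's response window would run past the
    end of the recording.
    """
    out = eeg.copy()
    if template.peak_amplitude == 0:
        return out  # null template: nothing to inject
    if rng is None:
        rng = np.random.default_rng(seed)

    topo = template.topography
    if topo is None:
        topo = default_topography(eeg.channel_names)
    topo = np.asarray(topo, dtype=float)
    if topo.size != eeg.n_channels:
        raise ValueError("topography must have one weight per channel")

    sigma_s = template.sigma_ms / 1000.0
    half = 3.0 * sigma_s
    t = np.arange(eeg.n_samples) / eeg.sfreq
    targets = np.flatnonzero(schedule.is_target)
    lat = template.peak_latency_ms / 1000.0 + rng.normal(
        0.0, template.latency_jitter_sd_ms / 1000.0, size=targets.size
    )
    amp = template.peak_amplitude + rng.normal(
        0.0, template.amplitude_jitter_sd, size=targets.size
    )
    for k, ev in enumerate(targets):
        center = schedule.onsets[ev] + lat[k]
        if center + half > eeg.duration:
            raise ValueError(
                f"event {ev} (onset {schedule.onsets[ev]:.3f}s) response window "
                f"exceeds recording end at {eeg.duration:.3f}s"
            )
        i0 = max(0, int(np.floor((center - half) * eeg.sfreq)))
        i1 = min(eeg.n_samples, int(np.ceil((center + half) * eeg.sfreq)) + 1)
        bump = amp[k] * np.exp(-0.5 * ((t[i0:i1] - center) / sigma_s) ** 2)
        out.data[:, i0:i1] += np.outer(topo, bump)
    return out


def simulate_session(
    kind: str = "training",
    template: ErpTemplate | None = None,
    noise_scale: float = 7.0,
    seed: int = 0,
    *,
    sfreq: float = 512.0,
    channel_names: tuple[str, ...] = CHANNELS_32,
    n_stimuli: int = 6,
    isi_ms: float = 187.5,
    gap_s: float = 2.0,
    blinks_per_stimulus: int | None = None,
    n_trials: int = 6,
) -> tuple[ContinuousEEG, StimulusSchedule, np.ndarray]:
    """Simulate one full session and return (record, schedule, true targets).

    ``training``: 6 sequential blocks, one per stimulus as target, 30
    flashes per stimulus per block (180 target / 900 nontarget events).
    ``online``: ``n_trials`` trials of two selections each (continent then
    place), 20 flashes per stimulus, targets drawn uniformly at random.
    Blocks are separated by ``gap_s`` seconds of plain background.
    """
    if kind not in ("training", "online"):
        raise ValueError(f"kind must be 'training' or 'online', got {kind!r}")
    if template is None:
        template = ErpTemplate()
    ss = np.random.SeedSequence(seed)
    rng_sched, rng_noise, rng_erp = (np.random.default_rng(s) for s in ss.spawn(3))

    if kind == "training":
        blinks = 30 if blinks_per_stimulus is None else blinks_per_stimulus
        targets = np.arange(n_stimuli)
    else:
        blinks = 20 if blinks_per_stimulus is None else blinks_per_stimulus
        targets = rng_sched.integers(0, n_stimuli, size=2 * n_trials)

    parts: list[StimulusSchedule] = []
    t = gap_s
    for b, tgt in enumerate(targets):
        block = build_stimulus_schedule(
            n_stimuli, blinks, isi_ms, int(tgt), t_start=t, block_id=b, rng=rng_sched
        )
        parts.append(block)
        t = block.onsets[-1] + isi_ms / 1000.0 + gap_s
    schedule = StimulusSchedule.concat(parts)
    schedule.blinks_per_stimulus = blinks

    duration = float(np.ceil(t + 1.0))  # whole-second tail for EDF records
    eeg = generate_background(
        len(channel_names), sfreq, duration, noise_scale,
        channel_names=channel_names, rng=rng_noise,
    )
    eeg = inject_erp(eeg, schedule, template, rng=rng_erp)
    return eeg, schedule, targets.astype(int)
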