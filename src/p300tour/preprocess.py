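"""Signal-processing chain from raw record to per-flash feature vectors.

Order of operations: resample (2048 -> 512 Hz in the reference setup),
common average reference, 0.5-10 Hz zero-phase band-pass, epoch extraction
over [200, 600) ms post-flash, per-epoch baseline correction, decimation to
128 Hz and channel-major flattening. No artifact detection or rejection is
performed anywhere in the chain; every epoch is kept.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .types import ContinuousEEG, EpochSet, FeatureMatrix, StimulusSchedule


def _resample_factors(sfreq: float, target: float) -> tuple[int, int]:
    frac = Fraction(target / sfreq).limit_denominator(1000)
    return frac.numerator, frac.denominator


def resample(eeg: ContinuousEEG, target_sfreq: float) -> ContinuousEEG:
    """Anti-alias filter and resample to ``target_sfreq`` (<= source rate)."""
    if target_sfreq <= 0:
        raise ValueError("target_sfreq must be positive")
    if target_sfreq > eeg.sfreq:
        raise ValueError(
            f"target_sfreq {target_sfreq} above source rate {eeg.sfreq}"
        )
    if target_sfreq == eeg.sfreq:
        return eeg.copy()
    up, down = _resample_factors(eeg.sfreq, target_sfreq)
    data = signal.resample_poly(eeg.data, up, down, axis=1)
    return ContinuousEEG(data, target_sfreq, eeg.channel_names)


def common_average_reference(eeg: ContinuousEEG) -> ContinuousEEG:
    """Subtract the instantaneous across-channel mean from every channel."""
    if eeg.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return ContinuousEEG(data, eeg.sfreq, eeg.channel_names)


def bandpass(
    eeg: ContinuousEEG, low: float = 0.5, high: float = 10.0, order: int = 4
) -> ContinuousEEG:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    nyq = eeg.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) Hz for sfreq {eeg.sfreq}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=eeg.sfreq, output="sos")
    data = signal.sosfiltfilt(sos, eeg.data, axis=1)
    return ContinuousEEG(data, eeg.sfreq, eeg.channel_names)


def extract_epochs(
    eeg: ContinuousEEG,
    schedule: StimulusSchedule,
    window_ms: tuple[float, float] = (200.0, 600.0),
) -> EpochSet:
    """Cut one half-open ``[start, end)`` window per flash event.

    Sample counts use floor((end-start)/1000 * sfreq), so a [200, 600) ms
    window yields 204 samples at 512 Hz and 51 at 128 Hz.
    """
    w0, w1 = window_ms
    if w0 >= w1:
        raise ValueError("window start must precede end")
    offset = int(round(w0 / 1000.0 * eeg.sfreq))
    n_samp = int(np.floor((w1 - w0) / 1000.0 * eeg.sfreq))
    if schedule.n_events == 0:
        return EpochSet(
            data=np.empty((0, eeg.n_channels, n_samp)),
            labels=np.empty(0, dtype=int),
            stimulus_ids=np.empty(0, dtype=int),
            block_ids=np.empty(0, dtype=int),
            window_ms=window_ms,
            sfreq=eeg.sfreq,
            channel_names=eeg.channel_names,
        )
    onset_idx = np.round(schedule.onsets * eeg.sfreq).astype(int)
    start = onset_idx + offset
    bad = np.flatnonzero((start < 0) | (start + n_samp > eeg.n_samples))
    if bad.size:
        ev = int(bad[0])
        raise ValueError(
            f"event {ev} (onset {schedule.onsets[ev]:.3f}s) epoch window "
            f"[{w0}, {w1}) ms falls outside the recording"
        )
    idx = start[:, None] + np.arange(n_samp)[None, :]
    data = eeg.data[:, idx].transpose(1, 0, 2)  # (epochs, channels, samples)
    return EpochSet(
        data=data,
        labels=schedule.is_target.astype(int),
        stimulus_ids=schedule.stimulus_ids,
        block_ids=schedule.block_ids,
        window_ms=window_ms,
        sfreq=eeg.sfreq,
        channel_names=eeg.channel_names,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch's per-channel mean over the whole window.

    The epoch starts 200 ms after flash onset, so there is no pre-stimulus
    segment inside it; whole-window mean subtraction is the baseline
    statistic consistent with epoching before correction. Idempotent.
    """
    if epochs.n_epochs == 0:
        raise ValueError("no epochs to baseline-correct")
    data = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    return EpochSet(
        data=data,
        labels=epochs.labels,
        stimulus_ids=epochs.stimulus_ids,
        block_ids=epochs.block_ids,
        window_ms=epochs.window_ms,
        sfreq=epochs.sfreq,
        channel_names=epochs.channel_names,
    )


def to_features(epochs: EpochSet, feature_sfreq: float = 128.0) -> FeatureMatrix:
    """Decimate epochs to ``feature_sfreq`` and flatten channel-major.

    Column ``c * n_times + t`` holds channel c at timepoint t; the returned
    ``feature_map`` records the (channel name, time in ms) of every column.
    """
    if feature_sfreq > epochs.sfreq:
        raise ValueError("feature_sfreq must not exceed the epoch sampling rate")
    data = epochs.data
    if feature_sfreq < epochs.sfreq:
        up, down = _resample_factors(epochs.sfreq, feature_sfreq)
        data = signal.resample_poly(data, up, down, axis=2)
    n_ep, n_ch, n_t = data.shape
    times = epochs.window_ms[0] + np.arange(n_t) / feature_sfreq * 1000.0
    feature_map = [
        (ch, float(tm)) for ch in epochs.channel_names for tm in times
    ]
    return FeatureMatrix(
        values=data.reshape(n_ep, n_ch * n_t),
        feature_map=feature_map,
        labels=epochs.labels,
        stimulus_ids=epochs.stimulus_ids,
        block_ids=epochs.block_ids,
    )


def preprocess(
    eeg: ContinuousEEG,
    schedule: StimulusSchedule,
    *,
    resample_to: float = 512.0,
    band: tuple[float, float] = (0.5, 10.0),
    window_ms: tuple[float, float] = (200.0, 600.0),
    feature_sfreq: float = 128.0,
    return_epochs: bool = False,
):
    """Full chain: resample -> CAR -> band-pass -> epoch -> baseline -> features."""
    x = resample(eeg, min(resample_to, eeg.sfreq))
    x = common_average_reference(x)
    x = bandpass(x, *band)
    epochs = extract_epochs(x, schedule, window_ms)
    epochs = baseline_correct(epochs)
    features = to_features(epochs, feature_sfreq)
    if return_epochs:
        return features, epochs
    return features
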