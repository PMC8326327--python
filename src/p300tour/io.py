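"""File formats: EDF recordings, CSV event tables, HDF5 epoch containers,
JSON model documents and the run configuration.

Conventions used everywhere: onsets are stored in seconds as floats,
sample indexing is 0-based, epoch windows half-open. Continuous records are
written as 16-bit EDF with 1-second data records (recordings are padded
with zeros to a whole-second length when needed); reading goes through MNE,
which keeps the writer honest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ContinuousEEG, EpochSet, StimulusSchedule

EVENT_COLUMNS = ("onset_s", "stimulus_id", "block_id", "is_target")


# ---------------------------------------------------------------------------
# EDF


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int = 8) -> bytes:
    for fmt in (f"{value:.6g}", f"{value:.3g}", f"{value:.1g}"):
        if len(fmt) <= width:
            return _ascii(fmt, width)
    return _ascii(f"{value:.0e}", width)


def write_edf(path: str | Path, eeg: ContinuousEEG) -> Path:
    """Write a minimal 16-bit EDF file (amplitudes in uV, 1-s records)."""
    path = Path(path)
    sfreq = eeg.sfreq
    spr = int(round(sfreq))
    if abs(spr - sfreq) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate in Hz")
    n_records = int(np.ceil(eeg.n_samples / spr))
    data = eeg.data
    pad = n_records * spr - eeg.n_samples
    if pad:
        data = np.pad(data, ((0, 0), (0, pad)))

    ns = eeg.n_channels
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    digital = np.round(data / phys_max[:, None] * 32767.0).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X", 80),                       # patient id
            _ascii("Startdate X p300tour", 80),    # recording id
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),                          # record duration (s)
            _ascii(ns, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_ascii(c, 16) for c in eeg.channel_names),
            b"".join(_ascii("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(_ascii("uV", 8) for _ in range(ns)),
            b"".join(_num(-m) for m in phys_max),
            b"".join(_num(m) for m in phys_max),
            b"".join(_ascii(-32767, 8) for _ in range(ns)),
            b"".join(_ascii(32767, 8) for _ in range(ns)),
            b"".join(_ascii("", 80) for _ in range(ns)),
            b"".join(_ascii(spr, 8) for _ in range(ns)),
            b"".join(_ascii("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        # record-interleaved: per record, all samples of ch0, then ch1, ...
        rec = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
        fh.write(rec.tobytes())
    return path


def read_edf(path: str | Path) -> ContinuousEEG:
    """Read an EDF recording back into microvolts (via MNE)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    return ContinuousEEG(data, float(raw.info["sfreq"]), tuple(raw.ch_names))


# ---------------------------------------------------------------------------
# Event tables


def write_events_csv(path: str | Path, schedule: StimulusSchedule) -> Path:
    path = Path(path)
    schedule.to_frame().to_csv(path, index=False, float_format="%.6f")
    return path


def read_events_csv(path: str | Path, isi_ms: float | None = None) -> StimulusSchedule:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file {path} lacks column {missing[0]!r}")
    onsets = df["onset_s"].to_numpy(float)
    stim = df["stimulus_id"].to_numpy(int)
    blocks = df["block_id"].to_numpy(int)
    if isi_ms is None:
        same_block = np.diff(blocks) == 0
        gaps = np.diff(onsets)[same_block]
        isi_ms = float(np.median(gaps) * 1000.0) if gaps.size else 187.5
    n_stimuli = int(stim.max()) + 1 if stim.size else 6
    first_block = blocks == blocks[0] if blocks.size else blocks
    blinks = int(np.sum(first_block) // max(n_stimuli, 1)) if stim.size else 0
    return StimulusSchedule(
        onsets=onsets,
        stimulus_ids=stim,
        block_ids=blocks,
        is_target=df["is_target"].to_numpy(bool),
        isi_ms=isi_ms,
        n_stimuli=n_stimuli,
        blinks_per_stimulus=blinks,
    )


def read_eeg(
    path: str | Path, events_path: str | Path | None = None
) -> tuple[ContinuousEEG, StimulusSchedule | None]:
    """Read an EDF file and its companion event CSV, with validation."""
    eeg = read_edf(path)
    schedule = None
    if events_path is not None:
        schedule = read_events_csv(events_path)
        if schedule.n_events and schedule.onsets[-1] > eeg.duration:
            raise ValueError(
                f"event onset {schedule.onsets[-1]:.3f}s lies beyond the "
                f"{eeg.duration:.3f}s recording"
            )
    return eeg, schedule


# ---------------------------------------------------------------------------
# Epoch container (HDF5 keyed arrays + attributes)


def save_epochs(path: str | Path, epochs: EpochSet) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("stimulus_ids", data=epochs.stimulus_ids)
        f.create_dataset("block_ids", data=epochs.block_ids)
        f.attrs["window_ms"] = list(epochs.window_ms)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["channel_names"] = list(epochs.channel_names)
    return path


def load_epochs(path: str | Path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            labels=f["labels"][()],
            stimulus_ids=f["stimulus_ids"][()],
            block_ids=f["block_ids"][()],
            window_ms=tuple(f.attrs["window_ms"]),
            sfreq=float(f.attrs["sfreq"]),
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
        )


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Every numeric constant of the pipeline in one serializable record."""

    acquisition_sfreq: float = 2048.0
    processing_sfreq: float = 512.0
    feature_sfreq: float = 128.0
    band_hz: tuple[float, float] = (0.5, 10.0)
    window_ms: tuple[float, float] = (200.0, 600.0)
    isi_ms: float = 187.5
    n_stimuli: int = 6
    blinks_training: int = 30
    blinks_online: int = 20
    p_enter: float = 0.05
    p_remove: float = 0.10
    max_features: int = 60
    threshold: float = 0.5
    subsample_ns: tuple[int, ...] = (1, 5, 10, 15, 20)
    subsample_repeats: int = 10
    response_time_s: dict = field(
        default_factory=lambda: {1: 6.62, 5: 11.37, 10: 17.75, 15: 23.87, 20: 30.5}
    )
    n_permutations: int = 10_000
    alpha: float = 0.05
    fdr_q: float = 0.05
    noise_scale: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_hz[0] < self.band_hz[1]:
            raise ValueError("invalid band")
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("invalid epoch window")
        for name in ("acquisition_sfreq", "processing_sfreq", "feature_sfreq",
                     "isi_ms", "p_enter", "p_remove", "alpha", "fdr_q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_stimuli < 2:
            raise ValueError("n_stimuli must be at least 2")
        self.response_time_s = {int(k): float(v) for k, v in self.response_time_s.items()}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        d["window_ms"] = list(self.window_ms)
        d["subsample_ns"] = list(self.subsample_ns)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("band_hz", "window_ms", "subsample_ns"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
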