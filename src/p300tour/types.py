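"""Core in-memory containers for the P300 oddball pipeline.

All amplitudes are microvolts, all onsets seconds, all windows milliseconds
relative to flash onset. Sample indexing is 0-based and epoch windows are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 32-electrode 10-20 montage used throughout (frontal to occipital
#: coverage; Fz/Cz/Pz/Oz are the midline sites).
CHANNELS_32: tuple[str, ...] = (
    "FP1", "AF3", "F7", "F3", "FC1", "FC5", "FC6", "FC2", "F4", "F8",
    "AF4", "FP2", "Fz", "C3", "CP1", "CP5", "CP6", "CP2", "C4", "Cz",
    "P7", "P3", "Pz", "PO3", "PO4", "P4", "P8", "T7", "T8", "O1", "Oz", "O2",
)


@dataclass
class StimulusSchedule:
    """Timed flash events for one or more 6-way selection blocks.

    Within a block every stimulus flashes exactly ``blinks_per_stimulus``
    times at a constant onset-to-onset spacing of ``isi_ms``, and exactly
    one stimulus id carries ``is_target`` on all of its events.
    """

    onsets: np.ndarray          # (n_events,) seconds, strictly increasing
    stimulus_ids: np.ndarray    # (n_events,) int in [0, n_stimuli)
    block_ids: np.ndarray       # (n_events,) int selection-block id
    is_target: np.ndarray       # (n_events,) bool
    isi_ms: float = 187.5
    n_stimuli: int = 6
    blinks_per_stimulus: int = 30

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids, dtype=int)
        self.block_ids = np.asarray(self.block_ids, dtype=int)
        self.is_target = np.asarray(self.is_target, dtype=bool)
        n = self.onsets.size
        if not (self.stimulus_ids.size == self.block_ids.size == self.is_target.size == n):
            raise ValueError("schedule arrays must share one length")
        if n > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    @property
    def blocks(self) -> np.ndarray:
        return np.unique(self.block_ids)

    def block_target(self, block_id: int) -> int:
        """Ground-truth target stimulus of one block (from the target flags)."""
        m = (self.block_ids == block_id) & self.is_target
        ids = np.unique(self.stimulus_ids[m])
        if ids.size != 1:
            raise ValueError(f"block {block_id} has {ids.size} target stimuli")
        return int(ids[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "onset_s": self.onsets,
                "stimulus_id": self.stimulus_ids,
                "block_id": self.block_ids,
                "is_target": self.is_target.astype(int),
            }
        )

    @classmethod
    def concat(cls, parts: list["StimulusSchedule"]) -> "StimulusSchedule":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        return cls(
            onsets=np.concatenate([p.onsets for p in parts]),
            stimulus_ids=np.concatenate([p.stimulus_ids for p in parts]),
            block_ids=np.concatenate([p.block_ids for p in parts]),
            is_target=np.concatenate([p.is_target for p in parts]),
            isi_ms=first.isi_ms,
            n_stimuli=first.n_stimuli,
            blinks_per_stimulus=first.blinks_per_stimulus,
        )


@dataclass
class ContinuousEEG:
    """A channels x samples amplitude record in microvolts."""

    data: np.ndarray                 # (n_channels, n_samples) float
    sfreq: float                     # Hz
    channel_names: tuple[str, ...] = CHANNELS_32

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.channel_names = tuple(self.channel_names)
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def copy(self) -> "ContinuousEEG":
        return ContinuousEEG(self.data.copy(), self.sfreq, self.channel_names)


@dataclass
class ErpTemplate:
    """Parametric stimulus-locked response injected at target flashes.

    The waveform is a Gaussian bump: ``width_ms`` is its full width
    (about four standard deviations), ``topography`` gives per-channel
    gain in [0, 1]. ``peak_amplitude == 0`` denotes the null template.
    """

    peak_amplitude: float = 5.0        # uV
    peak_latency_ms: float = 350.0     # ms after flash onset
    width_ms: float = 80.0             # full temporal spread, ~4 sigma
    topography: np.ndarray | None = None   # one weight per channel, in [0, 1]
    latency_jitter_sd_ms: float = 20.0
    amplitude_jitter_sd: float = 1.0   # uV

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if self.latency_jitter_sd_ms < 0 or self.amplitude_jitter_sd < 0:
            raise ValueError("jitter SDs must be non-negative")
        if self.topography is not None:
            self.topography = np.asarray(self.topography, dtype=float)

    @property
    def sigma_ms(self) -> float:
        return self.width_ms / 2.0


@dataclass
class EpochSet:
    """Per-flash signal windows with their labels and block membership."""

    data: np.ndarray            # (n_epochs, n_channels, n_samples)
    labels: np.ndarray          # (n_epochs,) 0/1 target flag
    stimulus_ids: np.ndarray
    block_ids: np.ndarray
    window_ms: tuple[float, float]
    sfreq: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.stimulus_ids = np.asarray(self.stimulus_ids, dtype=int)
        self.block_ids = np.asarray(self.block_ids, dtype=int)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epochs, channels, samples)")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window start must precede end")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window_ms[0] + np.arange(n) / self.sfreq * 1000.0


@dataclass
class FeatureMatrix:
    """Flattened channel-major epoch amplitudes plus the (channel, time) map.

    ``feature_map[j] == (channel_name, time_ms)`` for column j; the map is a
    bijection onto the channels x timepoints grid. Epoch metadata rides along
    so downstream voting can group by selection block and stimulus.
    """

    values: np.ndarray                       # (n_epochs, n_features)
    feature_map: list[tuple[str, float]]
    labels: np.ndarray | None = None
    stimulus_ids: np.ndarray | None = None
    block_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (epochs x features)")
        if len(self.feature_map) != self.values.shape[1]:
            raise ValueError("feature_map length must equal feature count")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SelectionResult:
    """Outcome of one 6-way vote: per-stimulus summed hard labels."""

    votes: np.ndarray           # (n_stimuli,) summed 0/1 labels
    predicted: int
    true_target: int | None = None
    n_blinks_used: int = 0

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=int)

    @property
    def correct(self) -> bool | None:
        if self.true_target is None:
            return None
        return self.predicted == int(self.true_target)


@dataclass
class TrialRecord:
    """One two-step (continent then place) trial of the selection game."""

    continent: SelectionResult
    place: SelectionResult
    instructed_continent: int
    instructed_place: int
    continent_name: str | None = None
    place_name: str | None = None

    @property
    def both_correct(self) -> bool:
        return bool(self.continent.correct) and bool(self.place.correct)


@dataclass
class SessionRecord:
    """Trials of one online session plus the destination catalogue used."""

    trials: list[TrialRecord] = field(default_factory=list)
    catalogue: dict[str, list[str]] | None = None

    @property
    def selections(self) -> list[SelectionResult]:
        out: list[SelectionResult] = []
        for t in self.trials:
            out.extend([t.continent, t.place])
        return out
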