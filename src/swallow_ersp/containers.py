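"""In-memory containers for continuous and epoched EEG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default epoch span relative to the swallowing cue, in ms.
EPOCH_SPAN_MS: tuple[float, float] = (-1000.0, 5000.0)


@dataclass
class Recording:
    """Continuous multichannel EEG.

    data : (n_channels, n_samples) array, microvolts
    rate : sampling rate in Hz
    channel_labels : 10-20 electrode names, one per row of ``data``
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.rate

    def copy_with(self, data: np.ndarray, rate: float | None = None) -> "Recording":
        return Recording(
            data=data,
            rate=self.rate if rate is None else rate,
            channel_labels=list(self.channel_labels),
            subject_id=self.subject_id,
            group_label=self.group_label,
        )


@dataclass
class EpochedRecording:
    """Stack of cue-locked trials.

    data : (n_trials, n_channels, n_samples) array, microvolts
    tmin_ms : time of the first sample relative to the cue
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    tmin_ms: float = EPOCH_SPAN_MS[0]
    subject_id: str = ""
    group_label: str = ""
    n_valid_trials: int = field(default=-1)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                "EpochedRecording.data must be 3-D (trials x channels x samples)"
            )
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel count does not match labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.n_valid_trials < 0:
            self.n_valid_trials = self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def time_axis_ms(self) -> np.ndarray:
        """Per-sample times in ms relative to the cue."""
        return self.tmin_ms + 1000.0 * np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        """(n_trials, n_samples) view of one channel."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[:, idx, :]

    def copy_with(self, data: np.ndarray) -> "EpochedRecording":
        return EpochedRecording(
            data=data,
            rate=self.rate,
            channel_labels=list(self.channel_labels),
            tmin_ms=self.tmin_ms,
            subject_id=self.subject_id,
            group_label=self.group_label,
            n_valid_trials=self.n_valid_trials,
        )
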