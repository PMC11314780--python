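"""Core containers: multichannel recordings, epoch stacks and frequency bands.

A :class:`MultichannelRecording` holds continuous data as a samples x channels
float array with its sample rate and an ordered list of unique channel labels.
An :class:`EpochSet` is a stack of fixed-length, non-overlapping, temporally
ordered epochs cut from one recording; it is the unit on which connectivity
is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MultichannelRecording",
    "EpochSet",
    "FrequencyBand",
    "DEFAULT_BANDS",
]

#: Montage identifiers accepted on ingestion. ANALYSIS52 marks a recording
#: already reduced to the canonical 52-channel analysis set.
KNOWN_MONTAGES = ("CAP60", "CAP64", "CAP128", "ANALYSIS52", "SYNTH")


@dataclass
class MultichannelRecording:
    """Continuous multichannel signal (samples x channels)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    montage_id: str = "SYNTH"
    subject_id: str | None = None
    timepoint: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D samples x channels array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[1]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray | None = None, **kwargs) -> "MultichannelRecording":
        """Return a copy with selected fields replaced."""
        return MultichannelRecording(
            data=self.data.copy() if data is None else data,
            fs=kwargs.get("fs", self.fs),
            channel_labels=kwargs.get("channel_labels", list(self.channel_labels)),
            montage_id=kwargs.get("montage_id", self.montage_id),
            subject_id=kwargs.get("subject_id", self.subject_id),
            timepoint=kwargs.get("timepoint", self.timepoint),
        )


@dataclass
class EpochSet:
    """Stack of fixed-length epochs: epochs x samples x channels."""

    epochs: np.ndarray
    fs: float
    epoch_length: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch, sample, channel)")
        expected = int(round(self.epoch_length * self.fs))
        if self.epochs.shape[1] != expected:
            raise ValueError(
                f"each epoch must have {expected} samples, got {self.epochs.shape[1]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[2]


@dataclass(frozen=True)
class FrequencyBand:
    """Half-open frequency interval [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band {self.name}: need 0 < low < high")

    def validate_for_fs(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz at or above Nyquist ({fs / 2} Hz)"
            )

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequency bins inside [low, high)."""
        freqs = np.asarray(freqs)
        return (freqs >= self.low) & (freqs < self.high)


#: The six analysis bands: delta, theta, low alpha, high alpha, beta, gamma.
#: Half-open edges mean adjacent bands never share a frequency bin.
DEFAULT_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 2.0, 4.0),
    FrequencyBand("theta", 4.0, 6.0),
    FrequencyBand("low_alpha", 6.0, 9.0),
    FrequencyBand("high_alpha", 9.0, 13.0),
    FrequencyBand("beta", 13.0, 30.0),
    FrequencyBand("gamma", 30.0, 45.0),
)

BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}
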