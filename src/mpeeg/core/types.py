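"""Core EEG data model: continuous recordings, epoched recordings, montages."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np


class Group(str, Enum):
    """Subject group label."""

    HC = "HC"
    PD = "PD"
    PD_OFF = "PD_OFF"
    PD_ON = "PD_ON"


#: The 32-channel montage common to both target acquisition systems,
#: in canonical order.
STANDARD_32_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)


class ValidationError(ValueError):
    """Raised when input data violates a documented precondition."""


@dataclass
class Recording:
    """One subject's continuous multi-channel EEG.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : Group
        Clinical group label.
    fs : float
        Sampling rate in Hz, strictly positive.
    channels : sequence of str
        Ordered, unique channel labels; one per data row.
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    """

    subject_id: str
    group: Group
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValidationError(
                f"data must be 2-D (channels x samples), got shape {self.data.shape}"
            )
        if self.data.shape[0] != len(self.channels):
            raise ValidationError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} channel labels"
            )
        if self.data.shape[1] < 1:
            raise ValidationError("recording must contain at least one sample")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def duration_s(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with selected fields replaced."""
        kwargs = dict(
            subject_id=self.subject_id,
            group=self.group,
            fs=self.fs,
            channels=self.channels,
            data=self.data,
        )
        kwargs.update(changes)
        return Recording(**kwargs)


@dataclass
class EpochedRecording:
    """A recording cut into fixed-length, non-overlapping epochs.

    ``epochs`` has shape (n_epochs, n_channels, samples_per_epoch);
    ``samples_per_epoch == round(fs * epoch_length_s)``.
    """

    subject_id: str
    group: Group
    fs: float
    channels: tuple[str, ...]
    epochs: np.ndarray
    epoch_length_s: float

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.channels = tuple(self.channels)
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValidationError(
                f"epochs must be 3-D (epoch x channel x sample), got {self.epochs.shape}"
            )
        if self.epochs.shape[1] != len(self.channels):
            raise ValidationError("epoch channel dimension does not match channel labels")
        expected = int(round(self.fs * self.epoch_length_s))
        if self.epochs.shape[2] != expected:
            raise ValidationError(
                f"samples per epoch {self.epochs.shape[2]} != round(fs*epoch_length)={expected}"
            )

    @property
    def n_epochs(self) -> int:
        return int(self.epochs.shape[0])

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def samples_per_epoch(self) -> int:
        return int(self.epochs.shape[2])


@dataclass
class MontageSpec:
    """Target montage plus rules for imputing missing channels.

    ``imputation_rules`` maps a missing target label to the donor labels
    whose arithmetic mean replaces it.
    """

    target_channels: tuple[str, ...] = STANDARD_32_CHANNELS
    imputation_rules: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {"Pz": ("P1", "P2", "CPz", "POz")}
    )

    def __post_init__(self) -> None:
        self.target_channels = tuple(self.target_channels)
        if len(set(self.target_channels)) != len(self.target_channels):
            raise ValidationError("target channels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.target_channels)
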