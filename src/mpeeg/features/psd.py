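"""Band power (activation-pattern) features from epoched EEG."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..core.types import EpochedRecording, ValidationError
from .bands import CANONICAL_BANDS, BandDefinition


@dataclass
class PSDFeatures:
    """Per-epoch, per-channel, per-band power.

    ``values`` has shape (n_epochs, n_channels, n_bands) and is
    non-negative; entries are one-sided periodogram power summed over the
    DFT bins falling in ``[low_hz, high_hz)`` of each band.
    """

    subject_id: str
    group: str
    values: np.ndarray
    band_defs: tuple[BandDefinition, ...]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("PSD values must be epoch x channel x band")
        if np.any(self.values < 0):
            raise ValidationError("band power must be non-negative")


def periodogram_power(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram, |DFT|^2 / (fs * n), doubled off DC/Nyquist.

    Works over the last axis; returns (frequencies, power).
    """
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    p = (spec.real**2 + spec.imag**2) / (fs * n)
    p[..., 1:] *= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0  # Nyquist bin is not mirrored
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, p


def compute_psd(
    ep: EpochedRecording,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
) -> PSDFeatures:
    """Band power per epoch and channel via the DFT periodogram.

    Bins are assigned half-open, ``low <= f < high``, so bands tiling a
    range never double-count a bin.

    Raises
    ------
    ValidationError
        If some band contains no DFT bin at this epoch length.
    """
    freqs, power = periodogram_power(ep.epochs, ep.fs)
    out = np.empty((ep.n_epochs, ep.n_channels, len(bands)), dtype=np.float64)
    for bi, band in enumerate(bands):
        mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
        if not mask.any():
            raise ValidationError(
                f"band {band.name} [{band.low_hz}, {band.high_hz}) Hz contains no "
                f"DFT bin for epochs of {ep.samples_per_epoch} samples at {ep.fs} Hz"
            )
        out[:, :, bi] = power[:, :, mask].sum(axis=-1)
    return PSDFeatures(
        subject_id=ep.subject_id,
        group=ep.group.value,
        values=out,
        band_defs=tuple(bands),
        channels=ep.channels,
    )
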