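"""Phase-locking (connectivity-pattern) features.

The pipeline is: Hamming-windowed FIR band-pass -> Hilbert analytic phase
-> per-epoch phase-locking value for every unordered channel pair.  Group
means of PLV are taken in the Fisher (arctanh) domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from ..core.types import EpochedRecording, ValidationError
from .bands import CANONICAL_BANDS, BandDefinition, channel_pairs

#: Fraction of each epoch trimmed per side before averaging phase
#: differences, excluding Hilbert edge artifacts.
DEFAULT_EDGE_TRIM = 0.1


@dataclass
class PLVFeatures:
    """Per-epoch, per-pair, per-band phase-locking values in [0, 1].

    ``values`` has shape (n_epochs, n_pairs, n_bands); ``pair_index`` lists
    every unordered channel pair exactly once (496 pairs for 32 channels),
    first channel earlier in montage order.
    """

    subject_id: str
    group: str
    values: np.ndarray
    pair_index: tuple[tuple[str, str], ...]
    band_defs: tuple[BandDefinition, ...]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("PLV values must be epoch x pair x band")
        if np.any(self.values < 0) or np.any(self.values > 1.0 + 1e-12):
            raise ValidationError("PLV values must lie in [0, 1]")

    @property
    def pair_names(self) -> tuple[str, ...]:
        return tuple(f"{a}-{b}" for a, b in self.pair_index)


def design_fir_bandpass(band: BandDefinition, fs: float, n_samples: int) -> np.ndarray:
    """Hamming-window FIR band-pass taps.

    The nominal order is ``3 * fs / low_hz`` taps (a standard
    transition-width heuristic), capped so that zero-phase application on
    ``n_samples``-long epochs stays well-posed; always odd (type-I linear
    phase).
    """
    if not (0.0 < band.low_hz < band.high_hz < fs / 2.0):
        raise ValidationError(
            f"band {band.name} [{band.low_hz}, {band.high_hz}] must lie inside "
            f"(0, {fs / 2.0}) Hz"
        )
    numtaps = int(round(3.0 * fs / band.low_hz))
    cap = max((n_samples - 2) // 3, 3)  # filtfilt needs padlen < n
    numtaps = min(numtaps, cap)
    if numtaps % 2 == 0:
        numtaps -= 1
    numtaps = max(numtaps, 3)
    return signal.firwin(
        numtaps, [band.low_hz, band.high_hz], pass_zero=False, window="hamming", fs=fs
    )


def fir_bandpass(ep: EpochedRecording, band: BandDefinition) -> EpochedRecording:
    """Band-pass each epoch of each channel with a zero-phase FIR.

    Symmetric (forward-backward) application cancels the linear phase of
    the Hamming FIR, so no group-delay correction is needed.
    """
    taps = design_fir_bandpass(band, ep.fs, ep.samples_per_epoch)
    padlen = min(3 * len(taps), ep.samples_per_epoch - 1)
    filtered = signal.filtfilt(taps, [1.0], ep.epochs, axis=-1, padlen=padlen)
    return EpochedRecording(
        subject_id=ep.subject_id,
        group=ep.group,
        fs=ep.fs,
        channels=ep.channels,
        epochs=filtered,
        epoch_length_s=ep.epoch_length_s,
    )


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Phase of the analytic (Hilbert) signal, in (-pi, pi], last axis = time.

    All-zero series have undefined phase; a warning is emitted and the
    phase is set to 0 by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValidationError("need at least 2 samples to estimate phase")
    analytic = signal.hilbert(x, axis=-1)
    phase = np.angle(analytic)
    zero_rows = ~np.any(x != 0, axis=-1)
    if np.any(zero_rows):
        warnings.warn("all-zero signal has undefined phase; returning 0", RuntimeWarning)
        phase[zero_rows] = 0.0
    return phase


def compute_plv(
    ep: EpochedRecording,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    edge_trim: float = DEFAULT_EDGE_TRIM,
) -> PLVFeatures:
    """Per-epoch PLV for every unordered channel pair and band.

    For channels A, B in one epoch, ``PLV = |mean_t exp(-i (phi_A(t) -
    phi_B(t)))|`` over the epoch's time points after trimming
    ``edge_trim`` of the samples from each side.
    """
    if not 0.0 <= edge_trim < 0.5:
        raise ValidationError(f"edge_trim must be in [0, 0.5), got {edge_trim}")
    n_ch = ep.n_channels
    pairs = channel_pairs(ep.channels)
    iu = np.triu_indices(n_ch, k=1)
    spe = ep.samples_per_epoch
    lo = int(np.floor(edge_trim * spe))
    hi = spe - lo
    out = np.empty((ep.n_epochs, len(pairs), len(bands)), dtype=np.float64)
    for bi, band in enumerate(bands):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            phase = instantaneous_phase(fir_bandpass(ep, band).epochs)
        u = np.exp(1j * phase[:, :, lo:hi])  # (ep, ch, t), unit modulus
        n_t = u.shape[-1]
        # |sum_t u_A conj(u_B)| / n_t  for all pairs at once
        cross = np.einsum("ect,edt->ecd", u, np.conj(u)) / n_t
        out[:, :, bi] = np.abs(cross[:, iu[0], iu[1]])
    np.clip(out, 0.0, 1.0, out=out)
    return PLVFeatures(
        subject_id=ep.subject_id,
        group=ep.group.value,
        values=out,
        pair_index=pairs,
        band_defs=tuple(bands),
        channels=ep.channels,
    )


def fisher_mean_plv(values: Iterable[float]) -> float:
    """Mean of PLV-like values through the Fisher (arctanh) transform:
    ``tanh(mean(arctanh(v)))``.  Values at 1 are clipped to 1 - 1e-10."""
    arr = np.asarray(list(values) if np.ndim(values) == 0 else values, dtype=np.float64)
    arr = arr.reshape(-1)
    if arr.size == 0:
        raise ValidationError("cannot Fisher-average an empty collection")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("Fisher averaging expects values in [0, 1]")
    arr = np.minimum(arr, 1.0 - 1e-10)
    return float(np.tanh(np.mean(np.arctanh(arr))))


def fisher_mean_plv_axis(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Vectorized :func:`fisher_mean_plv` along one axis."""
    arr = np.minimum(np.asarray(values, dtype=np.float64), 1.0 - 1e-10)
    return np.tanh(np.mean(np.arctanh(arr), axis=axis))
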