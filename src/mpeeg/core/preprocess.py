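"""Continuous-signal preprocessing: band-pass filtering, montage
harmonization, truncation and epoching."""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy import signal

from .types import EpochedRecording, MontageSpec, Recording, ValidationError

#: Hook signature: takes a Recording, returns a cleaned Recording.  Artifact
#: removal (ICA etc.) is delegated to callers through this hook; the pipeline
#: otherwise assumes clean input.
PreprocessHook = Callable[[Recording], Recording]


def bandpass_filter(
    rec: Recording, low_hz: float, high_hz: float, order: int = 8
) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward (``sosfiltfilt``) application gives zero phase
    distortion; the effective magnitude response is the square of the
    single-pass response.

    Raises
    ------
    ValidationError
        Unless ``0 < low_hz < high_hz < fs/2``.
    """
    nyq = rec.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValidationError(
            f"band edges must satisfy 0 < low < high < fs/2={nyq}; "
            f"got low={low_hz}, high={high_hz}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=filtered)


def harmonize_montage(rec: Recording, spec: Optional[MontageSpec] = None) -> Recording:
    """Reduce/reorder a recording to the montage's target channels.

    A target channel absent from the recording is imputed as the arithmetic
    mean of its donor channels when an imputation rule exists and every
    donor is present.

    Raises
    ------
    ValidationError
        If a target channel is neither present nor imputable; the message
        lists the offending channels.
    """
    if spec is None:
        spec = MontageSpec()
    index = {label: i for i, label in enumerate(rec.channels)}
    rows = np.empty((spec.n_channels, rec.n_samples), dtype=np.float64)
    missing: list[str] = []
    for out_row, label in enumerate(spec.target_channels):
        if label in index:
            rows[out_row] = rec.data[index[label]]
            continue
        donors = spec.imputation_rules.get(label)
        if donors and all(d in index for d in donors):
            donor_rows = [index[d] for d in donors]
            rows[out_row] = rec.data[donor_rows].mean(axis=0)
        else:
            missing.append(label)
    if missing:
        raise ValidationError(
            "channels neither present nor imputable: " + ", ".join(missing)
        )
    return rec.copy_with(channels=spec.target_channels, data=rows)


def truncate(rec: Recording, duration_s: float) -> Recording:
    """Keep exactly the first ``duration_s`` seconds.

    Raises
    ------
    ValidationError
        If the recording is shorter than ``duration_s`` (message reports the
        available length).
    """
    n_keep = int(round(duration_s * rec.fs))
    if n_keep > rec.n_samples:
        raise ValidationError(
            f"requested {duration_s} s but only {rec.duration_s:.3f} s "
            f"({rec.n_samples} samples) available"
        )
    return rec.copy_with(data=rec.data[:, :n_keep].copy())


def segment(rec: Recording, epoch_length_s: float = 1.0) -> EpochedRecording:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing remainder shorter than one epoch is discarded, so
    ``n_epochs = floor(duration / epoch_length_s)``.  Sample values are
    copied bit-exactly; no filtering or scaling happens here.
    """
    if epoch_length_s <= 0:
        raise ValidationError(f"epoch length must be positive, got {epoch_length_s}")
    spe = int(round(rec.fs * epoch_length_s))
    if spe < 1:
        raise ValidationError(f"epoch length {epoch_length_s} s is under one sample")
    n_epochs = rec.n_samples // spe
    used = rec.data[:, : n_epochs * spe]
    # (ch, ep, t) -> (ep, ch, t)
    epochs = used.reshape(rec.n_channels, n_epochs, spe).transpose(1, 0, 2).copy()
    return EpochedRecording(
        subject_id=rec.subject_id,
        group=rec.group,
        fs=rec.fs,
        channels=rec.channels,
        epochs=epochs,
        epoch_length_s=epoch_length_s,
    )


def preprocess_recording(
    rec: Recording,
    low_hz: float = 0.5,
    high_hz: float = 50.0,
    montage: Optional[MontageSpec] = None,
    duration_s: Optional[float] = None,
    epoch_length_s: float = 1.0,
    hook: Optional[PreprocessHook] = None,
) -> EpochedRecording:
    """Standard preprocessing chain: band-pass, optional artifact hook,
    montage harmonization, truncation, epoching."""
    rec = bandpass_filter(rec, low_hz, high_hz)
    if hook is not None:
        rec = hook(rec)
    rec = harmonize_montage(rec, montage)
    if duration_s is not None:
        rec = truncate(rec, duration_s)
    return segment(rec, epoch_length_s)
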