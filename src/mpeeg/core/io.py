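"""Readers and writers for EEG interchange formats.

Supports EDF, BioSemi BDF and EEGLAB ``.set``/``.fdt`` files, plus an
internal HDF5 container for preprocessed epoched data.  The EDF/BDF codec
is implemented directly against the published header layout (256-byte
fixed header + 256 bytes per signal, int16/int24 little-endian records);
``.set`` files are MATLAB v5 files and are read with :mod:`scipy.io`.
"""

from __future__ import annotations

import os
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
from scipy import io as sio

from .types import EpochedRecording, Group, Recording, ValidationError


class RecordingFormat(str, Enum):
    EDF = "EDF"
    BDF = "BDF"
    EEGLAB_SET = "EEGLAB_SET"


class FileFormatError(IOError):
    """File exists but cannot be parsed as the requested format."""


_EDF_HEADER = 256
_PER_SIGNAL = 256


def _ascii(field: bytes) -> str:
    return field.decode("ascii", errors="replace").strip()


def _read_edf_like(path: Union[str, Path], bdf: bool) -> Recording:
    path = Path(path)
    name = "BDF" if bdf else "EDF"
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise IOError(f"cannot read {name} file {path}: {exc}") from exc
    if len(raw) < _EDF_HEADER:
        raise FileFormatError(f"{path}: file shorter than the {name} fixed header")
    if bdf:
        if raw[0] != 0xFF or raw[1:8].strip() != b"BIOSEMI":
            raise FileFormatError(f"{path}: missing BDF magic bytes")
    else:
        if raw[0:1] == b"\xff":
            raise FileFormatError(f"{path}: looks like BDF, not EDF")
    try:
        n_records = int(_ascii(raw[236:244]))
        record_dur = float(_ascii(raw[244:252]))
        n_signals = int(_ascii(raw[252:256]))
    except ValueError as exc:
        raise FileFormatError(f"{path}: corrupt {name} header fields") from exc
    if n_signals <= 0 or n_records < 0:
        raise FileFormatError(f"{path}: implausible {name} header counts")
    sig_hdr_end = _EDF_HEADER + _PER_SIGNAL * n_signals
    if len(raw) < sig_hdr_end:
        raise FileFormatError(f"{path}: truncated {name} signal headers")

    def field(offset: int, width: int, i: int) -> bytes:
        base = _EDF_HEADER + offset * n_signals + width * i
        return raw[base : base + width]

    labels = [_ascii(field(0, 16, i)) for i in range(n_signals)]
    try:
        phys_min = np.array([float(_ascii(field(104, 8, i))) for i in range(n_signals)])
        phys_max = np.array([float(_ascii(field(112, 8, i))) for i in range(n_signals)])
        dig_min = np.array([float(_ascii(field(120, 8, i))) for i in range(n_signals)])
        dig_max = np.array([float(_ascii(field(128, 8, i))) for i in range(n_signals)])
        spr = np.array([int(_ascii(field(216, 8, i))) for i in range(n_signals)])
    except ValueError as exc:
        raise FileFormatError(f"{path}: corrupt {name} signal header fields") from exc
    if np.any(spr <= 0) or record_dur <= 0:
        raise FileFormatError(f"{path}: invalid samples-per-record or record duration")
    fs = spr / record_dur
    if not np.allclose(fs, fs[0]):
        raise FileFormatError(f"{path}: mixed sampling rates are not supported")

    bytes_per = 3 if bdf else 2
    rec_bytes = int(spr.sum()) * bytes_per
    expected = sig_hdr_end + n_records * rec_bytes
    if len(raw) < expected:
        raise FileFormatError(
            f"{path}: truncated {name} data ({len(raw)} bytes, expected {expected})"
        )
    body = raw[sig_hdr_end:expected]
    if bdf:
        u = np.frombuffer(body, dtype=np.uint8).astype(np.int32)
        u = u.reshape(-1, 3)
        digital = u[:, 0] | (u[:, 1] << 8) | (u[:, 2] << 16)
        digital = np.where(digital >= 1 << 23, digital - (1 << 24), digital)
    else:
        digital = np.frombuffer(body, dtype="<i2").astype(np.int32)

    data = np.empty((n_signals, int(spr[0]) * n_records), dtype=np.float64)
    offsets = np.concatenate([[0], np.cumsum(spr)])
    per_rec = int(spr.sum())
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    for i in range(n_signals):
        chunks = [
            digital[r * per_rec + offsets[i] : r * per_rec + offsets[i + 1]]
            for r in range(n_records)
        ]
        dig = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int32)
        data[i] = (dig - dig_min[i]) * gain[i] + phys_min[i]
    return Recording(
        subject_id=path.stem,
        group=Group.HC,
        fs=float(fs[0]),
        channels=tuple(labels),
        data=data,
    )


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _write_edf_like(
    path: Union[str, Path], rec: Recording, bdf: bool
) -> None:
    path = Path(path)
    n_signals = rec.n_channels
    n_samples = rec.n_samples
    dig_max = (1 << 23) - 1 if bdf else 32767
    dig_min = -dig_max
    # Symmetric physical range padded slightly so round-trip clipping never bites.
    span = float(np.max(np.abs(rec.data))) if n_samples else 1.0
    span = max(span, 1e-6) * 1.000001
    gain = (2 * span) / (dig_max - dig_min)

    head = bytearray()
    head += b"\xffBIOSEMI" if bdf else _pad("0", 8)
    head += _pad("synthetic", 80)
    head += _pad(f"subject={rec.subject_id} group={rec.group.value}", 80)
    head += _pad("01.01.20", 8) + _pad("00.00.00", 8)
    head += _pad(str(_EDF_HEADER + _PER_SIGNAL * n_signals), 8)
    head += _pad("24BIT" if bdf else "", 44)
    head += _pad("1", 8)  # one data record holding everything
    head += _pad(f"{n_samples / rec.fs:.6g}", 8)
    head += _pad(str(n_signals), 4)
    for width, values in (
        (16, rec.channels),
        (80, ["" for _ in rec.channels]),
        (8, ["uV" for _ in rec.channels]),
        (8, [f"{-span:.6g}" for _ in rec.channels]),
        (8, [f"{span:.6g}" for _ in rec.channels]),
        (8, [str(dig_min) for _ in rec.channels]),
        (8, [str(dig_max) for _ in rec.channels]),
        (80, ["" for _ in rec.channels]),
        (8, [str(n_samples) for _ in rec.channels]),
        (32, ["" for _ in rec.channels]),
    ):
        for v in values:
            head += _pad(str(v), width)

    digital = np.rint((rec.data + span) / gain).astype(np.int64) + dig_min
    digital = np.clip(digital, dig_min, dig_max)
    if bdf:
        flat = digital.reshape(-1).astype(np.int64)
        flat = np.where(flat < 0, flat + (1 << 24), flat).astype(np.uint32)
        body = np.empty((flat.size, 3), dtype=np.uint8)
        body[:, 0] = flat & 0xFF
        body[:, 1] = (flat >> 8) & 0xFF
        body[:, 2] = (flat >> 16) & 0xFF
        payload = body.tobytes()
    else:
        payload = digital.astype("<i2").tobytes()
    path.write_bytes(bytes(head) + payload)


def read_eeglab_set(path: Union[str, Path]) -> Recording:
    """Read an EEGLAB ``.set`` file (MATLAB v5 container).

    Continuous data may live inline or in a sibling ``.fdt`` float32 file.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read EEGLAB set file {path}: no such file")
    try:
        mat = sio.loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except Exception as exc:  # scipy raises assorted types on corruption
        raise FileFormatError(f"{path}: not a readable MATLAB/.set file ({exc})") from exc
    if "EEG" in mat:
        eeg = mat["EEG"]
    else:
        candidates = [v for k, v in mat.items() if not k.startswith("__")]
        if not candidates:
            raise FileFormatError(f"{path}: no EEG struct found")
        eeg = candidates[0]
    try:
        fs = float(np.squeeze(eeg.srate))
        nbchan = int(np.squeeze(eeg.nbchan))
        pnts = int(np.squeeze(eeg.pnts))
        raw = eeg.data
    except AttributeError as exc:
        raise FileFormatError(f"{path}: missing EEG fields ({exc})") from exc
    if isinstance(raw, str):
        fdt = path.parent / raw
        if not fdt.exists():
            fdt = path.with_suffix(".fdt")
        if not fdt.exists():
            raise IOError(f"cannot read EEGLAB data file for {path}: {raw} missing")
        data = np.fromfile(fdt, dtype="<f4")
        if data.size != nbchan * pnts:
            raise FileFormatError(f"{fdt}: size does not match nbchan x pnts")
        data = data.reshape((nbchan, pnts), order="F").astype(np.float64)
    else:
        data = np.asarray(raw, dtype=np.float64)
        if data.ndim == 3:  # already-epoched set: concatenate trials
            data = data.reshape(nbchan, -1, order="F")
    labels: list[str] = []
    chanlocs = getattr(eeg, "chanlocs", None)
    if chanlocs is not None:
        locs = np.atleast_1d(chanlocs)
        for loc in locs:
            lab = getattr(loc, "labels", "")
            labels.append(str(np.squeeze(lab)))
    if len(labels) != nbchan:
        labels = [f"Ch{i + 1}" for i in range(nbchan)]
    return Recording(
        subject_id=path.stem,
        group=Group.HC,
        fs=fs,
        channels=tuple(labels),
        data=data,
    )


def write_eeglab_set(path: Union[str, Path], rec: Recording) -> None:
    """Write a minimal EEGLAB-compatible ``.set`` file (inline data)."""
    chanlocs = np.array(
        [(lab,) for lab in rec.channels], dtype=[("labels", object)]
    )
    eeg = {
        "srate": float(rec.fs),
        "nbchan": rec.n_channels,
        "pnts": rec.n_samples,
        "trials": 1,
        "data": rec.data.astype(np.float32),
        "chanlocs": chanlocs,
        "setname": rec.subject_id,
    }
    sio.savemat(str(path), {"EEG": eeg})


def read_recording(
    path: Union[str, Path],
    fmt: Union[RecordingFormat, str, None] = None,
    subject_id: Optional[str] = None,
    group: Union[Group, str, None] = None,
) -> Recording:
    """Read a continuous recording, dispatching on ``fmt`` (or the suffix).

    No resampling or rescaling is performed; values are returned exactly as
    stored (EDF/BDF physical units).
    """
    path = Path(path)
    if fmt is None:
        fmt = {
            ".edf": RecordingFormat.EDF,
            ".bdf": RecordingFormat.BDF,
            ".set": RecordingFormat.EEGLAB_SET,
        }.get(path.suffix.lower())
        if fmt is None:
            raise ValidationError(f"cannot infer format from suffix of {path}")
    if not isinstance(fmt, RecordingFormat):
        fmt = RecordingFormat(str(fmt).upper())
    if not path.exists():
        raise IOError(f"cannot read recording {path}: no such file")
    if fmt is RecordingFormat.EDF:
        rec = _read_edf_like(path, bdf=False)
    elif fmt is RecordingFormat.BDF:
        rec = _read_edf_like(path, bdf=True)
    else:
        rec = read_eeglab_set(path)
    if subject_id is not None:
        rec = rec.copy_with(subject_id=subject_id)
    if group is not None:
        rec = rec.copy_with(group=Group(group))
    return rec


def write_recording(path: Union[str, Path], rec: Recording,
                    fmt: Union[RecordingFormat, str, None] = None) -> None:
    """Write a recording as EDF, BDF or EEGLAB set (16/24-bit quantized)."""
    path = Path(path)
    if fmt is None:
        fmt = {
            ".edf": RecordingFormat.EDF,
            ".bdf": RecordingFormat.BDF,
            ".set": RecordingFormat.EEGLAB_SET,
        }.get(path.suffix.lower())
        if fmt is None:
            raise ValidationError(f"cannot infer format from suffix of {path}")
    if not isinstance(fmt, RecordingFormat):
        fmt = RecordingFormat(str(fmt).upper())
    if fmt is RecordingFormat.EDF:
        _write_edf_like(path, rec, bdf=False)
    elif fmt is RecordingFormat.BDF:
        _write_edf_like(path, rec, bdf=True)
    else:
        write_eeglab_set(path, rec)


def save_epoched(path: Union[str, Path], ep: EpochedRecording) -> None:
    """Persist an epoched recording to the internal HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=ep.epochs)
        f.attrs["subject_id"] = ep.subject_id
        f.attrs["group"] = ep.group.value
        f.attrs["fs"] = ep.fs
        f.attrs["epoch_length_s"] = ep.epoch_length_s
        f.attrs["channels"] = list(ep.channels)


def load_epoched(path: Union[str, Path]) -> EpochedRecording:
    """Load an epoched recording written by :func:`save_epoched`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read container {path}: no such file")
    with h5py.File(path, "r") as f:
        return EpochedRecording(
            subject_id=str(f.attrs["subject_id"]),
            group=Group(str(f.attrs["group"])),
            fs=float(f.attrs["fs"]),
            channels=tuple(str(c) for c in f.attrs["channels"]),
            epochs=f["epochs"][()],
            epoch_length_s=float(f.attrs["epoch_length_s"]),
        )
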