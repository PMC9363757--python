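"""Tabular persistence for feature tensors.

One row per subject x epoch; feature columns are named
``psd_<channel>_<band>`` and ``plv_<ChA-ChB>_<band>`` (pair labels use
montage order, first channel before second).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .psd import PSDFeatures
from .plv import PLVFeatures


def psd_to_frame(feat: PSDFeatures) -> pd.DataFrame:
    n_ep, n_ch, n_b = feat.values.shape
    cols = {
        f"psd_{ch}_{band.name}": feat.values[:, ci, bi]
        for bi, band in enumerate(feat.band_defs)
        for ci, ch in enumerate(feat.channels)
    }
    df = pd.DataFrame(cols)
    df.insert(0, "epoch", range(n_ep))
    df.insert(0, "group", feat.group)
    df.insert(0, "subject_id", feat.subject_id)
    return df


def plv_to_frame(feat: PLVFeatures) -> pd.DataFrame:
    n_ep = feat.values.shape[0]
    cols = {
        f"plv_{a}-{b}_{band.name}": feat.values[:, pi, bi]
        for bi, band in enumerate(feat.band_defs)
        for pi, (a, b) in enumerate(feat.pair_index)
    }
    df = pd.DataFrame(cols)
    df.insert(0, "epoch", range(n_ep))
    df.insert(0, "group", feat.group)
    df.insert(0, "subject_id", feat.subject_id)
    return df


def write_feature_table(
    path: Union[str, Path],
    psd: Sequence[PSDFeatures] = (),
    plv: Sequence[PLVFeatures] = (),
) -> pd.DataFrame:
    """Concatenate per-subject features into one CSV table and write it."""
    frames = []
    psd_by_subject = {f.subject_id: psd_to_frame(f) for f in psd}
    plv_by_subject = {f.subject_id: plv_to_frame(f) for f in plv}
    subjects = list(dict.fromkeys(list(psd_by_subject) + list(plv_by_subject)))
    for sid in subjects:
        parts = []
        if sid in psd_by_subject:
            parts.append(psd_by_subject[sid])
        if sid in plv_by_subject:
            p = plv_by_subject[sid]
            if parts:
                p = p.drop(columns=["subject_id", "group", "epoch"])
            parts.append(p)
        frames.append(pd.concat(parts, axis=1))
    table = pd.concat(frames, axis=0, ignore_index=True)
    table.to_csv(path, index=False)
    return table


def read_feature_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)
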