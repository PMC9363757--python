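"""Group-level contrast maps: ratio of group means with Student's-t
significance masks, per channel (PSD) or channel pair (PLV)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core.types import ValidationError
from .features.bands import BandDefinition
from .features.plv import PLVFeatures, fisher_mean_plv_axis
from .features.psd import PSDFeatures

Features = Union[PSDFeatures, PLVFeatures]


@dataclass
class ContrastMap:
    """Per-unit group-mean ratio + p-value + significance mask.

    ``mode`` is "PSD" (units = channels) or "PLV" (units = channel pairs);
    ``ratio`` is mean(group A)/mean(group B), Fisher-domain means for PLV.
    """

    band: BandDefinition
    mode: str
    unit_names: tuple[str, ...]
    ratio: np.ndarray
    p_value: np.ndarray
    alpha: float = 0.05
    group_a: str = "A"
    group_b: str = "B"
    significant: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=np.float64)
        self.p_value = np.asarray(self.p_value, dtype=np.float64)
        if not (len(self.unit_names) == self.ratio.size == self.p_value.size):
            raise ValidationError("unit_names, ratio and p_value lengths differ")
        if np.any((self.p_value < 0) | (self.p_value > 1)):
            raise ValidationError("p-values must lie in [0, 1]")
        self.significant = self.p_value <= self.alpha


def _pool(feats: Sequence[Features], band: BandDefinition,
          per_subject_mean: bool) -> np.ndarray:
    """Stack one band's values into (observations, units)."""
    if not feats:
        raise ValidationError("group is empty")
    ref = feats[0]
    try:
        bi = list(ref.band_defs).index(band)
    except ValueError as exc:
        raise ValidationError(f"band {band.name} missing from features") from exc
    blocks = []
    for f in feats:
        if f.band_defs != ref.band_defs:
            raise ValidationError("all features in a group must share band definitions")
        vals = f.values[:, :, bi]
        if per_subject_mean:
            vals = vals.mean(axis=0, keepdims=True)
        blocks.append(vals)
    return np.concatenate(blocks, axis=0)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up FDR)."""
    p = np.asarray(p, dtype=np.float64)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def group_contrast(
    feat_a: Sequence[Features],
    feat_b: Sequence[Features],
    band: BandDefinition,
    alpha: float = 0.05,
    per_subject_mean: bool = False,
    fdr: bool = False,
) -> ContrastMap:
    """Two-sample pooled-variance t-test + mean ratio per unit.

    Observations are per-epoch feature values pooled across each group's
    subjects (or per-subject means when ``per_subject_mean``).  PLV group
    means are taken in the Fisher domain; the mask is ``p <= alpha``
    (BH-adjusted first when ``fdr``).
    """
    if not feat_a or not feat_b:
        raise ValidationError("both groups must be non-empty")
    is_plv = isinstance(feat_a[0], PLVFeatures)
    if isinstance(feat_b[0], PLVFeatures) != is_plv:
        raise ValidationError("groups must hold the same feature mode")
    a = _pool(feat_a, band, per_subject_mean)
    b = _pool(feat_b, band, per_subject_mean)
    if a.shape[1] != b.shape[1]:
        raise ValidationError("groups cover different unit sets")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} unit(s) with zero variance in both groups; "
            "p set to 1",
            RuntimeWarning,
        )
        p = np.where(degenerate, 1.0, p)
    if fdr:
        p = benjamini_hochberg(p)

    if is_plv:
        mean_a = fisher_mean_plv_axis(a, axis=0)
        mean_b = fisher_mean_plv_axis(b, axis=0)
        unit_names = feat_a[0].pair_names
        mode = "PLV"
    else:
        mean_a = a.mean(axis=0)
        mean_b = b.mean(axis=0)
        unit_names = feat_a[0].channels
        mode = "PSD"
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_a / mean_b
    return ContrastMap(
        band=band,
        mode=mode,
        unit_names=tuple(unit_names),
        ratio=ratio,
        p_value=p,
        alpha=alpha,
        group_a=feat_a[0].group,
        group_b=feat_b[0].group,
    )


#: Approximate 2-D head-plane coordinates for the standard 32-channel
#: montage (x = left-right, y = posterior-anterior), used only for plotting.
CHANNEL_COORDS_32 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95), "AF3": (-0.35, 0.75),
    "AF4": (0.35, 0.75), "F7": (-0.81, 0.59), "F3": (-0.45, 0.55),
    "Fz": (0.0, 0.5), "F4": (0.45, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.69, 0.3), "FC1": (-0.25, 0.27), "FC2": (0.25, 0.27),
    "FC6": (0.69, 0.3), "T7": (-1.0, 0.0), "C3": (-0.5, 0.0),
    "Cz": (0.0, 0.0), "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.69, -0.3), "CP1": (-0.25, -0.27), "CP2": (0.25, -0.27),
    "CP6": (0.69, -0.3), "P7": (-0.81, -0.59), "P3": (-0.45, -0.55),
    "Pz": (0.0, -0.5), "P4": (0.45, -0.55), "P8": (0.81, -0.59),
    "PO3": (-0.35, -0.75), "PO4": (0.35, -0.75), "O1": (-0.31, -0.95),
    "Oz": (0.0, -0.9), "O2": (0.31, -0.95),
}


def render_contrast(
    cmap: ContrastMap,
    path: Union[str, Path],
    coords: Optional[dict] = None,
) -> Path:
    """Render a contrast map: channel scatter topomap for PSD, pair matrix
    heat map for PLV.  Non-significant units are blanked (null color)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    title = f"{cmap.group_a}/{cmap.group_b} {cmap.mode} ratio, {cmap.band.name}"
    if cmap.mode == "PSD":
        coords = coords or CHANNEL_COORDS_32
        missing = [u for u in cmap.unit_names if u not in coords]
        if missing:
            plt.close(fig)
            raise ValidationError("no coordinates for channels: " + ", ".join(missing))
        xs = [coords[u][0] for u in cmap.unit_names]
        ys = [coords[u][1] for u in cmap.unit_names]
        colors = np.where(cmap.significant, cmap.ratio, np.nan)
        sc = ax.scatter(xs, ys, c=colors, s=250, cmap="coolwarm", plotnonfinite=False,
                        edgecolors="gray")
        nul = ~cmap.significant
        ax.scatter(np.asarray(xs)[nul], np.asarray(ys)[nul], facecolors="white",
                   edgecolors="gray", s=250)
        for x, y, u in zip(xs, ys, cmap.unit_names):
            ax.annotate(u, (x, y), fontsize=5, ha="center", va="center")
        fig.colorbar(sc, ax=ax)
        ax.set_aspect("equal")
        ax.axis("off")
    else:
        channels = sorted({c for name in cmap.unit_names for c in name.split("-")})
        idx = {c: i for i, c in enumerate(channels)}
        n = len(channels)
        mat = np.full((n, n), np.nan)
        for name, r, sig in zip(cmap.unit_names, cmap.ratio, cmap.significant):
            a, b = name.split("-")
            if sig:
                mat[idx[a], idx[b]] = r
                mat[idx[b], idx[a]] = r
        im = ax.imshow(mat, cmap="coolwarm")
        fig.colorbar(im, ax=ax)
        ax.set_xlabel("channel index")
        ax.set_ylabel("channel index")
    ax.set_title(title, fontsize=9)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
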