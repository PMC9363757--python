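"""Feature assembly, normalization, linear-SVM cross-validation and metrics.

Observations are subject-epochs.  The default split is stratified k-fold at
the epoch level (matching a 9:1 epoch split at k=10); a subject-level mode
is available because epoch-level splitting leaks subject identity across
folds — a caveat of the reproduced protocol, not of this implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .core.types import ValidationError
from .features.bands import BandDefinition
from .features.plv import PLVFeatures
from .features.psd import PSDFeatures

MODES = ("PSD", "PLV", "PSD_PLV")


@dataclass
class FeatureMatrix:
    """Observation x feature matrix with per-row labels and provenance."""

    rows: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    epoch_index: np.ndarray
    feature_names: tuple[str, ...]
    band: BandDefinition
    mode: str
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids)
        self.epoch_index = np.asarray(self.epoch_index, dtype=np.int64)
        n = self.rows.shape[0]
        if not (len(self.labels) == len(self.subject_ids) == len(self.epoch_index) == n):
            raise ValidationError("rows, labels and metadata must have equal length")
        if self.rows.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length must match column count")
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode}")

    @property
    def n_rows(self) -> int:
        return int(self.rows.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.rows.shape[1])


@dataclass
class NormalizationStats:
    mean: np.ndarray
    std: np.ndarray


@dataclass
class FoldMetrics:
    confusion: np.ndarray  # (n_classes, n_classes), rows = truth
    accuracy: float
    sensitivity: np.ndarray  # per class, one-vs-rest TPR
    specificity: np.ndarray  # per class, one-vs-rest TNR


@dataclass
class CVResult:
    """Aggregate cross-validation outcome (percent-scale metrics)."""

    fold_metrics: list[FoldMetrics]
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray  # (n_points, 2): FPR, TPR
    auc: float
    fold_assignments: np.ndarray
    class_names: tuple[str, ...]
    seed: int
    per_class_sensitivity: np.ndarray = field(default=None)
    per_class_specificity: np.ndarray = field(default=None)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "classes": list(self.class_names),
            "seed": self.seed,
            "per_class_sensitivity": list(np.asarray(self.per_class_sensitivity)),
            "per_class_specificity": list(np.asarray(self.per_class_specificity)),
            "fold_accuracies": [f.accuracy for f in self.fold_metrics],
            "fold_confusions": [f.confusion.tolist() for f in self.fold_metrics],
            "roc_points": self.roc_points.tolist(),
        }


def assemble_features(
    psd: Sequence[PSDFeatures],
    plv: Sequence[PLVFeatures],
    mode: str,
    band: BandDefinition,
    groups: Sequence[str],
) -> FeatureMatrix:
    """Pool per-epoch features of the requested groups into one matrix.

    Rows for mode PSD_PLV are the concatenation [PSD(32) || PLV(496)].
    Class labels follow the order of ``groups``: 0 for the first listed
    group, 1 for the second (and 2 for a third).
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode}")
    groups = [str(g) for g in groups]
    psd_by_sid = {f.subject_id: f for f in psd}
    plv_by_sid = {f.subject_id: f for f in plv}

    use_psd = mode in ("PSD", "PSD_PLV")
    use_plv = mode in ("PLV", "PSD_PLV")
    source = psd if use_psd else plv
    rows, labels, sids, epochs = [], [], [], []
    feature_names: Optional[tuple[str, ...]] = None
    for ci, group in enumerate(groups):
        members = [f for f in source if f.group == group]
        if not members:
            raise ValidationError(f"no subjects found for group {group!r}")
        for f in members:
            bi = list(f.band_defs).index(band)
            blocks, names = [], []
            if use_psd:
                pf = psd_by_sid[f.subject_id]
                blocks.append(pf.values[:, :, list(pf.band_defs).index(band)])
                names += [f"psd_{c}_{band.name}" for c in pf.channels]
            if use_plv:
                vf = plv_by_sid.get(f.subject_id)
                if vf is None:
                    raise ValidationError(f"PLV features missing for {f.subject_id}")
                blocks.append(vf.values[:, :, list(vf.band_defs).index(band)])
                names += [f"plv_{a}-{b}_{band.name}" for a, b in vf.pair_index]
            block = np.concatenate(blocks, axis=1)
            if feature_names is None:
                feature_names = tuple(names)
            elif feature_names != tuple(names):
                raise ValidationError("subjects disagree on montage/band layout")
            rows.append(block)
            labels.append(np.full(block.shape[0], ci, dtype=np.int64))
            sids.append(np.full(block.shape[0], f.subject_id, dtype=object))
            epochs.append(np.arange(block.shape[0], dtype=np.int64))
    return FeatureMatrix(
        rows=np.concatenate(rows, axis=0),
        labels=np.concatenate(labels),
        subject_ids=np.concatenate(sids),
        epoch_index=np.concatenate(epochs),
        feature_names=feature_names,
        band=band,
        mode=mode,
        class_names=tuple(groups),
    )


def split_train_test(
    fm: FeatureMatrix, test_fraction: float = 0.1, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified epoch-level train/test split (paper-style 9:1 default).

    Returns (train_indices, test_indices); test size is
    ``round(test_fraction * n_rows)`` apportioned per class.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in np.unique(fm.labels):
        members = np.flatnonzero(fm.labels == cls)
        n_test = int(round(test_fraction * len(members)))
        test_idx.append(rng.permutation(members)[:n_test])
    test_idx = np.sort(np.concatenate(test_idx))
    mask = np.ones(fm.n_rows, dtype=bool)
    mask[test_idx] = False
    return np.flatnonzero(mask), test_idx


def fit_normalization(rows: np.ndarray) -> NormalizationStats:
    """Per-feature z-score statistics from training rows only."""
    rows = np.asarray(rows, dtype=np.float64)
    if rows.shape[0] < 2:
        raise ValidationError("need at least 2 rows to fit normalization")
    mean = rows.mean(axis=0)
    std = rows.std(axis=0, ddof=0)
    if np.any(std == 0):
        warnings.warn("zero-variance feature(s) scaled to 0", RuntimeWarning)
    return NormalizationStats(mean=mean, std=std)


def apply_normalization(rows: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    safe = np.where(stats.std == 0, 1.0, stats.std)
    out = (rows - stats.mean) / safe
    return np.where(stats.std == 0, 0.0, out)


def normalize(fm: FeatureMatrix,
              stats: Optional[NormalizationStats] = None
              ) -> tuple[FeatureMatrix, NormalizationStats]:
    """Z-score the matrix; fits stats when not given (training use)."""
    if stats is None:
        stats = fit_normalization(fm.rows)
    out = FeatureMatrix(
        rows=apply_normalization(fm.rows, stats),
        labels=fm.labels,
        subject_ids=fm.subject_ids,
        epoch_index=fm.epoch_index,
        feature_names=fm.feature_names,
        band=fm.band,
        mode=fm.mode,
        class_names=fm.class_names,
    )
    return out, stats


def compute_fold_metrics(confusion: np.ndarray) -> FoldMetrics:
    """Accuracy plus one-vs-rest sensitivity/specificity from a confusion
    matrix (rows = truth, cols = prediction), as percentages."""
    confusion = np.asarray(confusion, dtype=np.float64)
    if np.any(confusion < 0):
        raise ValidationError("confusion counts must be non-negative")
    total = confusion.sum()
    if total == 0:
        raise ValidationError("empty fold: no test observations")
    k = confusion.shape[0]
    acc = 100.0 * np.trace(confusion) / total
    sens = np.empty(k)
    spec = np.empty(k)
    for c in range(k):
        tp = confusion[c, c]
        fn = confusion[c].sum() - tp
        fp = confusion[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = 100.0 * tp / (tp + fn) if tp + fn > 0 else np.nan
        spec[c] = 100.0 * tn / (tn + fp) if tn + fp > 0 else np.nan
    return FoldMetrics(confusion=confusion, accuracy=acc, sensitivity=sens,
                       specificity=spec)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC by threshold sweep over unique scores; AUC by trapezoid rule.

    Tie handling makes the AUC equal the normalized Mann-Whitney U
    statistic.  Class 1 is positive.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = pos[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep the last index of every tied score block
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _aggregate(fold_metrics: list[FoldMetrics], fold_assignments: np.ndarray,
               scores: np.ndarray, labels: np.ndarray,
               class_names: tuple[str, ...], seed: int) -> CVResult:
    n_classes = len(class_names)
    acc = float(np.mean([f.accuracy for f in fold_metrics]))
    sens_pc = np.nanmean([f.sensitivity for f in fold_metrics], axis=0)
    spec_pc = np.nanmean([f.specificity for f in fold_metrics], axis=0)
    if n_classes == 2:
        # disease-type class (label 1) is positive
        sens, spec = float(sens_pc[1]), float(spec_pc[1])
        points, auc = roc_auc(scores[:, 1] if scores.ndim == 2 else scores,
                              labels)
    else:
        sens, spec = float(np.nanmean(sens_pc)), float(np.nanmean(spec_pc))
        aucs, points = [], np.empty((0, 2))
        for c in range(n_classes):
            _, a = roc_auc(scores[:, c], (labels == c).astype(int))
            aucs.append(a)
        auc = float(np.mean(aucs))  # macro one-vs-rest
    return CVResult(
        fold_metrics=fold_metrics,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        roc_points=points,
        auc=auc,
        fold_assignments=fold_assignments,
        class_names=class_names,
        seed=seed,
        per_class_sensitivity=sens_pc,
        per_class_specificity=spec_pc,
    )


def _make_folds(fm: FeatureMatrix, k: int, seed: int, subject_level: bool):
    if subject_level:
        splitter = GroupKFold(n_splits=k)
        return list(splitter.split(fm.rows, fm.labels, groups=fm.subject_ids))
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(fm.rows, fm.labels))
        ok = all(
            len(np.unique(fm.labels[tr])) == len(np.unique(fm.labels))
            for tr, _ in folds
        )
        if ok:
            return folds
    raise ValidationError("could not stratify folds with all classes present")


def crossval(
    fm: FeatureMatrix,
    k: int,
    seed: int,
    fit_predict,
    subject_level: bool = False,
) -> CVResult:
    """Generic k-fold CV driver with per-fold normalization refit.

    ``fit_predict(train_rows, train_labels, test_rows, fold_seed)`` must
    return ``(predictions, scores)`` where scores has one column per class
    (or is 1-D for binary decision values).
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    classes, counts = np.unique(fm.labels, return_counts=True)
    if np.any(counts < k):
        raise ValidationError("every class needs at least k rows")
    n_classes = len(classes)
    folds = _make_folds(fm, k, seed, subject_level)
    fold_assignments = np.full(fm.n_rows, -1, dtype=np.int64)
    all_scores = np.zeros((fm.n_rows, n_classes), dtype=np.float64)
    fold_metrics = []
    for fi, (train_idx, test_idx) in enumerate(folds):
        stats = fit_normalization(fm.rows[train_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            x_train = apply_normalization(fm.rows[train_idx], stats)
            x_test = apply_normalization(fm.rows[test_idx], stats)
        preds, scores = fit_predict(x_train, fm.labels[train_idx], x_test,
                                    seed + 1000 * fi)
        scores = np.asarray(scores, dtype=np.float64)
        if scores.ndim == 1:  # binary decision values -> class-1 column
            scores = np.column_stack([-scores, scores])
        fold_assignments[test_idx] = fi
        all_scores[test_idx] = scores
        conf = np.zeros((n_classes, n_classes))
        for t, p in zip(fm.labels[test_idx], preds):
            conf[int(t), int(p)] += 1
        fold_metrics.append(compute_fold_metrics(conf))
    return _aggregate(fold_metrics, fold_assignments, all_scores, fm.labels,
                      fm.class_names, seed)


def svm_crossval(
    fm: FeatureMatrix,
    k: int = 10,
    seed: int = 0,
    c: float = 1.0,
    subject_level: bool = False,
) -> CVResult:
    """Stratified k-fold CV of a linear-kernel SVM (C=1 by default)."""

    def fit_predict(x_train, y_train, x_test, fold_seed):
        clf = SVC(kernel="linear", C=c, random_state=fold_seed)
        clf.fit(x_train, y_train)
        preds = clf.predict(x_test)
        scores = clf.decision_function(x_test)
        return preds, scores

    return crossval(fm, k, seed, fit_predict, subject_level=subject_level)
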