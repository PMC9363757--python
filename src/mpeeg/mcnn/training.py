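"""SGD training loop with inverse-time learning-rate decay, plus k-fold
cross-validation of the CNN models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..classify import CVResult, FeatureMatrix, crossval
from ..core.types import ValidationError
from .models import ClassifierNet, MCNNConfig, build_mcnn, rows_to_tensor


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _evaluate(model: ClassifierNet, x: np.ndarray, y: np.ndarray,
              batch_size: int = 256) -> tuple[float, float]:
    losses, correct = [], 0
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        yb = y[start : start + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = model.loss_and_grad(logits, yb)
        losses.append(loss * len(yb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(y)), float(correct / len(y))


def train_model(
    model: ClassifierNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: MCNNConfig,
    checkpoint_best: bool = True,
) -> TrainingHistory:
    """SGD with per-epoch schedule ``lr_t = lr0 / (1 + decay * t)``.

    In ``weight_decay`` mode the learning rate stays constant and
    ``cfg.decay`` is applied as L2 shrinkage.  With ``checkpoint_best`` the
    parameters from the best-validation-accuracy epoch are restored at the
    end.  ``max_epochs == 0`` returns the untrained model with an empty
    history.
    """
    if x_train.shape[0] != y_train.shape[0]:
        raise ValidationError("training data and labels disagree in length")
    if np.any(y_train >= model.n_classes) or np.any(y_train < 0):
        raise ValidationError("labels must lie in [0, n_classes)")
    history = TrainingHistory()
    if cfg.max_epochs == 0:
        return history
    rng = np.random.default_rng(cfg.seed + 17)
    params = model.params()
    best_acc, best_state = -1.0, None
    n = x_train.shape[0]
    for epoch in range(cfg.max_epochs):
        if cfg.decay_mode == "inverse_time":
            lr = cfg.learning_rate / (1.0 + cfg.decay * epoch)
            wd = 0.0
        else:
            lr = cfg.learning_rate
            wd = cfg.decay
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = model.loss_and_grad(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss {loss}"
                )
            model.backward(dlogits)
            for p in params:
                if wd:
                    p.grad += wd * p.value
                p.value -= lr * p.grad
            ep_loss += loss * len(yb)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        history.train_loss.append(ep_loss / n)
        history.train_accuracy.append(ep_correct / n)
        val_loss, val_acc = _evaluate(model, x_val, y_val)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        if checkpoint_best and val_acc > best_acc:
            best_acc = val_acc
            best_state = model.get_state()
    if checkpoint_best and best_state is not None:
        model.set_state(best_state)
    return history


def train_mcnn(
    model: ClassifierNet,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    cfg: MCNNConfig,
) -> tuple[ClassifierNet, TrainingHistory]:
    """Convenience wrapper taking (inputs, labels) tuples."""
    history = train_model(model, train[0], train[1], val[0], val[1], cfg)
    return model, history


def crossval_mcnn(
    fm: FeatureMatrix,
    k: int = 10,
    cfg: MCNNConfig | None = None,
    model_factory=None,
    subject_level: bool = False,
    val_fraction: float = 0.1,
) -> CVResult:
    """Stratified k-fold CV with per-fold model re-initialization.

    Rows must be PSD+PLV vectors reshapeable to the square input; fold
    bookkeeping and normalization refit are shared with the SVM path.  A
    ``val_fraction`` slice of each training fold drives best-epoch
    checkpointing.  ROC scores are predicted class probabilities.
    """
    cfg = cfg or MCNNConfig()
    n_channels = cfg.input_side
    if model_factory is None:
        model_factory = build_mcnn

    def fit_predict(x_train, y_train, x_test, fold_seed):
        fold_cfg = MCNNConfig(**{**cfg.__dict__, "seed": fold_seed,
                                 "n_classes": cfg.n_classes})
        try:
            model = model_factory(fold_cfg)
        except TypeError:  # factories like build_lenet5 take (n_classes, seed)
            model = model_factory(fold_cfg.n_classes, seed=fold_seed)
        xt = rows_to_tensor(x_train, n_channels)
        xs = rows_to_tensor(x_test, n_channels)
        rng = np.random.default_rng(fold_seed + 1)
        n_val = max(1, int(round(val_fraction * len(y_train))))
        perm = rng.permutation(len(y_train))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        train_model(model, xt[tr_idx], y_train[tr_idx], xt[val_idx],
                    y_train[val_idx], fold_cfg)
        proba = model.predict_proba(xs)
        return proba.argmax(axis=1), proba

    return crossval(fm, k, cfg.seed, fit_predict, subject_level=subject_level)
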