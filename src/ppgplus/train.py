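"""Classifier training under k-fold cross-validation.

The trainable model is exposed as a scikit-learn-style estimator
(:class:`CNNClassifier`): ``fit`` / ``predict`` / ``predict_proba`` with
``get_params``/``set_params``, fitted attributes with a trailing underscore,
softmax cross-entropy loss and the Adam optimizer. ``train_cv`` wraps it with
the binary-trial definitions (NT vs HT, NT vs PHT, (NT+PHT) vs HT) and reports
per-fold and fold-averaged F1 / sensitivity / specificity / ROC.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .labeling import BPClass
from .metrics import EvalMetrics, compute_metrics
from .models import ModelSpec, adapt_backbone
from .nn import Adam, Dropout, Residual, Sequential

__all__ = [
    "TrainConfig",
    "TrialSpec",
    "TRIALS",
    "CVResult",
    "CNNClassifier",
    "train_cv",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings. Defaults follow the reference protocol: Adam at
    learning rate 0.001, 25 epochs per fold, 5 folds."""

    learning_rate: float = 0.001
    epochs: int = 25
    k_folds: int = 5
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass(frozen=True)
class TrialSpec:
    """A binary trial: which classes are pooled as positive and negative.

    NT reads as the positive class where it appears alone (the sensitivity
    narrative counts correctly predicted normotensive samples); for
    (NT+PHT) vs HT the pooled non-hypertensive group is positive.
    """

    name: str
    positive: frozenset[BPClass]
    negative: frozenset[BPClass]

    def covers(self, cls: BPClass) -> bool:
        return cls in self.positive or cls in self.negative

    def to_binary(self, cls: BPClass) -> int:
        if cls in self.positive:
            return 1
        if cls in self.negative:
            return 0
        raise ValueError(f"class {cls} not part of trial {self.name}")


TRIALS: dict[str, TrialSpec] = {
    "nt-vs-ht": TrialSpec("nt-vs-ht", frozenset({BPClass.NT}), frozenset({BPClass.HT})),
    "nt-vs-pht": TrialSpec("nt-vs-pht", frozenset({BPClass.NT}), frozenset({BPClass.PHT})),
    "ntpht-vs-ht": TrialSpec(
        "ntpht-vs-ht", frozenset({BPClass.NT, BPClass.PHT}), frozenset({BPClass.HT})
    ),
}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _reseed_dropout(model: Sequential, seed_seq: np.random.SeedSequence) -> None:
    stack = [model]
    while stack:
        layer = stack.pop()
        if isinstance(layer, Dropout):
            layer.rng = np.random.default_rng(seed_seq.spawn(1)[0])
        elif isinstance(layer, Sequential):
            stack.extend(layer.layers)
        elif isinstance(layer, Residual):
            stack.append(layer.main)
            if layer.shortcut:
                stack.append(layer.shortcut)


class CNNClassifier(BaseEstimator, ClassifierMixin):
    """CNN classifier over 3 x 224 x 224 network inputs, scikit-learn style.

    Parameters mirror the training protocol; the default backbone is the
    CPU-sized ``small_cnn``. ``X`` may be (n, 3, 224, 224) or flattened
    (n, 3*224*224). Training is fully seeded (weight init, batch shuffling,
    dropout masks) and single-threaded.

    Attributes (after ``fit``): ``classes_``, ``model_``, ``history_`` —
    per-epoch training accuracy (and validation accuracy when an eval set is
    supplied).
    """

    def __init__(
        self,
        backbone: str = "small_cnn",
        dropout_p: float = 0.6,
        learning_rate: float = 0.001,
        epochs: int = 25,
        batch_size: int = 16,
        seed: int = 0,
        pretrained: bool = False,
    ):
        self.backbone = backbone
        self.dropout_p = dropout_p
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.pretrained = pretrained

    def _as_tensor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X.reshape(X.shape[0], 3, 224, 224)
        if X.ndim != 4:
            raise ValueError("X must be (n, 3, 224, 224) or (n, 3*224*224)")
        return X

    def fit(self, X, y, eval_set: tuple[np.ndarray, np.ndarray] | None = None):
        X = self._as_tensor(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("binary trials require exactly 2 classes in y")
        ss = np.random.SeedSequence(self.seed)
        init_seed, shuffle_ss, drop_ss = ss.spawn(3)
        spec = ModelSpec(
            backbone=self.backbone, dropout_p=self.dropout_p,
            n_outputs=2, pretrained=self.pretrained,
        )
        self.model_ = adapt_backbone(spec, seed=int(init_seed.generate_state(1)[0] % 2**31))
        _reseed_dropout(self.model_, drop_ss)
        opt = Adam(self.model_.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng(shuffle_ss)
        n = X.shape[0]
        self.history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            correct = 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y_idx[idx]
                logits = self.model_.forward(xb, train=True)
                prob = _softmax(logits)
                correct += int(np.sum(prob.argmax(axis=1) == yb))
                grad = prob.copy()
                grad[np.arange(yb.size), yb] -= 1.0
                self.model_.backward((grad / yb.size).astype(np.float32))
                opt.step()
            entry = {"epoch": epoch, "train_acc": correct / n}
            if eval_set is not None:
                entry["eval_acc"] = float(
                    np.mean(self.predict(eval_set[0]) == np.asarray(eval_set[1]))
                )
            self.history_.append(entry)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._as_tensor(X)
        out = []
        for start in range(0, X.shape[0], 64):
            out.append(_softmax(self.model_.forward(X[start : start + 64], train=False)))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


@dataclass(frozen=True)
class CVResult:
    """Per-fold metrics, their fold averages, and per-epoch accuracy histories."""

    per_fold: list[EvalMetrics]
    histories: list[list[dict]]

    @property
    def mean(self) -> dict[str, float]:
        keys = ("f1", "tpr", "tnr", "auc")
        return {k: float(np.mean([getattr(m, k) for m in self.per_fold])) for k in keys}


def train_cv(
    X: np.ndarray,
    labels: list[BPClass] | np.ndarray,
    folds: np.ndarray,
    trial: TrialSpec,
    model_spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
) -> CVResult:
    """k-fold cross-validated training of one binary trial.

    ``folds`` assigns each row a fold id (rows with fold < 0 — e.g. the
    held-out test split — are ignored). Rows whose class the trial does not
    cover are dropped. For each fold, the model trains on the other folds and
    is evaluated on the held-out one; per-fold metrics and their mean are
    returned. Fully seeded and deterministic.
    """
    model_spec = model_spec or ModelSpec()
    cfg = cfg or TrainConfig()
    labels = np.asarray([BPClass(l) for l in np.asarray(labels)], dtype=object)
    folds = np.asarray(folds)
    keep = np.array([trial.covers(l) for l in labels]) & (folds >= 0)
    X, labels, folds = X[keep], labels[keep], folds[keep]
    y = np.array([trial.to_binary(l) for l in labels])
    fold_ids = sorted(int(f) for f in np.unique(folds))
    if len(fold_ids) < 2:
        raise ValueError("need at least 2 folds with trial data")
    per_fold: list[EvalMetrics] = []
    histories: list[list[dict]] = []
    for f in fold_ids:
        tr, ev = folds != f, folds == f
        if not ev.any() or not tr.any():
            raise ValueError(f"fold {f} is empty")
        clf = CNNClassifier(
            backbone=model_spec.backbone, dropout_p=model_spec.dropout_p,
            learning_rate=cfg.learning_rate, epochs=cfg.epochs,
            batch_size=cfg.batch_size, seed=cfg.seed,  # fold-id independent, so
            # fold-averaged metrics are invariant to fold relabeling
            pretrained=model_spec.pretrained,
        )
        clf.fit(X[tr], y[tr], eval_set=(X[ev], y[ev]))
        pos_col = int(np.where(clf.classes_ == 1)[0][0])
        scores = clf.predict_proba(X[ev])[:, pos_col]
        per_fold.append(compute_metrics(scores, y[ev]))
        histories.append(clf.history_)
    return CVResult(per_fold=per_fold, histories=histories)
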