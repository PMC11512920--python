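"""Two-stage CNN-LSTM classification of CFS image sequences.

Each 32 x 32 x 3 frame passes through a convolutional feature extractor (two
convolution / batch-norm / ReLU blocks, then flattening); the per-frame
feature vectors feed a two-layer stacked LSTM (hidden size 20) whose output
sequence, after dropout, is flattened into two fully-connected layers ending
in two class logits.  Training minimises (optionally class-weighted)
cross-entropy with Adam and early stopping on a training-loss plateau.

Evaluation follows subject-level stratified k-fold cross-validation: the
cross-validation unit is the subject's whole sequence, so no frames of a test
subject ever appear in training.  Fold metrics are sensitivity, specificity,
their mean (balanced accuracy -- robust to the class imbalance typical of
clinical cohorts) and ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import nn

__all__ = [
    "CNNConfig", "LSTMConfig", "TrainConfig", "FoldMetrics", "CVResults",
    "SequenceNet", "CFSSequenceClassifier", "evaluate", "cross_validate",
]

#: Class encoding used throughout: the clinical class is the positive one.
CLASS_NAMES = ("control", "dyslexic")


@dataclass(frozen=True)
class CNNConfig:
    """Convolutional feature extractor: two conv/batch-norm/ReLU blocks.

    Defaults: 8 and 16 filters, 3 x 3 kernels, stride 1 then 2 (the second
    stride bounds the flattened feature size), batch normalisation on.
    """

    filters: tuple[int, int] = (8, 16)
    kernel: int = 3
    strides: tuple[int, int] = (1, 2)
    batch_norm: bool = True

    def feature_size(self, height: int = 32, width: int = 32) -> int:
        h, w = height, width
        for s in self.strides:
            h = (h + 2 * ((self.kernel - 1) // 2) - self.kernel) // s + 1
            w = (w + 2 * ((self.kernel - 1) // 2) - self.kernel) // s + 1
        return h * w * self.filters[-1]


@dataclass(frozen=True)
class LSTMConfig:
    """Recurrent stage: stacked LSTM, dropout, two fully-connected layers."""

    layers: int = 2
    hidden: int = 20
    dropout: float = 0.5
    fc_hidden: int = 20
    n_classes: int = 2


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe (the architecture does not prescribe one).

    Adam at ``lr``; full-batch epochs; early stopping once the smoothed
    training loss improves by less than ``tol`` for ``patience`` epochs.
    ``class_weight='balanced'`` reweights the loss inversely to class counts.
    """

    lr: float = 1e-3
    epochs: int = 200
    patience: int = 20
    tol: float = 1e-4
    class_weight: str | None = "balanced"


class SequenceNet:
    """The assembled two-stage network with manual forward/backward."""

    def __init__(self, n_frames: int, cnn: CNNConfig, lstm: LSTMConfig,
                 rng: np.random.Generator, frame_shape=(32, 32, 3)):
        h, w, c = frame_shape
        self.frame_shape = frame_shape
        self.n_frames = n_frames
        self.cnn_cfg, self.lstm_cfg = cnn, lstm
        f1, f2 = cnn.filters
        self.conv1 = nn.Conv2d(c, f1, cnn.kernel, cnn.strides[0], rng)
        self.conv2 = nn.Conv2d(f1, f2, cnn.kernel, cnn.strides[1], rng)
        self.bn1 = nn.BatchNorm2d(f1) if cnn.batch_norm else None
        self.bn2 = nn.BatchNorm2d(f2) if cnn.batch_norm else None
        self.relu1, self.relu2 = nn.ReLU(), nn.ReLU()
        self.feature_size = cnn.feature_size(h, w)
        self.lstms = []
        size = self.feature_size
        for _ in range(lstm.layers):
            self.lstms.append(nn.LSTM(size, lstm.hidden, rng))
            size = lstm.hidden
        self.dropout = nn.Dropout(lstm.dropout)
        self.fc1 = nn.Linear(n_frames * lstm.hidden, lstm.fc_hidden, rng)
        self.fc_relu = nn.ReLU()
        self.fc2 = nn.Linear(lstm.fc_hidden, lstm.n_classes, rng)

    # -- forward -----------------------------------------------------------
    def cnn_forward(self, frames: np.ndarray, train: bool) -> np.ndarray:
        """(M, H, W, C) frames -> (M, feature_size) flattened activations."""
        x = np.ascontiguousarray(frames.transpose(0, 3, 1, 2))
        x = self.conv1.forward(x)
        if self.bn1 is not None:
            x = self.bn1.forward(x, train)
        x = self.relu1.forward(x)
        x = self.conv2.forward(x)
        if self.bn2 is not None:
            x = self.bn2.forward(x, train)
        x = self.relu2.forward(x)
        self._cnn_out_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def head_forward(self, feats: np.ndarray, train: bool,
                     rng: np.random.Generator | None = None) -> np.ndarray:
        """(B, T, feature_size) -> (B, n_classes) logits."""
        h = feats
        for layer in self.lstms:
            h = layer.forward(h)
        h = self.dropout.forward(h, train, rng)
        B = h.shape[0]
        z = self.fc1.forward(h.reshape(B, -1))
        z = self.fc_relu.forward(z)
        self._head_in_shape = h.shape
        return self.fc2.forward(z)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """(B, T, H, W, C) sequences -> (B, n_classes) logits."""
        B, T = x.shape[:2]
        if T != self.n_frames:
            raise ValueError(f"model built for {self.n_frames}-frame sequences, "
                             f"got {T}")
        feats = self.cnn_forward(x.reshape((B * T,) + x.shape[2:]), train)
        return self.head_forward(feats.reshape(B, T, -1), train, rng)

    def head_logits_variants(self, base_feats: np.ndarray, frame_idx: int,
                             variants: np.ndarray) -> np.ndarray:
        """Logits for sequences equal to ``base_feats`` except at one frame.

        ``base_feats`` is the (T, F) feature sequence of the unperturbed
        subject; ``variants`` is an (N, F) batch of replacement features for
        frame ``frame_idx``.  The recurrent state up to that frame is shared
        by every variant, so it is computed once on the base sequence and the
        recurrence is only run over the suffix -- results are identical to
        evaluating each full sequence.
        """
        T, F = base_feats.shape
        N = variants.shape[0]
        # base pass caching per-layer entry states and base hidden outputs
        prefix_states = []  # per layer: (h, c) at entry of frame_idx
        base_out = base_feats[None]  # (1, t, features)
        base_hidden = None
        for layer in self.lstms:
            h = np.zeros((1, layer.hidden_size))
            c = np.zeros((1, layer.hidden_size))
            outs = np.empty((1, T, layer.hidden_size))
            for t in range(T):
                if t == frame_idx:
                    prefix_states.append((h, c))
                h, c = layer.step(base_out[:, t], h, c)
                outs[:, t] = h
            base_out = outs
            base_hidden = outs
        # suffix pass over the variant batch
        states = [(np.repeat(h, N, axis=0), np.repeat(c, N, axis=0))
                  for h, c in prefix_states]
        top = np.repeat(base_hidden, N, axis=0)  # (N, T, H)
        for t in range(frame_idx, T):
            x = variants if t == frame_idx else np.broadcast_to(
                base_feats[t], (N, F))
            for li, layer in enumerate(self.lstms):
                h, c = layer.step(x, *states[li])
                states[li] = (h, c)
                x = h
            top[:, t] = x
        z = self.fc1.forward(top.reshape(N, -1))
        z = self.fc_relu.forward(z)
        return self.fc2.forward(z)

    # -- backward ----------------------------------------------------------
    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.fc2.backward(dlogits)
        dz = self.fc_relu.backward(dz)
        dh = self.fc1.backward(dz).reshape(self._head_in_shape)
        dh = self.dropout.backward(dh)
        for layer in reversed(self.lstms):
            dh = layer.backward(dh)
        B, T, F = dh.shape
        dx = dh.reshape(B * T, F).reshape(self._cnn_out_shape)
        dx = self.relu2.backward(dx)
        if self.bn2 is not None:
            dx = self.bn2.backward(dx)
        dx = self.conv2.backward(dx)
        dx = self.relu1.backward(dx)
        if self.bn1 is not None:
            dx = self.bn1.backward(dx)
        self.conv1.backward(dx)

    def parameters(self) -> list[nn.Parameter]:
        params = self.conv1.parameters() + self.conv2.parameters()
        for bn in (self.bn1, self.bn2):
            if bn is not None:
                params += bn.parameters()
        for layer in self.lstms:
            params += layer.parameters()
        return params + self.fc1.parameters() + self.fc2.parameters()

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))


class CFSSequenceClassifier:
    """Scikit-learn-style estimator over CFS image sequences.

    ``fit(X, y)`` expects ``X`` of shape (subjects, frames, 32, 32, 3) and
    integer labels (0 = control, 1 = dyslexic).  Deterministic for a fixed
    ``seed``: weight initialisation, dropout and the optimisation path are
    all driven by one generator.
    """

    def __init__(self, cnn: CNNConfig | None = None,
                 lstm: LSTMConfig | None = None,
                 train: TrainConfig | None = None, seed: int = 0):
        self.cnn = cnn or CNNConfig()
        self.lstm = lstm or LSTMConfig()
        self.train_cfg = train or TrainConfig()
        self.seed = seed
        self.net: SequenceNet | None = None
        self.loss_trace_: list[float] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CFSSequenceClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(self.seed)
        self.net = SequenceNet(X.shape[1], self.cnn, self.lstm, rng,
                               frame_shape=X.shape[2:])
        cfg = self.train_cfg
        weights = None
        if cfg.class_weight == "balanced":
            counts = np.bincount(y, minlength=self.lstm.n_classes)
            weights = np.where(counts > 0, y.size / np.maximum(counts, 1)
                               / self.lstm.n_classes, 0.0)
        opt = nn.Adam(self.net.parameters(), lr=cfg.lr)
        self.loss_trace_ = []
        best, stale = np.inf, 0
        for _ in range(cfg.epochs):
            logits = self.net.forward(X, train=True, rng=rng)
            loss, dlogits = nn.cross_entropy(logits, y, weights)
            opt.zero_grad()
            self.net.backward(dlogits)
            opt.step()
            self.loss_trace_.append(loss)
            smoothed = float(np.mean(self.loss_trace_[-5:]))
            if smoothed < best - cfg.tol:
                best, stale = smoothed, 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        return self

    def _require_fitted(self) -> SequenceNet:
        if self.net is None:
            raise RuntimeError("classifier is not fitted")
        return self.net

    def decision_logits(self, X: np.ndarray) -> np.ndarray:
        return self._require_fitted().forward(np.asarray(X, np.float64),
                                              train=False)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return nn.softmax(self.decision_logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.decision_logits(X), axis=1)

    # hooks used by the explanation module to avoid recomputing unchanged
    # frames: features of individual frames, and the recurrent head alone
    def frame_features(self, frames: np.ndarray) -> np.ndarray:
        return self._require_fitted().cnn_forward(
            np.asarray(frames, np.float64), train=False)

    def head_proba(self, feats: np.ndarray) -> np.ndarray:
        return nn.softmax(self._require_fitted().head_forward(feats, False))

    def head_logits_variants(self, base_feats: np.ndarray, frame_idx: int,
                             variants: np.ndarray) -> np.ndarray:
        return self._require_fitted().head_logits_variants(
            base_feats, frame_idx, variants)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint configuration, weights and batch-norm statistics."""
        import dataclasses
        import json

        net = self._require_fitted()
        arrays = {f"param_{i}": p.value
                  for i, p in enumerate(net.parameters())}
        for name, bn in (("bn1", net.bn1), ("bn2", net.bn2)):
            if bn is not None:
                arrays[f"{name}_mean"] = bn.running_mean
                arrays[f"{name}_var"] = bn.running_var
        meta = json.dumps({
            "cnn": dataclasses.asdict(self.cnn),
            "lstm": dataclasses.asdict(self.lstm),
            "train": dataclasses.asdict(self.train_cfg),
            "seed": self.seed,
            "n_frames": net.n_frames,
            "frame_shape": list(net.frame_shape),
            "loss_trace": self.loss_trace_,
        })
        np.savez_compressed(path, meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path) -> "CFSSequenceClassifier":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            cnn = CNNConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in meta["cnn"].items()})
            lstm = LSTMConfig(**meta["lstm"])
            train = TrainConfig(**meta["train"])
            clf = cls(cnn=cnn, lstm=lstm, train=train, seed=meta["seed"])
            clf.net = SequenceNet(meta["n_frames"], cnn, lstm,
                                  np.random.default_rng(0),
                                  frame_shape=tuple(meta["frame_shape"]))
            for i, p in enumerate(clf.net.parameters()):
                p.value[...] = z[f"param_{i}"]
            for name, bn in (("bn1", clf.net.bn1), ("bn2", clf.net.bn2)):
                if bn is not None:
                    bn.running_mean[...] = z[f"{name}_mean"]
                    bn.running_var[...] = z[f"{name}_var"]
            clf.loss_trace_ = list(meta["loss_trace"])
        return clf


@dataclass(frozen=True)
class FoldMetrics:
    """Confusion counts and derived scores for one evaluation fold.

    Sensitivity ``TP / (TP + FN)`` and specificity ``TN / (TN + FP)`` follow
    the standard definitions; balanced accuracy is their mean; AUC is the
    probability that a random positive outranks a random negative.
    """

    n_tp: int
    n_tn: int
    n_fp: int
    n_fn: int
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float

    @property
    def n(self) -> int:
        return self.n_tp + self.n_tn + self.n_fp + self.n_fn


def evaluate(scores: np.ndarray, labels: np.ndarray) -> FoldMetrics:
    """Fold metrics from per-subject class scores.

    ``scores`` may be (n, 2) logits/probabilities (argmax decision) or a 1-D
    positive-class score with threshold 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim == 2:
        pred = np.argmax(scores, axis=1)
        pos = nn.softmax(scores)[:, 1] if not np.allclose(
            scores.sum(axis=1), 1.0) else scores[:, 1]
    else:
        pred = (scores >= 0.5).astype(int)
        pos = scores
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: evaluation set has a single class")
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return FoldMetrics(
        n_tp=tp, n_tn=tn, n_fp=fp, n_fn=fn,
        sensitivity=sens, specificity=spec,
        balanced_accuracy=0.5 * (sens + spec),
        auc=float(roc_auc_score(labels, pos)),
    )


@dataclass
class CVResults:
    """Per-fold metrics with mean +/- sd summaries and the fitted fold models."""

    folds: list[FoldMetrics]
    models: list[CFSSequenceClassifier]
    test_indices: list[np.ndarray]
    predictions: np.ndarray  # out-of-fold predicted label per subject
    scores: np.ndarray  # out-of-fold positive-class probability
    labels: np.ndarray
    seed: int

    _METRICS = ("balanced_accuracy", "sensitivity", "specificity", "auc")

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f, metric) for f in self.folds]))

    def sd(self, metric: str) -> float:
        return float(np.std([getattr(f, metric) for f in self.folds]))

    @property
    def correct(self) -> np.ndarray:
        """Boolean mask of subjects correctly classified out of fold."""
        return self.predictions == self.labels

    def to_frame(self):
        import pandas as pd

        rows = [{m: getattr(f, m) for m in self._METRICS} |
                {"fold": i + 1, "n": f.n}
                for i, f in enumerate(self.folds)]
        return pd.DataFrame(rows).set_index("fold")

    def summary(self) -> str:
        lines = [f"{len(self.folds)}-fold stratified cross-validation "
                 f"(n={self.labels.size}, seed={self.seed})"]
        for m in self._METRICS:
            lines.append(f"  {m:>18s}: {self.mean(m):.3f} +/- {self.sd(m):.3f}")
        return "\n".join(lines)


def cross_validate(X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0,
                   cnn: CNNConfig | None = None, lstm: LSTMConfig | None = None,
                   train: TrainConfig | None = None) -> CVResults:
    """Subject-stratified k-fold cross-validation of the sequence classifier.

    Folds are deterministic for a fixed seed; each fold's model is freshly
    initialised from a fold-specific seed.  ``k`` equal to the cohort size
    gives leave-one-out behaviour (AUC is then computed on pooled scores
    only).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 1:
        raise ValueError("both classes must be present")
    if k > counts[counts > 0].min():
        raise ValueError(f"k={k} exceeds the smaller class count "
                         f"({counts[counts > 0].min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds, models, test_indices = [], [], []
    oof_pred = np.full(y.size, -1)
    oof_score = np.full(y.size, np.nan)
    for fold_idx, (tr, te) in enumerate(skf.split(np.zeros(y.size), y)):
        clf = CFSSequenceClassifier(cnn=cnn, lstm=lstm, train=train,
                                    seed=seed * 1000 + fold_idx)
        clf.fit(X[tr], y[tr])
        proba = clf.predict_proba(X[te])
        oof_pred[te] = np.argmax(proba, axis=1)
        oof_score[te] = proba[:, 1]
        models.append(clf)
        test_indices.append(te)
        if np.unique(y[te]).size == 2:
            folds.append(evaluate(proba, y[te]))
    return CVResults(folds=folds, models=models, test_indices=test_indices,
                     predictions=oof_pred, scores=oof_score, labels=y,
                     seed=seed)
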