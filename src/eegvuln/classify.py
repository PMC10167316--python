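"""Classifier benchmarking: DT, MLP, 1D-CNN, LSTM and BLSTM on windowed EEG.

Continuous or epoched EEG is cut into fixed-length windows (default 32
samples, never crossing trial boundaries); each window inherits its
subject's group as the binary label (high = 1, low = 0).  Two split
protocols are provided:

* ``sample_level`` — windows pooled over subjects, stratified 60:20:20
  (or k-fold).  This mirrors common practice but lets windows from the
  same subject appear in train and test, so accuracy can be inflated by
  subject-specific signal leaking across the split.
* ``subject_level`` — whole subjects assigned to exactly one partition;
  the honest protocol for subject-level claims.

Decision trees and the MLP (Adam, configurable hidden sizes) come from
scikit-learn; the 1D-CNN, LSTM and BLSTM are the package's own NumPy
networks (see :mod:`eegvuln.nn`), trained with early stopping on
validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from . import nn
from .containers import EpochSet, Recording

__all__ = [
    "WindowedDataset",
    "SplitSpec",
    "ModelSpec",
    "EvalReport",
    "window_sequences",
    "make_splits",
    "make_kfold",
    "train_eval",
    "benchmark",
]


@dataclass
class WindowedDataset:
    """Windows x channels x samples with labels and subject provenance."""

    x: np.ndarray  # (n_windows, n_channels, window)
    y: np.ndarray  # 0 = low, 1 = high
    subject_ids: np.ndarray  # str per window
    band: str = "raw"
    kind: str = "rest"  # 'rest' | 'task'

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.subject_ids)):
            raise ValueError("x, y and subject_ids must align")

    @property
    def n_windows(self) -> int:
        return len(self.x)

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(self.x[idx], self.y[idx], self.subject_ids[idx], self.band, self.kind)


@dataclass(frozen=True)
class SplitSpec:
    mode: str = "sample_level"  # 'sample_level' | 'subject_level'
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("sample_level", "subject_level"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if any(r <= 0 for r in self.ratios) or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must be positive and sum to 1")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one classifier family.

    Defaults follow the benchmarked configurations: DT depth 3 (Gini);
    MLP hidden (16, 8), lr 0.001, batch 32, Adam(0.9, 0.999); sequence
    models use window length 32, lr 0.001, batch 32; the BLSTM head is
    dropout + dense 64/32.
    """

    family: str  # 'dt' | 'mlp' | 'cnn1d' | 'lstm' | 'blstm'
    max_depth: int = 3
    hidden: tuple[int, ...] = (16, 8)
    conv_filters: tuple[int, ...] = (32, 64)
    kernel: int = 3
    lstm_hidden: int = 64
    dense_head: tuple[int, ...] = (64, 32)
    dropout: float = 0.2
    lr: float = 0.001
    batch_size: int = 32
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 50
    patience: int = 5

    def __post_init__(self) -> None:
        if self.family not in ("dt", "mlp", "cnn1d", "lstm", "blstm"):
            raise ValueError(f"unknown model family {self.family!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class EvalReport:
    family: str
    accuracy: float
    confusion: np.ndarray  # rows true (low, high), cols predicted
    precision: tuple[float, float]
    recall: tuple[float, float]
    f1: tuple[float, float]
    n_test: int
    split_mode: str
    seed: int
    band: str = "raw"
    kind: str = "rest"

    def as_row(self) -> dict:
        return {
            "model": self.family,
            "band": self.band,
            "data_kind": self.kind,
            "split_mode": self.split_mode,
            "seed": self.seed,
            "n_test": self.n_test,
            "accuracy": self.accuracy,
            "precision_low": self.precision[0],
            "precision_high": self.precision[1],
            "recall_low": self.recall[0],
            "recall_high": self.recall[1],
            "f1_low": self.f1[0],
            "f1_high": self.f1[1],
        }


# ---------------------------------------------------------------------------
# Windowing and splits
# ---------------------------------------------------------------------------


def window_sequences(
    source: EpochSet | Recording,
    window: int = 32,
    stride: Optional[int] = None,
    band: str = "raw",
    kind: str = "rest",
) -> WindowedDataset:
    """Cut fixed-length windows per trial (or from a continuous recording).

    Windows never cross trial boundaries; the label is the source
    subject's group.  ``stride`` defaults to ``window`` (disjoint tiling).
    """
    stride = window if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if isinstance(source, Recording):
        trials = source.data[None, :, :]
    else:
        trials = source.data
    if trials.shape[-1] < window:
        raise ValueError(f"window {window} longer than signal length {trials.shape[-1]}")
    if source.group not in ("high", "low"):
        raise ValueError("source must carry a group label")
    wins = []
    for t in range(trials.shape[0]):
        for s in range(0, trials.shape[-1] - window + 1, stride):
            wins.append(trials[t, :, s : s + window])
    x = np.stack(wins)
    y = np.full(len(wins), 1 if source.group == "high" else 0)
    sids = np.full(len(wins), source.subject_id, dtype=object)
    return WindowedDataset(x, y, sids, band=band, kind=kind)


def concat_windows(parts: Sequence[WindowedDataset]) -> WindowedDataset:
    if not parts:
        raise ValueError("no datasets to concatenate")
    return WindowedDataset(
        np.concatenate([p.x for p in parts]),
        np.concatenate([p.y for p in parts]),
        np.concatenate([p.subject_ids for p in parts]),
        band=parts[0].band,
        kind=parts[0].kind,
    )


def _stratified_three_way(y: np.ndarray, ratios, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n = len(idx)
        n_tr = int(round(ratios[0] * n))
        n_va = int(round(ratios[1] * n))
        train.append(idx[:n_tr])
        val.append(idx[n_tr : n_tr + n_va])
        test.append(idx[n_tr + n_va :])
    return (np.sort(np.concatenate(train)), np.sort(np.concatenate(val)), np.sort(np.concatenate(test)))


def make_splits(ds: WindowedDataset, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Train/val/test window indices; disjoint and exhaustive, seeded."""
    if ds.n_windows == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng([spec.seed % (2**31), 0x51])
    if spec.mode == "sample_level":
        return _stratified_three_way(ds.y, spec.ratios, rng)
    # subject_level: whole subjects to one partition, stratified by class
    subjects = pd.DataFrame({"sid": ds.subject_ids, "y": ds.y}).drop_duplicates("sid")
    parts = {0: [], 1: [], 2: []}
    for cls in (0, 1):
        sids = subjects.loc[subjects["y"] == cls, "sid"].to_numpy()
        if len(sids) < 3:
            raise ValueError("subject-level splits need >= 3 subjects per class")
        sids = rng.permutation(sids)
        n_tr = max(1, int(round(spec.ratios[0] * len(sids))))
        n_va = max(1, int(round(spec.ratios[1] * len(sids))))
        n_tr = min(n_tr, len(sids) - 2)
        parts[0].extend(sids[:n_tr])
        parts[1].extend(sids[n_tr : n_tr + n_va])
        parts[2].extend(sids[n_tr + n_va :])
    out = []
    for p in (0, 1, 2):
        sel = np.isin(ds.subject_ids, list(parts[p]))
        out.append(np.flatnonzero(sel))
    return tuple(out)


def make_kfold(ds: WindowedDataset, spec: SplitSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified (sample-level) or grouped (subject-level) k folds."""
    from sklearn.model_selection import GroupKFold, StratifiedKFold

    if spec.mode == "sample_level":
        cv = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=spec.seed % (2**31))
        return list(cv.split(ds.x.reshape(ds.n_windows, -1), ds.y))
    cv = GroupKFold(n_splits=spec.k)
    return list(cv.split(ds.x.reshape(ds.n_windows, -1), ds.y, groups=ds.subject_ids))


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------


def _build_network(model: ModelSpec, n_channels: int, window: int, seed: int) -> nn.Network:
    rng = np.random.default_rng([seed % (2**31), 0xDD])
    layers: list[nn.Layer] = []
    if model.family == "cnn1d":
        length = window
        c_in = n_channels
        for f in model.conv_filters:
            layers += [nn.Conv1D(c_in, f, model.kernel, rng), nn.ReLU()]
            length = length - model.kernel + 1
            if length >= 4:
                layers.append(nn.MaxPool1D(2))
                length //= 2
            c_in = f
        layers.append(nn.GlobalAvgPool1D())
        feat = c_in
    elif model.family in ("lstm", "blstm"):
        layers.append(nn.TimeFirst())
        if model.family == "lstm":
            layers.append(nn.LSTM(n_channels, model.lstm_hidden, rng))
            feat = model.lstm_hidden
        else:
            layers.append(nn.BiLSTM(n_channels, model.lstm_hidden, rng))
            feat = 2 * model.lstm_hidden
        if model.dropout > 0:
            layers.append(nn.Dropout(model.dropout, rng))
    else:
        raise ValueError(f"no network builder for family {model.family!r}")
    for h in model.dense_head:
        layers += [nn.Dense(feat, h, rng), nn.ReLU()]
        feat = h
    layers.append(nn.Dense(feat, 2, rng))
    return nn.Network(layers, seed=seed)


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, tuple, tuple, tuple]:
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    precision, recall, f1 = [], [], []
    for cls in (0, 1):
        tp = cm[cls, cls]
        fp = cm[1 - cls, cls]
        fn = cm[cls, 1 - cls]
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        precision.append(float(p))
        recall.append(float(r))
        f1.append(float(f))
    return cm, tuple(precision), tuple(recall), tuple(f1)


def train_eval(
    ds: WindowedDataset,
    model: ModelSpec,
    splits: tuple[np.ndarray, np.ndarray, np.ndarray],
    seed: int = 0,
    split_mode: str = "sample_level",
) -> EvalReport:
    """Fit on train (validation for early stopping of neural nets), report on test."""
    if not np.all(np.isfinite(ds.x)):
        raise ValueError("non-finite values in dataset")
    tr, va, te = splits
    x_flat = ds.x.reshape(ds.n_windows, -1)
    y = ds.y
    if model.family == "dt":
        clf = DecisionTreeClassifier(max_depth=model.max_depth, criterion="gini", random_state=seed % (2**31))
        clf.fit(x_flat[np.concatenate([tr, va])], y[np.concatenate([tr, va])])
        y_pred = clf.predict(x_flat[te])
    elif model.family == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=model.hidden,
            solver="adam",
            learning_rate_init=model.lr,
            batch_size=model.batch_size,
            beta_1=model.beta1,
            beta_2=model.beta2,
            max_iter=model.max_epochs,
            n_iter_no_change=model.patience,
            random_state=seed % (2**31),
        )
        clf.fit(x_flat[np.concatenate([tr, va])], y[np.concatenate([tr, va])])
        y_pred = clf.predict(x_flat[te])
    else:
        net = _build_network(model, ds.x.shape[1], ds.x.shape[2], seed)
        # standardize on the training partition
        mu = ds.x[tr].mean()
        sd = ds.x[tr].std() or 1.0
        xs = (ds.x - mu) / sd
        net.fit(
            xs[tr],
            y[tr],
            xs[va],
            y[va],
            epochs=model.max_epochs,
            batch_size=model.batch_size,
            lr=model.lr,
            beta1=model.beta1,
            beta2=model.beta2,
            patience=model.patience,
        )
        y_pred = net.predict(xs[te])
    cm, precision, recall, f1 = _metrics(y[te], y_pred)
    return EvalReport(
        family=model.family,
        accuracy=float((y_pred == y[te]).mean()),
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        n_test=len(te),
        split_mode=split_mode,
        seed=seed,
        band=ds.band,
        kind=ds.kind,
    )


def benchmark(
    datasets: Sequence[WindowedDataset],
    models: Sequence[ModelSpec],
    split_spec: SplitSpec,
) -> pd.DataFrame:
    """Cross-product run over datasets (e.g. bands) and model families."""
    rows = []
    for ds in datasets:
        splits = make_splits(ds, split_spec)
        for model in models:
            rep = train_eval(ds, model, splits, seed=split_spec.seed, split_mode=split_spec.mode)
            rows.append(rep.as_row())
    cols = [
        "model", "band", "data_kind", "split_mode", "seed", "n_test", "accuracy",
        "precision_low", "precision_high", "recall_low", "recall_high", "f1_low", "f1_high",
    ]
    return pd.DataFrame(rows, columns=cols)
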