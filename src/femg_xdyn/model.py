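"""CNN-TCN expression classifier, baseline architectures, training loop,
classification metrics and leave-one-participant-out (LOPO) validation.

The default network mirrors the three-block design: a CNN block (two 1-D
convolutions over time with batch norm, ReLU and max pooling) extracting
inter-channel spatial patterns, a TCN block (residual dilated causal
convolutions) modeling temporal dependencies, and a fully connected head
ending in a 4-way softmax.  Baselines (cnn, tcn, lstm, gru, cnn-lstm) share
the training and evaluation contract.

Class imbalance (calibration sets are neutral-heavy) is handled with
inverse-frequency class weights in the loss.  Early stopping monitors the
validation weighted F1.  Everything is seeded and single-threaded
deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

from . import nn
from .io_preprocess import LabeledWindow
from .types import CHANNELS, LABEL_NAMES, N_CHANNELS, N_CLASSES, label_id

ARCHITECTURES = ("cnn", "tcn", "lstm", "cnn-lstm", "gru", "cnn-tcn")


@dataclass
class ModelConfig:
    architecture: str = "cnn-tcn"
    cnn_filters: tuple[int, ...] = (32, 64)
    cnn_kernel: int = 5
    pool: int = 2
    tcn_filters: int = 64
    tcn_kernel: int = 3
    tcn_dilations: tuple[int, ...] = (1, 2, 4)
    dropout: float = 0.2
    rnn_hidden: int = 32
    fc_hidden: int = 64
    n_classes: int = N_CLASSES
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    class_weighting: str = "inverse"  # or "none"
    n_val_participants: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; one of {ARCHITECTURES}")
        if self.n_classes != N_CLASSES:
            raise ValueError("n_classes must be 4")
        d = self.tcn_dilations
        if any(b <= a for a, b in zip(d, d[1:])) or any(x & (x - 1) for x in d):
            raise ValueError("tcn_dilations must be strictly increasing powers of 2")
        if self.class_weighting not in ("inverse", "none"):
            raise ValueError("class_weighting must be 'inverse' or 'none'")


@dataclass
class ExpressionClassifier:
    """A built network with its window length and fixed class order."""

    net: nn.Sequential
    config: ModelConfig
    window_len: int
    class_order: tuple[str, ...] = LABEL_NAMES

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Class probabilities for windows X of shape (n, w, 7)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != self.window_len or X.shape[2] != N_CHANNELS:
            raise ValueError(
                f"windows must be (n, {self.window_len}, {N_CHANNELS}), got {X.shape}"
            )
        out = np.empty((X.shape[0], self.config.n_classes))
        for a in range(0, X.shape[0], batch):
            logits = self.net.forward(np.transpose(X[a : a + batch], (0, 2, 1)), training=False)
            out[a : a + batch] = nn.softmax(logits)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Integer class ids; argmax with ties broken by the fixed class
        order (neutral < smile < frown < raised_eyebrow)."""
        return self.predict_proba(X).argmax(axis=1)

    @property
    def n_parameters(self) -> int:
        return nn.parameter_count(self.net)


def _cnn_stack(cfg: ModelConfig, rng: np.random.Generator) -> tuple[list[nn.Layer], int]:
    layers: list[nn.Layer] = []
    in_ch = N_CHANNELS
    for f in cfg.cnn_filters:
        layers += [
            nn.Conv1d(in_ch, f, cfg.cnn_kernel, rng),
            nn.BatchNorm1d(f),
            nn.ReLU(),
            nn.MaxPool1d(cfg.pool),
        ]
        in_ch = f
    return layers, in_ch


def _fc_head(cfg: ModelConfig, in_dim: int, rng: np.random.Generator) -> list[nn.Layer]:
    return [
        nn.Dense(in_dim, cfg.fc_hidden, rng),
        nn.ReLU(),
        nn.Dropout(cfg.dropout, rng),
        nn.Dense(cfg.fc_hidden, cfg.n_classes, rng),
    ]


def build_model(config: ModelConfig, window_len: int) -> ExpressionClassifier:
    """Build a seeded, untrained classifier for (window_len x 7) inputs."""
    config.validate()
    pooled = window_len
    if config.architecture in ("cnn", "cnn-tcn", "cnn-lstm"):
        for _ in config.cnn_filters:
            pooled //= config.pool
        if pooled < 1:
            raise ValueError(
                f"window length {window_len} incompatible with {len(config.cnn_filters)} "
                f"pooling stages of size {config.pool}"
            )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 11]))
    layers: list[nn.Layer]
    if config.architecture == "cnn-tcn":
        layers, ch = _cnn_stack(config, rng)
        for d in config.tcn_dilations:
            layers.append(nn.TCNBlock(ch, config.tcn_filters, config.tcn_kernel, d, config.dropout, rng))
            ch = config.tcn_filters
        layers.append(nn.GlobalAvgPool())
        layers += _fc_head(config, ch, rng)
    elif config.architecture == "cnn":
        layers, ch = _cnn_stack(config, rng)
        layers.append(nn.GlobalAvgPool())
        layers += _fc_head(config, ch, rng)
    elif config.architecture == "tcn":
        layers = []
        ch = N_CHANNELS
        for d in config.tcn_dilations:
            layers.append(nn.TCNBlock(ch, config.tcn_filters, config.tcn_kernel, d, config.dropout, rng))
            ch = config.tcn_filters
        layers.append(nn.GlobalAvgPool())
        layers += _fc_head(config, ch, rng)
    elif config.architecture == "lstm":
        layers = [nn.LSTMLayer(N_CHANNELS, config.rnn_hidden, rng)]
        layers += _fc_head(config, config.rnn_hidden, rng)
    elif config.architecture == "gru":
        layers = [nn.GRULayer(N_CHANNELS, config.rnn_hidden, rng)]
        layers += _fc_head(config, config.rnn_hidden, rng)
    else:  # cnn-lstm
        layers, ch = _cnn_stack(config, rng)
        layers.append(nn.LSTMLayer(ch, config.rnn_hidden, rng))
        layers += _fc_head(config, config.rnn_hidden, rng)
    return ExpressionClassifier(nn.Sequential(layers), config, window_len)


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class ClassificationMetrics:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    roc_auc: float
    confusion: np.ndarray  # 4x4 row-normalized by true class

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        d.pop("confusion")
        return d


def evaluate(
    y_true: np.ndarray, y_pred: np.ndarray, probabilities: np.ndarray | None = None
) -> ClassificationMetrics:
    """Standard metric suite.

    Macro metrics average per-class scores without weighting; weighted
    metrics weight by true-class frequency.  Precision of a never-predicted
    class is 0.  ROC-AUC is one-vs-rest, macro-averaged over classes present
    in ``y_true`` (absent classes excluded with a warning).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    labels = np.arange(N_CLASSES)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mp, mr, mf, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="macro", zero_division=0
        )
        wp, wr, wf, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="weighted", zero_division=0
        )
    auc = np.nan
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        if probabilities.shape != (y_true.size, N_CLASSES):
            raise ValueError("probabilities must be (n, 4)")
        if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        aucs = []
        for c in labels:
            pos = y_true == c
            if pos.all() or not pos.any():
                warnings.warn(f"class {LABEL_NAMES[c]} degenerate in y_true; excluded from ROC-AUC")
                continue
            aucs.append(roc_auc_score(pos, probabilities[:, c]))
        auc = float(np.mean(aucs)) if aucs else np.nan
    cm = confusion_matrix(y_true, y_pred, labels=labels).astype(float)
    row = cm.sum(axis=1, keepdims=True)
    cm = np.divide(cm, row, out=np.zeros_like(cm), where=row > 0)
    return ClassificationMetrics(
        accuracy=float(accuracy_score(y_true, y_pred)),
        macro_precision=float(mp),
        macro_recall=float(mr),
        macro_f1=float(mf),
        weighted_precision=float(wp),
        weighted_recall=float(wr),
        weighted_f1=float(wf),
        roc_auc=float(auc),
        confusion=cm,
    )


def permutation_null_macro_f1(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
    balanced: bool = True,
) -> float:
    """Chance-level macro-F1 floor: mean macro-F1 of the predictions against
    label permutations.  With ``balanced=True`` classes are first subsampled
    to equal counts so the chance level is ~1/n_classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    rng = np.random.default_rng(seed)
    if balanced:
        counts = np.bincount(y_true, minlength=N_CLASSES)
        m = counts[counts > 0].min()
        idx = np.concatenate(
            [rng.permutation(np.flatnonzero(y_true == c))[:m] for c in range(N_CLASSES) if counts[c]]
        )
        y_true, y_pred = y_true[idx], y_pred[idx]
    vals = [
        evaluate(rng.permutation(y_true), y_pred).macro_f1 for _ in range(n_permutations)
    ]
    return float(np.mean(vals))


def predict_window(model: ExpressionClassifier, window: np.ndarray) -> tuple[str, np.ndarray]:
    """Label and probability vector of one (w x 7) window."""
    probs = model.predict_proba(window[None] if window.ndim == 2 else window)[0]
    return LABEL_NAMES[int(probs.argmax())], probs


# ---------------------------------------------------------------------------
# Training


def _class_weights(y: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return np.ones(N_CLASSES)
    counts = np.bincount(y, minlength=N_CLASSES).astype(float)
    w = np.where(counts > 0, np.where(counts > 0, counts, 1) ** -1.0, 0.0)
    nz = w[w > 0]
    return w / nz.mean() if nz.size else np.ones(N_CLASSES)


def train(
    model: ExpressionClassifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> dict:
    """Train in place with Adam on class-weighted cross-entropy.

    Early stopping monitors validation weighted F1 (training loss when no
    validation split is given); the best parameters are restored.  Returns a
    history dict with per-epoch loss and weighted F1 for both splits.
    """
    cfg = model.config
    y_train = np.asarray(y_train)
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels must contain >= 2 classes")
    if y_val is not None and len(np.unique(y_val)) < N_CLASSES:
        warnings.warn("validation set is missing a class; metrics computed over present classes")
    weights = _class_weights(y_train, cfg.class_weighting)
    loss_fn = nn.WeightedCrossEntropy()
    opt = nn.Adam(model.net, lr=cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 13]))
    Xt = np.transpose(np.asarray(X_train, dtype=float), (0, 2, 1))
    history: dict[str, list] = {"epoch": [], "train_loss": [], "train_wf1": [], "val_loss": [], "val_wf1": []}
    best_score, best_params, best_epoch, bad = -np.inf, None, 0, 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(Xt.shape[0])
        losses = []
        for a in range(0, len(order), cfg.batch_size):
            idx = order[a : a + cfg.batch_size]
            logits = model.net.forward(Xt[idx], training=True)
            losses.append(loss_fn.forward(logits, y_train[idx], weights))
            model.net.backward(loss_fn.backward())
            opt.step()
        train_pred = model.predict(X_train)
        train_wf1 = evaluate(y_train, train_pred).weighted_f1
        train_loss = float(np.mean(losses))
        if X_val is not None and len(X_val):
            val_probs = model.predict_proba(X_val)
            val_pred = val_probs.argmax(axis=1)
            val_wf1 = evaluate(y_val, val_pred).weighted_f1
            val_loss = loss_fn.forward(np.log(val_probs + 1e-12), np.asarray(y_val), weights)
            score = val_wf1
        else:
            val_wf1, val_loss = np.nan, np.nan
            score = -train_loss
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["train_wf1"].append(train_wf1)
        history["val_loss"].append(val_loss)
        history["val_wf1"].append(val_wf1)
        if score > best_score + 1e-6:
            best_score, best_epoch, bad = score, epoch, 0
            best_params = [p.copy() for p in nn.get_parameters(model.net)]
        else:
            bad += 1
            if bad >= cfg.patience:
                break
    if best_params is not None:
        nn.set_parameters(model.net, best_params)
    history["stopped_epoch"] = history["epoch"][-1]
    history["best_epoch"] = best_epoch
    return history


# ---------------------------------------------------------------------------
# Windows <-> arrays


def windows_to_arrays(windows: list[LabeledWindow]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack labeled windows into (X, y, participant_ids)."""
    labeled = [w for w in windows if w.label is not None]
    if not labeled:
        raise ValueError("no labeled windows")
    X = np.stack([w.data for w in labeled])
    y = np.array([label_id(w.label) for w in labeled])
    pids = np.array([w.participant for w in labeled])
    return X, y, pids


# ---------------------------------------------------------------------------
# LOPO cross-validation


@dataclass
class FoldResult:
    test_participant: str
    train: ClassificationMetrics
    validation: ClassificationMetrics
    test: ClassificationMetrics
    history: dict = field(repr=False, default_factory=dict)


@dataclass
class LOPOResult:
    folds: list[FoldResult]

    def aggregate(self, split: str = "test") -> dict[str, tuple[float, float]]:
        """Mean and SD of each scalar metric across folds."""
        out: dict[str, tuple[float, float]] = {}
        for key in self.folds[0].test.as_dict():
            vals = np.array([getattr(f, split).as_dict()[key] for f in self.folds])
            out[key] = (float(np.nanmean(vals)), float(np.nanstd(vals)))
        return out


def _fold_splits(participants: list[str], fold: int, n_val: int) -> tuple[list[str], list[str]]:
    """Rotating participant-disjoint validation split for one LOPO fold."""
    remaining = [p for i, p in enumerate(participants) if i != fold]
    n_val = min(n_val, len(remaining) - 1)
    val = [remaining[(fold + j) % len(remaining)] for j in range(n_val)]
    train_p = [p for p in remaining if p not in val]
    return train_p, val


def lopo_cross_validate(
    X: np.ndarray, y: np.ndarray, pids: np.ndarray, config: ModelConfig
) -> LOPOResult:
    """Leave-one-participant-out validation: each participant is the test
    set exactly once; the validation subset is participant-disjoint from
    training (rotating choice of ``n_val_participants``)."""
    config.validate()
    participants = sorted(np.unique(pids))
    if len(participants) < 3:
        raise ValueError("LOPO requires >= 3 participants")
    folds: list[FoldResult] = []
    for fold, test_p in enumerate(participants):
        train_p, val_p = _fold_splits(participants, fold, config.n_val_participants)
        tr = np.isin(pids, train_p)
        va = np.isin(pids, val_p)
        te = pids == test_p
        assert not (tr & va).any() and not (tr & te).any() and not (va & te).any()
        model = build_model(config, X.shape[1])
        hist = train(model, X[tr], y[tr], X[va], y[va])
        fold_metrics = {}
        for name, mask in (("train", tr), ("validation", va), ("test", te)):
            probs = model.predict_proba(X[mask])
            fold_metrics[name] = evaluate(y[mask], probs.argmax(axis=1), probs)
        folds.append(FoldResult(test_p, fold_metrics["train"], fold_metrics["validation"], fold_metrics["test"], hist))
    return LOPOResult(folds)


def retrain_full(
    X: np.ndarray,
    y: np.ndarray,
    pids: np.ndarray,
    config: ModelConfig,
    expected_participants: list[str] | None = None,
    val_fraction: float = 0.1,
) -> tuple[ExpressionClassifier, dict, ClassificationMetrics]:
    """Retrain a single shared model on the full pooled calibration set, with
    a random held-out window split for monitoring."""
    config.validate()
    if expected_participants is not None:
        missing = set(expected_participants) - set(np.unique(pids))
        if missing:
            warnings.warn(f"calibration data missing for participants {sorted(missing)}; proceeding")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 17]))
    order = rng.permutation(X.shape[0])
    n_val = max(1, int(val_fraction * X.shape[0]))
    va, tr = order[:n_val], order[n_val:]
    model = build_model(config, X.shape[1])
    history = train(model, X[tr], y[tr], X[va], y[va])
    probs = model.predict_proba(X[va])
    metrics = evaluate(y[va], probs.argmax(axis=1), probs)
    return model, history, metrics


def train_baseline(
    architecture: str, X: np.ndarray, y: np.ndarray, pids: np.ndarray, config: ModelConfig
) -> LOPOResult:
    """Run LOPO for one of the benchmark architectures under the identical
    training/evaluation contract."""
    cfg = ModelConfig(**{**asdict(config), "architecture": architecture})
    # dataclass asdict turns tuples into lists; restore
    cfg.cnn_filters = tuple(cfg.cnn_filters)
    cfg.tcn_dilations = tuple(cfg.tcn_dilations)
    return lopo_cross_validate(X, y, pids, cfg)


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: ExpressionClassifier, path: str | Path) -> None:
    """Save parameters (+ batch-norm running stats) as .npz with a JSON
    descriptor next to it."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.net.layers()):
        for name, p in layer.params.items():
            arrays[f"{i}:{name}"] = p
        if isinstance(layer, nn.BatchNorm1d):
            arrays[f"{i}:running_mean"] = layer.running_mean
            arrays[f"{i}:running_var"] = layer.running_var
    np.savez(path.with_suffix(".npz"), **arrays)
    desc = {
        "config": asdict(model.config),
        "window_len": model.window_len,
        "class_order": list(model.class_order),
        "channel_order": list(CHANNELS),
    }
    path.with_suffix(".json").write_text(json.dumps(desc, indent=1))


def load_model(path: str | Path) -> ExpressionClassifier:
    path = Path(path)
    desc = json.loads(path.with_suffix(".json").read_text())
    cfg_d = desc["config"]
    cfg_d["cnn_filters"] = tuple(cfg_d["cnn_filters"])
    cfg_d["tcn_dilations"] = tuple(cfg_d["tcn_dilations"])
    config = ModelConfig(**cfg_d)
    model = build_model(config, desc["window_len"])
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    data = np.load(npz_path)
    for i, layer in enumerate(model.net.layers()):
        for name in layer.params:
            layer.params[name][...] = data[f"{i}:{name}"]
        if isinstance(layer, nn.BatchNorm1d):
            layer.running_mean = data[f"{i}:running_mean"]
            layer.running_var = data[f"{i}:running_var"]
    return model
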