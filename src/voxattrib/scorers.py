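"""Small differentiable 3D-CNN scorers over voxel grids.

Three tasks are supported: a clash detector and a docking-pose classifier
(binary, pre-sigmoid logit output) and a pKd-like regression head.  The
attribution pipeline only requires the scorer to expose ``forward`` (grid
batch -> scalar per grid) and ``input_gradients``; a closed-form
:class:`LinearScorer` implements the same interface for diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._net import Adam, Conv3DNet, bce_with_logits, mse
from .voxelizer import ChannelScheme, VoxelGrid, default_scheme

TASKS = ("clash", "pose", "regression")


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    lr: float = 2e-3
    epochs: int = 30
    batch_size: int = 16
    val_fraction: float = 0.2
    patience: int = 4
    min_delta: float = 1e-3
    seed: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _as_batch(grids) -> np.ndarray:
    if isinstance(grids, VoxelGrid):
        return grids.values[None].astype(np.float32)
    if isinstance(grids, np.ndarray):
        return grids if grids.ndim == 5 else grids[None]
    return np.stack([g.values for g in grids]).astype(np.float32)


@dataclass
class TrainedScorer:
    """A differentiable grid -> scalar scorer with its training metadata."""

    task: str
    net: Conv3DNet
    scheme_fingerprint: str
    train_config: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def forward(self, grids) -> np.ndarray:
        return self.net.forward(_as_batch(grids))

    def input_gradients(self, grids) -> np.ndarray:
        return self.net.input_gradients(_as_batch(grids))

    def __call__(self, grids) -> np.ndarray:
        return self.forward(grids)

    # -- checkpointing ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = json.dumps(dict(task=self.task,
                               scheme_fingerprint=self.scheme_fingerprint,
                               net_config={k: (list(v) if isinstance(v, tuple) else v)
                                           for k, v in self.net.config.items()},
                               train_config=self.train_config,
                               metrics=self.metrics))
        np.savez(path, __meta__=np.array(meta), **self.net.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedScorer":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = {k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in meta["net_config"].items()}
            net = Conv3DNet(**cfg)
            net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
        return cls(task=meta["task"], net=net,
                   scheme_fingerprint=meta["scheme_fingerprint"],
                   train_config=meta["train_config"], metrics=meta["metrics"])


class LinearScorer:
    """F(x) = sum_i w_i x_i + b — a scorer whose attributions are known exactly."""

    def __init__(self, weights: np.ndarray, bias: float = 0.0):
        self.weights = np.asarray(weights, dtype=float)
        self.bias = float(bias)
        self.task = "linear"

    def forward(self, grids) -> np.ndarray:
        x = _as_batch(grids).astype(float)
        return np.tensordot(x, self.weights, axes=([1, 2, 3, 4], [0, 1, 2, 3])) + self.bias

    def input_gradients(self, grids) -> np.ndarray:
        x = _as_batch(grids)
        return np.broadcast_to(self.weights, x.shape).astype(float).copy()

    def __call__(self, grids):
        return self.forward(grids)


def build_scorer(task: str, scheme: ChannelScheme | None = None,
                 seed: int = 0, grid_size: int = 24) -> TrainedScorer:
    """Untrained scorer with deterministic seed-controlled initialization."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    scheme = scheme or default_scheme()
    if len(scheme) != 16:
        raise ValueError("channel scheme must define 16 channels")
    net = Conv3DNet(in_channels=16, grid_size=grid_size, seed=seed)
    return TrainedScorer(task=task, net=net,
                         scheme_fingerprint=scheme.fingerprint)


def train_scorer(scorer: TrainedScorer, grids, labels,
                 config: TrainConfig | None = None) -> TrainedScorer:
    """Train in place by Adam on cross-entropy (classification) or MSE.

    A fixed seed-controlled split holds out ``val_fraction`` of the data;
    training early-stops on validation loss and restores the best weights.
    Held-out metrics (accuracy/precision or Pearson r) are recorded on the
    returned scorer.
    """
    config = config or TrainConfig()
    X = _as_batch(grids)
    y = np.asarray(labels, dtype=np.float32)
    if not np.all(np.isfinite(y)):
        raise TrainingError("labels must be finite")
    classification = scorer.task in ("clash", "pose")
    if classification and len(np.unique(y)) < 2:
        raise TrainingError("classification needs at least two classes present")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(X))
    n_val = max(1, int(round(config.val_fraction * len(X))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise TrainingError("no training samples left after validation split")
    loss_fn = bce_with_logits if classification else mse

    opt = Adam(scorer.net, lr=config.lr)
    best_val = np.inf
    best_state = scorer.net.state_arrays()
    best_state = {k: v.copy() for k, v in best_state.items()}
    stale = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(train_idx)
        scorer.net.train_mode(True)
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start:start + config.batch_size]
            z = scorer.net.forward(X[batch])
            loss, dz = loss_fn(z, y[batch])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"training diverged (loss={loss}) with config {config.to_dict()}")
            scorer.net.backward(dz)
            opt.step()
        scorer.net.train_mode(False)
        val_loss = _dataset_loss(scorer.net, X, y, val_idx, loss_fn,
                                 config.batch_size)
        if val_loss < best_val - config.min_delta:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in scorer.net.state_arrays().items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    scorer.net.load_state_arrays(best_state)

    scorer.train_config = config.to_dict()
    if classification:
        metrics = evaluate_classifier(scorer, X[val_idx], y[val_idx])
    else:
        pred = _predict(scorer.net, X, val_idx, config.batch_size)
        truth = y[val_idx]
        if np.std(pred) > 0 and np.std(truth) > 0:
            r = float(np.corrcoef(pred, truth)[0, 1])
        else:
            r = None
        metrics = {"pearson_r": r, "val_loss": best_val}
    metrics["n_validation"] = int(n_val)
    scorer.metrics = metrics
    return scorer


def _predict(net: Conv3DNet, X: np.ndarray, idx: np.ndarray,
             batch_size: int) -> np.ndarray:
    out = np.empty(len(idx), dtype=np.float64)
    for start in range(0, len(idx), batch_size):
        sel = idx[start:start + batch_size]
        out[start:start + len(sel)] = net.forward(X[sel])
    return out


def _dataset_loss(net, X, y, idx, loss_fn, batch_size) -> float:
    z = _predict(net, X, idx, batch_size)
    loss, _ = loss_fn(z, y[idx].astype(np.float64))
    return loss


def evaluate_classifier(scorer: TrainedScorer, grids, labels) -> dict:
    """Accuracy and precision at decision threshold logit 0.

    Precision is ``None`` (undefined) when nothing is predicted positive.
    """
    X = _as_batch(grids)
    if len(X) == 0:
        raise ValueError("empty evaluation set")
    y = np.asarray(labels).astype(int)
    if isinstance(scorer, TrainedScorer):
        z = _predict(scorer.net, X, np.arange(len(X)), 32)
    else:
        z = np.asarray(scorer.forward(X))
    pred = (np.asarray(z) > 0).astype(int)
    accuracy = float(np.mean(pred == y))
    n_pos_pred = int(pred.sum())
    if n_pos_pred == 0:
        precision = None
    else:
        precision = float(np.sum((pred == 1) & (y == 1)) / n_pos_pred)
    return {"accuracy": accuracy, "precision": precision}
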