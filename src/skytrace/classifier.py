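"""Training and prediction pipeline for the trajectory classifier.

The classifier labels a trajectory as biological ("bird-like", label 0)
or mechanical ("drone-like", label 1) from its 3-D positions alone.
Pipeline: load JSON records, thin each to at most ``max_len`` frames,
split stratified by class, standardise features with the mean and
standard deviation of the *training* frames only, zero-pad to
``max_len`` with a validity mask, and train a stacked bidirectional
recurrent network (LSTM by default, GRU as a baseline) with Adam on a
masked per-frame binary cross-entropy in which the sequence label is
broadcast to every valid frame.  The overall probability of a
trajectory is the masked mean of its per-frame probabilities; model
selection keeps the epoch with the highest validation AUC of that
sequence probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .nn import Adam, BiRNNClassifier
from .simulate import (
    TrajectoryRecord,
    downsample,
    generate_dataset,
    load_dataset,
    read_trajectory_json,
)

__all__ = [
    "NormalizationStats",
    "ClassifierConfig",
    "TrainedModel",
    "split_dataset",
    "compute_stats",
    "normalize",
    "denormalize",
    "pad_and_mask",
    "masked_bce",
    "sequence_probability",
    "train",
    "gru_train",
    "evaluate_auc",
    "predict_record",
    "predict_file",
    "save_model",
    "load_model",
    "plot_loss_history",
]

_SIGMA_FLOOR = 1e-8
_BCE_EPS = 1e-7


@dataclass
class NormalizationStats:
    """Per-feature mean and standard deviation of the training frames."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(3)
        self.sigma = np.maximum(np.asarray(self.sigma, dtype=float).reshape(3),
                                _SIGMA_FLOOR)


@dataclass
class ClassifierConfig:
    """Hyper-parameters of the classifier and its training schedule."""

    input_dim: int = 3
    hidden: int = 64
    layers: int = 2
    bidirectional: bool = True
    dropout: float = 0.2
    max_len: int = 100
    learning_rate: float = 1e-3
    epochs: int = 35
    batch_size: int = 16
    split_fraction: float = 0.8
    seed: int = 0
    cell: str = "lstm"


@dataclass
class TrainedModel:
    """A trained classifier, its normalisation statistics and history.

    ``model`` carries the best-validation-AUC weights (the selected
    model); ``final_weights`` keeps the weights after the last epoch.
    """

    model: BiRNNClassifier
    stats: NormalizationStats
    config: ClassifierConfig
    loss_history: list[float] = field(default_factory=list)
    auc_history: list[float] = field(default_factory=list)
    best_epoch: int = 0
    final_weights: dict | None = None


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def split_dataset(
    records: list[TrajectoryRecord], split_fraction: float, seed: int
) -> tuple[list[TrajectoryRecord], list[TrajectoryRecord]]:
    """Disjoint stratified split, deterministic given ``seed``."""
    birds = [r for r in records if not r.is_drone]
    drones = [r for r in records if r.is_drone]
    if not birds or not drones:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    train: list[TrajectoryRecord] = []
    test: list[TrajectoryRecord] = []
    for group in (birds, drones):
        idx = rng.permutation(len(group))
        n_train = int(round(split_fraction * len(group)))
        train.extend(group[i] for i in idx[:n_train])
        test.extend(group[i] for i in idx[n_train:])
    return train, test


def compute_stats(records: list[TrajectoryRecord]) -> NormalizationStats:
    """Mean/std per feature, pooled over all frames of all records."""
    if not records:
        raise ValueError("cannot compute statistics of an empty training set")
    pooled = np.concatenate([r.positions for r in records], axis=0)
    return NormalizationStats(mu=pooled.mean(axis=0), sigma=pooled.std(axis=0))


def normalize(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Feature-wise standardisation ``(X - mu) / sigma``."""
    return (np.asarray(X, dtype=float) - stats.mu) / stats.sigma


def denormalize(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return np.asarray(X, dtype=float) * stats.sigma + stats.mu


def pad_and_mask(
    sequences: list[np.ndarray], max_len: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad sequences with zeros to ``max_len``; return batch and mask.

    Sequences longer than ``max_len`` are truncated to their first
    ``max_len`` frames; the mask is 1 on valid frames and 0 on padding.
    """
    if not sequences:
        raise ValueError("empty batch")
    B = len(sequences)
    X = np.zeros((B, max_len, 3))
    mask = np.zeros((B, max_len))
    for i, seq in enumerate(sequences):
        seq = np.asarray(seq, dtype=float)
        if seq.ndim != 2 or seq.shape[1] != 3 or len(seq) == 0:
            raise ValueError("each sequence must be a non-empty (T, 3) array")
        n = min(len(seq), max_len)
        X[i, :n] = seq[:n]
        mask[i, :n] = 1.0
    return X, mask


# ---------------------------------------------------------------------------
# loss and aggregation
# ---------------------------------------------------------------------------


def masked_bce(p: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    """Mean binary cross-entropy over valid frames only.

    Padded frames provably do not contribute: their entries are
    multiplied by a zero mask before the sum.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=float)
    total = mask.sum()
    if total <= 0:
        raise ValueError("mask must select at least one valid frame")
    pc = np.clip(p, _BCE_EPS, 1.0 - _BCE_EPS)
    bce = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    return float((bce * mask).sum() / total)


def sequence_probability(p: np.ndarray, mask: np.ndarray) -> float | np.ndarray:
    """Masked mean of per-frame probabilities (the trajectory score).

    Accepts a single sequence (1-D) or a batch (2-D, reduced over the
    last axis).  The binary decision threshold is 0.5.
    """
    p = np.asarray(p, dtype=float)
    mask = np.asarray(mask, dtype=float)
    total = mask.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("mask must select at least one valid frame")
    out = (p * mask).sum(axis=-1) / total
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _prepare(records, stats, max_len):
    seqs = [normalize(r.positions, stats) for r in records]
    X, mask = pad_and_mask(seqs, max_len)
    y = np.array([1.0 if r.is_drone else 0.0 for r in records])
    return X, mask, y


def _sequence_scores(model, X, mask, batch_size=64):
    scores = []
    for i in range(0, len(X), batch_size):
        p = model.forward(X[i:i + batch_size])
        scores.append(sequence_probability(p, mask[i:i + batch_size]))
    return np.concatenate([np.atleast_1d(s) for s in scores])


def train(
    dataset_dir: str | Path,
    config: ClassifierConfig | None = None,
    *,
    n_per_class_if_empty: int = 200,
    log=None,
) -> TrainedModel:
    """Train the classifier on a directory of trajectory JSON files.

    If the directory is empty (or missing), a balanced synthetic
    dataset is generated there first.  Deterministic given
    ``config.seed``: data order, weight initialisation and dropout all
    derive from it.  Returns a :class:`TrainedModel` whose ``model``
    holds the best-validation-AUC weights.
    """
    if config is None:
        config = ClassifierConfig()
    dataset_dir = Path(dataset_dir)
    if not dataset_dir.exists() or not any(dataset_dir.glob("*.json")):
        generate_dataset(n_per_class_if_empty, dataset_dir, seed=config.seed)
    records = [downsample(r, config.max_len) for r in load_dataset(dataset_dir)]
    return train_records(records, config, log=log)


def train_records(
    records: list[TrajectoryRecord],
    config: ClassifierConfig | None = None,
    *,
    log=None,
) -> TrainedModel:
    """Train on in-memory records (already at classifier length)."""
    if config is None:
        config = ClassifierConfig()
    labels = {bool(r.is_drone) for r in records}
    if labels != {False, True}:
        raise ValueError("training requires records from both classes")

    train_recs, test_recs = split_dataset(records, config.split_fraction, config.seed)
    stats = compute_stats(train_recs)
    Xtr, mtr, ytr = _prepare(train_recs, stats, config.max_len)
    Xte, mte, yte = _prepare(test_recs, stats, config.max_len)

    rng = np.random.default_rng(config.seed)
    model = BiRNNClassifier(
        input_size=config.input_dim, hidden=config.hidden,
        n_layers=config.layers, dropout=config.dropout,
        cell=config.cell, rng=rng,
    )
    opt = Adam(model.parameters(), lr=config.learning_rate)

    loss_history: list[float] = []
    auc_history: list[float] = []
    best_auc = -np.inf
    best_epoch = 0
    best_weights = model.get_weights()
    n = len(Xtr)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        loss_sum = 0.0
        frame_sum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb, mb = Xtr[idx], mtr[idx]
            yb = np.broadcast_to(ytr[idx][:, None], mb.shape)
            p = model.forward(Xb, train=True, rng=rng)
            loss = masked_bce(p, yb, mb)
            # d(masked BCE)/d(logit) = (p - y) * mask / sum(mask)
            dlogits = (p - yb) * mb / mb.sum()
            model.zero_grad()
            model.backward(dlogits)
            opt.step(model.gradients())
            valid = mb.sum()
            loss_sum += loss * valid
            frame_sum += valid
        loss_history.append(loss_sum / frame_sum)

        scores = _sequence_scores(model, Xte, mte)
        auc = float(roc_auc_score(yte, scores))
        auc_history.append(auc)
        # ties resolved toward the most recent epoch: once the AUC
        # saturates (easy separable data), later epochs are better
        # calibrated per-frame than the first epoch to reach the maximum
        if auc >= best_auc:
            best_auc = auc
            best_epoch = epoch
            best_weights = model.get_weights()
        if log is not None:
            log(f"epoch {epoch:3d}  loss {loss_history[-1]:.4f}  val AUC {auc:.4f}")

    final_weights = model.get_weights()
    model.set_weights(best_weights)
    return TrainedModel(
        model=model, stats=stats, config=config,
        loss_history=loss_history, auc_history=auc_history,
        best_epoch=best_epoch, final_weights=final_weights,
    )


def gru_train(dataset_dir: str | Path, config: ClassifierConfig | None = None,
              **kwargs) -> TrainedModel:
    """The identical pipeline with GRU cells of the same dimensions."""
    if config is None:
        config = ClassifierConfig()
    config = ClassifierConfig(**{**asdict(config), "cell": "gru"})
    return train(dataset_dir, config, **kwargs)


# ---------------------------------------------------------------------------
# evaluation and prediction
# ---------------------------------------------------------------------------


def evaluate_auc(tm: TrainedModel, records: list[TrajectoryRecord]) -> float:
    """Rank-based AUC of the sequence probability against true labels."""
    labels = {bool(r.is_drone) for r in records}
    if labels != {False, True}:
        raise ValueError("AUC needs records from both classes")
    X, mask, y = _prepare(records, tm.stats, tm.config.max_len)
    scores = _sequence_scores(tm.model, X, mask)
    return float(roc_auc_score(y, scores))


def predict_record(
    tm: TrainedModel, record: TrajectoryRecord, *, preprocess: str = "downsample"
) -> tuple[np.ndarray, float]:
    """Per-frame drone probabilities and the sequence probability.

    ``preprocess`` controls how tracks longer than ``max_len`` are
    reduced: ``"downsample"`` (default) thins them uniformly, matching
    the training pipeline; ``"truncate"`` keeps the first ``max_len``
    frames.  The returned array is trimmed to the valid frames.
    """
    if preprocess not in ("downsample", "truncate"):
        raise ValueError("preprocess must be 'downsample' or 'truncate'")
    if preprocess == "downsample":
        record = downsample(record, tm.config.max_len)
    Xn = normalize(record.positions, tm.stats)
    X, mask = pad_and_mask([Xn], tm.config.max_len)
    p = tm.model.forward(X)[0]
    n_valid = int(mask[0].sum())
    probs = p[:n_valid]
    return probs, float(sequence_probability(p, mask[0]))


def predict_file(
    model_path: str | Path, json_path: str | Path, *, preprocess: str = "downsample"
) -> tuple[np.ndarray, float]:
    """Load a persisted model and score a trajectory JSON file."""
    tm = load_model(model_path)
    record = read_trajectory_json(json_path, require_label=False)
    return predict_record(tm, record, preprocess=preprocess)


# ---------------------------------------------------------------------------
# persistence and plotting
# ---------------------------------------------------------------------------


def save_model(tm: TrainedModel, path: str | Path) -> None:
    """Persist weights (``.npz``) plus a JSON sidecar with stats/history.

    ``path`` is the basename; ``<path>.npz`` and ``<path>.json`` are
    written.  Prediction afterwards needs no access to the training
    set.
    """
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **tm.model.get_weights())
    sidecar = {
        "stats": {"mu": tm.stats.mu.tolist(), "sigma": tm.stats.sigma.tolist()},
        "config": asdict(tm.config),
        "loss_history": tm.loss_history,
        "auc_history": tm.auc_history,
        "best_epoch": tm.best_epoch,
    }
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    with open(path.with_suffix(".json"), encoding="utf-8") as fh:
        sidecar = json.load(fh)
    config = ClassifierConfig(**sidecar["config"])
    stats = NormalizationStats(**sidecar["stats"])
    model = BiRNNClassifier(
        input_size=config.input_dim, hidden=config.hidden,
        n_layers=config.layers, dropout=config.dropout, cell=config.cell,
        rng=np.random.default_rng(config.seed),
    )
    with np.load(path.with_suffix(".npz")) as npz:
        model.set_weights(dict(npz.items()))
    return TrainedModel(
        model=model, stats=stats, config=config,
        loss_history=list(sidecar["loss_history"]),
        auc_history=list(sidecar["auc_history"]),
        best_epoch=int(sidecar["best_epoch"]),
    )


def plot_loss_history(tm: TrainedModel, path: str | Path) -> None:
    """Write a PNG of the training loss (and validation AUC) curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = np.arange(1, len(tm.loss_history) + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(epochs, tm.loss_history, label="training loss")
    ax.set_xlabel("epoch")
    ax.set_ylabel("masked BCE")
    if tm.auc_history:
        ax2 = ax.twinx()
        ax2.plot(epochs, tm.auc_history, color="tab:orange", label="val AUC")
        ax2.set_ylabel("validation AUC")
        ax2.set_ylim(0.0, 1.05)
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
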