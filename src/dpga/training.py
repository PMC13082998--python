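"""Losses, metrics and the training/evaluation protocol.

Training is transductive: the whole patient graph participates in message
passing every epoch, while only training-node labels enter the
classification loss.  The objective is binary cross-entropy plus a
graph-Laplacian smoothness penalty on the position embeddings,
L_total = L_c + lambda * L_p.  Model selection keeps the parameters from
the epoch with the best validation accuracy; reported results average
test-set metrics over several runs with fresh splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .graph import DataSplit, PatientGraph, split_dataset
from .model import DPGAModel, LayerConfig

__all__ = [
    "TrainingConfig", "Metrics", "LossBreakdown",
    "classification_loss", "position_loss", "total_loss",
    "confusion_counts", "accuracy", "f1_score",
    "compute_metrics", "training_loss", "train", "evaluate_runs",
]


@dataclass
class TrainingConfig:
    lam: float = 1.0            # position-loss weight
    lr: float = 5e-4            # 0.0005 for the two smaller cohorts, 0.001 CHD
    epochs: int = 1000
    runs: int = 5
    optimizer: str = "adam"
    weight_decay: float = 5e-4
    patience: int | None = None  # early stopping on validation ACC; off by default
    seed: int = 0
    stratify: bool = True
    ratios: tuple = (0.6, 0.2, 0.2)

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class Metrics:
    acc: float
    f1: float
    precision: dict
    recall: dict
    confusion: dict   # XP, XN, EP, EN


@dataclass
class LossBreakdown:
    L_c: float
    L_p: float
    lam: float

    @property
    def L_total(self) -> float:
        return self.L_c + self.lam * self.L_p


# -- losses -------------------------------------------------------------------

def classification_loss(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Binary cross-entropy of predicted probabilities for the positive class."""
    y_hat = np.clip(np.asarray(y_hat, dtype=float), 1e-7, 1.0 - 1e-7)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError("probability and label vectors differ in length")
    return float(-np.mean(y * np.log(y_hat) + (1 - y) * np.log(1 - y_hat)))


def position_loss(P: np.ndarray, pairs: np.ndarray,
                  w: np.ndarray | None = None) -> float:
    """Laplacian smoothness: sum over unordered edges of w_ij ||p_i - p_j||^2."""
    P = np.asarray(P, dtype=float)
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    if len(pairs) == 0:
        return 0.0
    diff = P[pairs[:, 0]] - P[pairs[:, 1]]
    sq = (diff ** 2).sum(axis=1)
    if w is None:
        return float(sq.sum())
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("edge weights must be nonnegative")
    return float((w * sq).sum())


def total_loss(L_c: float, L_p: float, lam: float) -> float:
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return L_c + lam * L_p


# -- metrics ------------------------------------------------------------------

def confusion_counts(predictions: np.ndarray, labels: np.ndarray,
                     positive: int = 1) -> dict:
    """True/false positives and negatives (XP, XN, EP, EN)."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("prediction and label vectors differ in length")
    return {
        "XP": int(((p == positive) & (y == positive)).sum()),
        "XN": int(((p != positive) & (y != positive)).sum()),
        "EP": int(((p == positive) & (y != positive)).sum()),
        "EN": int(((p != positive) & (y == positive)).sum()),
    }


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    if len(np.asarray(labels)) == 0:
        raise ValueError("cannot compute accuracy on an empty set")
    c = confusion_counts(predictions, labels)
    return (c["XP"] + c["XN"]) / (c["XP"] + c["XN"] + c["EP"] + c["EN"])


def _prf(predictions, labels, positive) -> tuple:
    c = confusion_counts(predictions, labels, positive=positive)
    pre = c["XP"] / (c["XP"] + c["EP"]) if (c["XP"] + c["EP"]) else 0.0
    rec = c["XP"] / (c["XP"] + c["EN"]) if (c["XP"] + c["EN"]) else 0.0
    f1 = 2 * pre * rec / (pre + rec) if (pre + rec) else 0.0
    return pre, rec, f1


def f1_score(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Macro-averaged F1 = mean over classes of 2*Pre*Rec / (Pre + Rec)."""
    classes = np.unique(np.asarray(labels))
    if classes.size == 0:
        raise ValueError("cannot compute F1 on an empty set")
    return float(np.mean([_prf(predictions, labels, c)[2] for c in classes]))


def compute_metrics(predictions: np.ndarray, labels: np.ndarray) -> Metrics:
    classes = np.unique(np.asarray(labels))
    precision, recall = {}, {}
    for c in classes:
        pre, rec, _ = _prf(predictions, labels, c)
        precision[int(c)], recall[int(c)] = pre, rec
    return Metrics(acc=accuracy(predictions, labels),
                   f1=f1_score(predictions, labels),
                   precision=precision, recall=recall,
                   confusion=confusion_counts(predictions, labels))


# -- training -----------------------------------------------------------------

def training_loss(model: DPGAModel, train_idx: np.ndarray, lam: float,
                  training: bool = False,
                  rng: np.random.Generator | None = None) -> tuple:
    """Differentiable L_total = L_c(train nodes) + lam * L_p(all edges)."""
    logits, _, _ = model.forward(training=training, rng=rng)
    log_probs = ad.log_softmax(logits).take_rows(train_idx)
    y = model.graph.cohort.y[train_idx].astype(float)
    onehot = np.stack([1.0 - y, y], axis=1)
    L_c = -(log_probs * onehot).sum(axis=1).mean()
    pairs = model.graph.pairs
    if len(pairs):
        diff = model.params.P0.take_rows(pairs[:, 0]) - \
            model.params.P0.take_rows(pairs[:, 1])
        L_p = diff.square().sum()
    else:
        L_p = Tensor(np.array(0.0))
    return L_c + lam * L_p, L_c, L_p


@dataclass
class TrainResult:
    model: DPGAModel
    split: DataSplit
    history: list = field(default_factory=list)
    best_epoch: int = -1

    def metrics_on(self, idx: np.ndarray) -> Metrics:
        proba = self.model.predict_proba()
        preds = proba.argmax(axis=1)
        return compute_metrics(preds[idx], self.model.graph.cohort.y[idx])


def train(graph: PatientGraph, split: DataSplit, model_config: LayerConfig,
          train_config: TrainingConfig, seed: int = 0,
          potential_features=None, mask_override=None) -> TrainResult:
    """Train one model on one split; deterministic given ``seed``."""
    model = DPGAModel(graph, model_config,
                      potential_features=potential_features, seed=seed)
    params = model.params.parameters()
    opt = Adam(params, lr=train_config.lr,
               weight_decay=train_config.weight_decay)
    drop_rng = np.random.default_rng((seed * 1_000_003 + 17) % (2 ** 31))
    if mask_override is not None:
        model.mask = mask_override

    best_val, best_snap, best_epoch = -np.inf, model.params.snapshot(), -1
    history = []
    stale = 0
    for epoch in range(train_config.epochs):
        loss, L_c, L_p = training_loss(model, split.train, train_config.lam,
                                       training=True, rng=drop_rng)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: loss={loss.data}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        proba = model.predict_proba()
        preds = proba.argmax(axis=1)
        y = graph.cohort.y
        val_acc = accuracy(preds[split.val], y[split.val])
        history.append({
            "epoch": epoch,
            "L_c": float(L_c.data), "L_p": float(L_p.data),
            "L_total": float(loss.data),
            "train_acc": accuracy(preds[split.train], y[split.train]),
            "val_acc": val_acc,
            "val_f1": f1_score(preds[split.val], y[split.val]),
        })
        if val_acc > best_val:
            best_val, best_snap, best_epoch = val_acc, model.params.snapshot(), epoch
            stale = 0
        else:
            stale += 1
            if train_config.patience is not None and stale >= train_config.patience:
                break
    model.params.restore(best_snap)
    return TrainResult(model=model, split=split, history=history,
                       best_epoch=best_epoch)


@dataclass
class RunSummary:
    acc_mean: float
    acc_std: float
    f1_mean: float
    f1_std: float
    per_run: list
    single_run: bool = False

    def format_table(self) -> str:
        return (f"ACC {self.acc_mean:.4f} ±{self.acc_std:.4f}\t"
                f"F1 {self.f1_mean:.4f} ±{self.f1_std:.4f}")


def evaluate_runs(graph: PatientGraph, model_config: LayerConfig,
                  train_config: TrainingConfig,
                  potential_features=None) -> RunSummary:
    """Repeat split+train+test; report mean and sample std over runs."""
    if train_config.runs < 1:
        raise ValueError("runs must be >= 1")
    per_run = []
    y = graph.cohort.y
    for r in range(train_config.runs):
        run_seed = (train_config.seed + 7919 * r) % (2 ** 31)
        split = split_dataset(graph.n_nodes, train_config.ratios,
                              seed=run_seed,
                              stratify_on=y if train_config.stratify else None)
        res = train(graph, split, model_config, train_config, seed=run_seed,
                    potential_features=potential_features)
        m = res.metrics_on(split.test)
        per_run.append({"seed": run_seed, "acc": m.acc, "f1": m.f1,
                        "best_epoch": res.best_epoch})
    accs = np.array([r["acc"] for r in per_run])
    f1s = np.array([r["f1"] for r in per_run])
    single = len(per_run) == 1
    return RunSummary(
        acc_mean=float(accs.mean()),
        acc_std=0.0 if single else float(accs.std(ddof=1)),
        f1_mean=float(f1s.mean()),
        f1_std=0.0 if single else float(f1s.std(ddof=1)),
        per_run=per_run, single_run=single)
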