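"""Scikit-learn-style estimator wrapping the DP-GA training protocol.

The classifier is transductive: ``fit`` takes a whole
:class:`~dpga.graph.PatientGraph` (labels live on the cohort), trains on
the designated training nodes with validation-based model selection, and
``predict`` scores any subset of nodes of that same graph.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .graph import PatientGraph, split_dataset
from .model import DPGAModel, LayerConfig, export_attention_tsv
from .training import TrainingConfig, train, evaluate_runs

__all__ = ["DPGAClassifier", "save_checkpoint", "load_checkpoint"]


class DPGAClassifier(ClassifierMixin, BaseEstimator):
    """Disease potential-driven graph attention classifier.

    Parameters mirror the layer and training configurations; fitted state
    carries a trailing underscore.  Because training is transductive the
    graph passed to :meth:`fit` is the population scored by
    :meth:`predict`.

    Examples
    --------
    >>> from dpga.simulate import SimulationConfig, generate_cohort
    >>> from dpga.graph import build_graph, split_dataset
    >>> sim = generate_cohort(SimulationConfig(n_case=30, n_control=30,
    ...     n_features=12, potential_features=(0, 1, 2), effect_size=0.4))
    >>> graph = build_graph(sim.cohort)
    >>> clf = DPGAClassifier(epochs=5, hid=8, heads=2).fit(graph)
    >>> clf.predict().shape
    (60,)
    """

    def __init__(self, hid: int = 64, heads: int = 4, drop: float = 0.3,
                 n_layers: int = 2, tau: float = 1.0, eps_mask: float = 0.1,
                 leaky_slope: float = 0.2,
                 renormalize_masked_attention: bool = False,
                 use_sim_diff_branch: bool = True,
                 lam: float = 1.0, lr: float = 5e-4, epochs: int = 1000,
                 weight_decay: float = 5e-4, patience: int | None = None,
                 ratios: tuple = (0.6, 0.2, 0.2), stratify: bool = True,
                 potential_features=None, seed: int = 0):
        self.hid = hid
        self.heads = heads
        self.drop = drop
        self.n_layers = n_layers
        self.tau = tau
        self.eps_mask = eps_mask
        self.leaky_slope = leaky_slope
        self.renormalize_masked_attention = renormalize_masked_attention
        self.use_sim_diff_branch = use_sim_diff_branch
        self.lam = lam
        self.lr = lr
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.patience = patience
        self.ratios = ratios
        self.stratify = stratify
        self.potential_features = potential_features
        self.seed = seed

    # -- config assembly ------------------------------------------------------

    def _layer_config(self) -> LayerConfig:
        return LayerConfig(
            hid=self.hid, heads=self.heads, drop=self.drop,
            n_layers=self.n_layers, tau=self.tau, eps_mask=self.eps_mask,
            leaky_slope=self.leaky_slope,
            renormalize_masked_attention=self.renormalize_masked_attention,
            use_sim_diff_branch=self.use_sim_diff_branch)

    def _training_config(self, runs: int = 1) -> TrainingConfig:
        return TrainingConfig(
            lam=self.lam, lr=self.lr, epochs=self.epochs, runs=runs,
            weight_decay=self.weight_decay, patience=self.patience,
            seed=self.seed, stratify=self.stratify, ratios=self.ratios)

    # -- sklearn surface ------------------------------------------------------

    def fit(self, graph: PatientGraph, y=None, split=None):
        """Train on one split of ``graph``; labels default to the cohort's."""
        if not isinstance(graph, PatientGraph):
            raise TypeError("fit expects a PatientGraph")
        labels = graph.cohort.y if y is None else np.asarray(y, dtype=np.int64)
        if labels.shape[0] != graph.n_nodes:
            raise ValueError("label vector length must equal node count")
        if split is None:
            split = split_dataset(graph.n_nodes, self.ratios, seed=self.seed,
                                  stratify_on=labels if self.stratify else None)
        result = train(graph, split, self._layer_config(),
                       self._training_config(), seed=self.seed,
                       potential_features=self.potential_features)
        self.graph_ = graph
        self.classes_ = np.unique(labels)
        self.model_ = result.model
        self.split_ = split
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        return self

    def predict_proba(self, indices=None) -> np.ndarray:
        self._check_fitted()
        proba = self.model_.predict_proba()
        return proba if indices is None else proba[np.asarray(indices)]

    def predict(self, indices=None) -> np.ndarray:
        return self.predict_proba(indices).argmax(axis=1)

    def score(self, indices=None, y=None) -> float:
        self._check_fitted()
        if indices is None:
            indices = self.split_.test
        indices = np.asarray(indices)
        if y is None:
            y = self.graph_.cohort.y[indices]
        preds = self.predict(indices)
        return float((preds == np.asarray(y)).mean())

    def evaluate(self, graph: PatientGraph, runs: int = 5):
        """Protocol evaluation: fresh split + retrain per run, mean +/- std."""
        return evaluate_runs(graph, self._layer_config(),
                             self._training_config(runs=runs),
                             potential_features=self.potential_features)

    def export_attention(self, path, layer: int = 0, head: int = 0) -> None:
        self._check_fitted()
        export_attention_tsv(self.model_.attention_state(layer, head), path)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(clf: DPGAClassifier, path) -> None:
    """Single-file parameter bundle with config and seed."""
    clf._check_fitted()
    named = clf.model_.params.named_parameters()
    meta = {"params": clf.get_params(deep=False),
            "layer_config": asdict(clf.model_.config),
            "seed": clf.seed}
    meta["params"] = {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in meta["params"].items()}
    arrays = {k: v.data for k, v in named.items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, graph: PatientGraph) -> DPGAClassifier:
    """Rebuild a fitted classifier from a checkpoint and its graph."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    params = meta["params"]
    if isinstance(params.get("ratios"), list):
        params["ratios"] = tuple(params["ratios"])
    if isinstance(params.get("potential_features"), list):
        params["potential_features"] = tuple(params["potential_features"])
    clf = DPGAClassifier(**params)
    model = DPGAModel(graph, clf._layer_config(),
                      potential_features=clf.potential_features,
                      seed=meta["seed"])
    for k, t in model.params.named_parameters().items():
        t.data = np.asarray(arrays[k], dtype=float)
    clf.graph_ = graph
    clf.classes_ = np.unique(graph.cohort.y)
    clf.model_ = model
    clf.split_ = split_dataset(graph.n_nodes, clf.ratios, seed=clf.seed,
                               stratify_on=graph.cohort.y if clf.stratify
                               else None)
    clf.history_ = []
    clf.best_epoch_ = -1
    return clf
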