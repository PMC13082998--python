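"""Synthetic case/control cohorts with planted comorbidity structure.

The generator emulates the statistical shape of hospital case/control
diagnosis data: balanced binary labels, a binary disease-indicator matrix,
blocks of co-occurring diseases (comorbidity modules), and a severity
gradient — a set of "potential" disease features whose prevalence is
elevated in cases — that couples the feature matrix to the outcome.

Co-occurrence within a module is induced by a shared latent Bernoulli
switch: when the switch fires for a patient, every feature of the module
is activated with high probability, otherwise at its baseline prevalence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .graph import CohortTable, DiseaseVocabulary, PatientGraph, build_graph

__all__ = [
    "DiseaseModule", "SimulationConfig", "SyntheticCohort",
    "generate_cohort", "generate_contingency_fixtures", "generate_toy_graph",
    "copd_shaped_config", "dm_shaped_config", "chd_shaped_config",
]


@dataclass(frozen=True)
class DiseaseModule:
    """A block of disease features that co-occur through a latent switch."""

    features: tuple                  # feature indices in the block
    switch_prob_case: float = 0.3    # P(latent switch fires | case)
    switch_prob_control: float = 0.3
    within_prob: float = 0.8         # P(feature active | switch fired)


@dataclass
class SimulationConfig:
    n_case: int = 315
    n_control: int = 315
    n_features: int = 355            # COPD-shaped default
    baseline_prevalence: float = 0.08
    modules: list = field(default_factory=list)
    potential_features: tuple = ()
    effect_size: float = 0.0         # added case prevalence on potential features
    seed: int = 0

    def __post_init__(self):
        if self.n_case + self.n_control < 4:
            raise ValueError("need at least 4 patients")
        if self.n_features < 2:
            raise ValueError("need at least 2 features")
        if not 0.0 <= self.baseline_prevalence <= 1.0:
            raise ValueError("baseline_prevalence must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for m in self.modules:
            if min(m.features) < 0 or max(m.features) >= self.n_features:
                raise ValueError("module feature index out of range")
        for q in self.potential_features:
            if not 0 <= q < self.n_features:
                raise ValueError("potential feature index out of range")


@dataclass
class SyntheticCohort:
    cohort: CohortTable
    config: SimulationConfig
    prevalence_case: np.ndarray      # per-feature generating prevalence, cases
    prevalence_control: np.ndarray

    @property
    def truth(self) -> dict:
        return {
            "modules": [list(m.features) for m in self.config.modules],
            "potential_features": list(self.config.potential_features),
            "effect_size": self.config.effect_size,
            "prevalence_case": self.prevalence_case.tolist(),
            "prevalence_control": self.prevalence_control.tolist(),
            "seed": self.config.seed,
        }

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=2)


def _group_matrix(rng: np.random.Generator, n: int, config: SimulationConfig,
                  is_case: bool) -> tuple:
    F = config.n_features
    prev = np.full(F, config.baseline_prevalence)
    if is_case and config.effect_size > 0:
        idx = np.asarray(config.potential_features, dtype=np.intp)
        prev[idx] = prev[idx] + config.effect_size
        if (prev > 1).any():
            warnings.warn("raised prevalence exceeded 1; clipped")
            prev = np.clip(prev, 0.0, 1.0)
    X = (rng.random((n, F)) < prev).astype(np.int8)
    for mod in config.modules:
        p_switch = mod.switch_prob_case if is_case else mod.switch_prob_control
        fired = rng.random(n) < p_switch
        idx = np.asarray(mod.features, dtype=np.intp)
        activate = rng.random((n, len(idx))) < mod.within_prob
        X[np.ix_(fired, idx)] |= activate[fired]
    return X, prev


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort; bit-identical regeneration from (config, seed)."""
    rng = np.random.default_rng(config.seed)
    X_case, prev_case = _group_matrix(rng, config.n_case, config, True)
    X_ctrl, prev_ctrl = _group_matrix(rng, config.n_control, config, False)
    X = np.concatenate([X_case, X_ctrl], axis=0)
    y = np.concatenate([np.ones(config.n_case, dtype=np.int64),
                        np.zeros(config.n_control, dtype=np.int64)])
    vocab = DiseaseVocabulary(tuple(f"D{q:03d}" for q in range(config.n_features)))
    ids = [f"case{i}" for i in range(config.n_case)] + \
          [f"ctrl{i}" for i in range(config.n_control)]
    cohort = CohortTable(X=X, y=y, vocabulary=vocab, patient_ids=ids)
    return SyntheticCohort(cohort=cohort, config=config,
                           prevalence_case=prev_case,
                           prevalence_control=prev_ctrl)


def generate_contingency_fixtures(n_tables: int, seed: int = 0,
                                  max_z: int = 40) -> list:
    """Random 2x2 tables with all margins >= 1.

    Returns dicts with the table and the (N_uv, Z, Y_u, Y_v) quadruple:
    N_uv patients carry both diseases, Y_u / Y_v carry each, Z in total.
    """
    if n_tables < 1:
        raise ValueError("n_tables must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_tables:
        Z = int(rng.integers(4, max_z + 1))
        u = rng.random(Z) < rng.uniform(0.2, 0.8)
        v = rng.random(Z) < rng.uniform(0.2, 0.8)
        Y_u, Y_v = int(u.sum()), int(v.sum())
        if not (0 < Y_u < Z and 0 < Y_v < Z):
            continue
        n11 = int((u & v).sum())
        table = np.array([[n11, Y_u - n11],
                          [Y_v - n11, Z - Y_u - Y_v + n11]], dtype=np.int64)
        out.append({"table": table, "N_uv": n11, "Z": Z, "Y_u": Y_u, "Y_v": Y_v})
    return out


def generate_toy_graph(n_nodes: int, feature_dim: int = 6,
                       seed: int = 0) -> PatientGraph:
    """Small random connected co-diagnosis graph for attention oracles."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    vocab = DiseaseVocabulary(tuple(f"D{q:03d}" for q in range(feature_dim)))
    for _ in range(200):
        X = (rng.random((n_nodes, feature_dim)) < 0.5).astype(np.int8)
        cohort = CohortTable(X=X, y=rng.integers(0, 2, n_nodes), vocabulary=vocab)
        try:
            g = build_graph(cohort, min_shared=1)
        except ValueError:
            continue
        if _connected(g.adjacency):
            return g
    # fall back: add a spanning chain of shared codes
    X[:, 0] = 1
    cohort = CohortTable(X=X, y=rng.integers(0, 2, n_nodes), vocabulary=vocab)
    return build_graph(cohort, min_shared=1)


def _connected(A: np.ndarray) -> bool:
    n = A.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(A[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    return bool(seen.all())


# -- Table-1-shaped presets ---------------------------------------------------

def _preset(n_per_group: int, F: int, seed: int) -> SimulationConfig:
    n_mod = 4
    block = max(3, F // 40)
    rng = np.random.default_rng(seed + 1_000_003)
    starts = rng.choice(F - block, size=n_mod, replace=False)
    modules = [DiseaseModule(features=tuple(range(int(s), int(s) + block)),
                             switch_prob_case=0.35, switch_prob_control=0.25)
               for s in starts]
    pot = tuple(int(q) for q in rng.choice(F, size=max(8, F // 25), replace=False))
    return SimulationConfig(n_case=n_per_group, n_control=n_per_group,
                            n_features=F, modules=modules,
                            potential_features=pot, effect_size=0.25, seed=seed)


def copd_shaped_config(seed: int = 0) -> SimulationConfig:
    """630 patients x 355 disease features, balanced case/control."""
    return _preset(315, 355, seed)


def dm_shaped_config(seed: int = 0) -> SimulationConfig:
    """1,024 patients x 435 disease features, balanced case/control."""
    return _preset(512, 435, seed)


def chd_shaped_config(seed: int = 0) -> SimulationConfig:
    """1,668 patients x 500 disease features, balanced case/control."""
    return _preset(834, 500, seed)
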