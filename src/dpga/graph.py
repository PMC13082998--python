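"""Patient graphs from diagnosis records.

Patients become nodes; two patients are connected when their diagnosis
histories share at least ``min_shared`` disease codes.  Node features are
binary disease-history indicators over a fixed vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DiseaseVocabulary", "PatientRecord", "CohortTable", "PatientGraph",
    "DataSplit", "encode_features", "build_graph", "split_dataset",
    "read_cohort_csv", "write_cohort_csv", "read_vocabulary",
    "write_edge_list", "write_feature_matrix",
]


@dataclass(frozen=True)
class DiseaseVocabulary:
    """Ordered, unique disease codes; column order of the feature matrix."""

    codes: tuple

    def __post_init__(self):
        codes = tuple(self.codes)
        if len(set(codes)) != len(codes):
            raise ValueError("vocabulary codes must be unique")
        object.__setattr__(self, "codes", codes)

    @property
    def size(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown disease code: {code!r}") from None

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    diagnoses: frozenset
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        object.__setattr__(self, "diagnoses", frozenset(self.diagnoses))


@dataclass
class CohortTable:
    """Binary feature matrix X (patients x diseases), labels y, vocabulary."""

    X: np.ndarray
    y: np.ndarray
    vocabulary: DiseaseVocabulary
    patient_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("X must be binary")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != self.vocabulary.size:
            raise ValueError("X column count does not match vocabulary size")
        if not self.patient_ids:
            self.patient_ids = [f"P{i}" for i in range(self.X.shape[0])]

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class PatientGraph:
    """Co-diagnosis patient graph: cohort + symmetric binary adjacency."""

    cohort: CohortTable
    adjacency: np.ndarray          # Z x Z, {0,1}, zero diagonal
    pairs: np.ndarray              # (n_pairs, 2) unordered i < j

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(A).any():
            raise ValueError("adjacency must have zero diagonal")
        self.adjacency = A.astype(np.int8)
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def directed_edges(self) -> tuple:
        """(receiver, sender) index arrays: each unordered pair both ways."""
        if len(self.pairs) == 0:
            e = np.zeros(0, dtype=np.int64)
            return e, e.copy()
        i = np.concatenate([self.pairs[:, 0], self.pairs[:, 1]])
        j = np.concatenate([self.pairs[:, 1], self.pairs[:, 0]])
        return i, j

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)


@dataclass(frozen=True)
class DataSplit:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    ratios: tuple
    seed: int

    def __post_init__(self):
        for name in ("train", "val", "test"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=np.int64))
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split index sets overlap")


def encode_features(records: list, vocabulary: DiseaseVocabulary) -> CohortTable:
    """Indicator-encode diagnosis histories: X[i, q] = 1 iff record i has code q."""
    if not records:
        raise ValueError("no patient records supplied")
    code_to_col = {c: q for q, c in enumerate(vocabulary.codes)}
    Z, F = len(records), vocabulary.size
    X = np.zeros((Z, F), dtype=np.int8)
    y = np.zeros(Z, dtype=np.int64)
    ids = []
    for i, rec in enumerate(records):
        for code in rec.diagnoses:
            if code not in code_to_col:
                raise KeyError(f"unknown disease code: {code!r}")
            X[i, code_to_col[code]] = 1
        y[i] = rec.label
        ids.append(rec.patient_id)
    return CohortTable(X=X, y=y, vocabulary=vocabulary, patient_ids=ids)


def build_graph(cohort: CohortTable, min_shared: int = 1) -> PatientGraph:
    """Connect patients sharing at least ``min_shared`` disease codes."""
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if cohort.n_patients < 2:
        raise ValueError("need at least 2 patients to build a graph")
    X = cohort.X.astype(np.int64)
    shared = X @ X.T
    np.fill_diagonal(shared, 0)
    A = (shared >= min_shared).astype(np.int8)
    iu, ju = np.triu_indices(cohort.n_patients, k=1)
    keep = A[iu, ju] == 1
    pairs = np.stack([iu[keep], ju[keep]], axis=1)
    return PatientGraph(cohort=cohort, adjacency=A, pairs=pairs)


def shared_counts(cohort: CohortTable) -> np.ndarray:
    """Number of co-diagnosed codes for every patient pair (zero diagonal)."""
    X = cohort.X.astype(np.int64)
    S = X @ X.T
    np.fill_diagonal(S, 0)
    return S


def split_dataset(Z: int, ratios=(0.6, 0.2, 0.2), seed: int = 0,
                  stratify_on: np.ndarray | None = None) -> DataSplit:
    """Train/val/test index split, stratified by label when possible.

    Sizes are floor(Z * ratio) per part with the remainder assigned to train;
    within a stratum the same rule applies, so balanced cohorts yield
    class-balanced partitions.
    """
    ratios = np.asarray(ratios, dtype=float)
    if (ratios <= 0).any():
        raise ValueError("ratios must be positive")
    ratios = ratios / ratios.sum()
    rng = np.random.default_rng(seed)

    def _allocate(idx: np.ndarray):
        n = len(idx)
        perm = idx[rng.permutation(n)]
        n_val = int(np.floor(n * ratios[1]))
        n_test = int(np.floor(n * ratios[2]))
        n_train = n - n_val - n_test
        return (perm[:n_train], perm[n_train:n_train + n_val],
                perm[n_train + n_val:])

    if stratify_on is not None:
        stratify_on = np.asarray(stratify_on)
        if stratify_on.shape[0] != Z:
            raise ValueError("stratify_on length must equal Z")
        classes, counts = np.unique(stratify_on, return_counts=True)
        if counts.min() < 3:
            warnings.warn("a label class has fewer members than split parts; "
                          "falling back to unstratified split")
            stratify_on = None
    if stratify_on is None:
        train, val, test = _allocate(np.arange(Z))
    else:
        parts = [_allocate(np.flatnonzero(stratify_on == c)) for c in classes]
        train = np.sort(np.concatenate([p[0] for p in parts]))
        val = np.sort(np.concatenate([p[1] for p in parts]))
        test = np.sort(np.concatenate([p[2] for p in parts]))
    return DataSplit(train=train, val=val, test=test,
                     ratios=tuple(ratios), seed=seed)


# -- text I/O -----------------------------------------------------------------

def read_vocabulary(path) -> DiseaseVocabulary:
    codes = [line.strip() for line in Path(path).read_text().splitlines()
             if line.strip()]
    return DiseaseVocabulary(tuple(codes))


def read_cohort_csv(path, vocabulary: DiseaseVocabulary | None = None) -> CohortTable:
    """Read a cohort CSV with columns patient_id, label, diagnoses.

    ``diagnoses`` is a semicolon-separated code list.  Without an explicit
    vocabulary, one is built from the codes present, in sorted order.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "diagnoses": str})
    required = {"patient_id", "label", "diagnoses"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort file must have columns {sorted(required)}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        diag = row.diagnoses
        codes = [] if (not isinstance(diag, str) or not diag.strip()) else \
            [c.strip() for c in diag.split(";") if c.strip()]
        try:
            records.append(PatientRecord(patient_id=row.patient_id,
                                         diagnoses=frozenset(codes),
                                         label=int(row.label)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed cohort row at line {lineno}: {exc}") from exc
    if vocabulary is None:
        all_codes = sorted(set().union(*(r.diagnoses for r in records)) or set())
        vocabulary = DiseaseVocabulary(tuple(all_codes))
    return encode_features(records, vocabulary)


def write_cohort_csv(cohort: CohortTable, path) -> None:
    rows = []
    for i in range(cohort.n_patients):
        codes = [cohort.vocabulary.codes[q]
                 for q in np.flatnonzero(cohort.X[i])]
        rows.append({"patient_id": cohort.patient_ids[i],
                     "label": int(cohort.y[i]),
                     "diagnoses": ";".join(codes)})
    pd.DataFrame(rows, columns=["patient_id", "label", "diagnoses"]) \
        .to_csv(path, index=False)


def write_feature_matrix(cohort: CohortTable, path) -> None:
    """Dense delimited dump of X with code headers, for inspection."""
    pd.DataFrame(cohort.X, index=cohort.patient_ids,
                 columns=list(cohort.vocabulary.codes)) \
        .to_csv(path, index_label="patient_id")


def write_edge_list(graph: PatientGraph, path) -> None:
    """Edge list TSV: node i, node j, number of shared codes."""
    S = shared_counts(graph.cohort)
    with open(path, "w") as fh:
        fh.write("i\tj\tshared_count\n")
        for i, j in graph.pairs:
            fh.write(f"{i}\t{j}\t{S[i, j]}\n")
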