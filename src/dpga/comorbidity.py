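"""Disease-disease comorbidity networks scored by the phi coefficient.

For diseases u and v in a cohort of Z patients, with prevalences Y_u and
Y_v (patient counts) and co-occurrence count N_uv, the phi coefficient is

    phi_uv = (N_uv * Z - Y_u * Y_v)
             / sqrt(Y_u * Y_v * (Z - Y_u) * (Z - Y_v)),

i.e. the Pearson correlation of the two binary indicator columns.  Edge
significance uses the t statistic of a correlation coefficient with Z - 2
degrees of freedom, t = phi * sqrt((Z - 2) / (1 - phi^2)).  Networks keep
pairs passing both a co-occurrence count and a t threshold; endpoint
degrees are computed on the surviving network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph import CohortTable

__all__ = [
    "DiseasePrevalence", "ComorbidityEdge", "ComorbidityNetwork",
    "prevalence", "phi_coefficient", "t_value",
    "build_comorbidity_network", "describe_groups",
]

TABLE_COLUMNS = ["V1", "V2", "V1 degree", "V2 degree", "Phi", "t-value",
                 "Number"]


@dataclass
class DiseasePrevalence:
    counts: np.ndarray      # Y_u per disease
    n_patients: int         # Z
    codes: tuple

    def __post_init__(self):
        if ((self.counts < 0) | (self.counts > self.n_patients)).any():
            raise ValueError("prevalence counts must lie in [0, Z]")


@dataclass
class ComorbidityEdge:
    u: str
    v: str
    n_uv: int
    phi: float
    t: float
    degree_u: int = 0
    degree_v: int = 0


@dataclass
class ComorbidityNetwork:
    prevalence: DiseasePrevalence
    edges: list = field(default_factory=list)
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [{"V1": e.u, "V2": e.v, "V1 degree": e.degree_u,
                 "V2 degree": e.degree_v, "Phi": e.phi, "t-value": e.t,
                 "Number": e.n_uv} for e in self.edges]
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        Z = self.prevalence.n_patients
        for code, cnt in zip(self.prevalence.codes, self.prevalence.counts):
            if cnt > 0:
                G.add_node(code, prevalence=int(cnt),
                           rate=float(cnt) / Z if Z else 0.0)
        for e in self.edges:
            G.add_edge(e.u, e.v, phi=float(e.phi), t=float(e.t),
                       number=int(e.n_uv))
        return G

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def prevalence(cohort: CohortTable) -> DiseasePrevalence:
    if cohort.n_patients == 0:
        raise ValueError("empty cohort")
    return DiseasePrevalence(counts=cohort.X.sum(axis=0).astype(np.int64),
                             n_patients=cohort.n_patients,
                             codes=cohort.vocabulary.codes)


def phi_coefficient(n_uv: int, z: int, y_u: int, y_v: int) -> float:
    """Phi for a disease pair; NaN when a margin is degenerate (Y in {0, Z})."""
    if not (0 < y_u < z and 0 < y_v < z):
        return math.nan
    num = n_uv * z - y_u * y_v
    den = math.sqrt(float(y_u) * y_v * (z - y_u) * (z - y_v))
    return num / den


def t_value(phi: float, z: int) -> float:
    """t statistic of a correlation coefficient, Z - 2 degrees of freedom."""
    if z <= 2:
        raise ValueError("need more than 2 patients for a t value")
    if math.isnan(phi):
        return math.nan
    if abs(phi) >= 1.0:
        return math.copysign(math.inf, phi)
    return phi * math.sqrt((z - 2) / (1.0 - phi * phi))


def build_comorbidity_network(cohort: CohortTable, min_t: float = 1.96,
                              min_pair_count: int = 5,
                              group: str = "") -> ComorbidityNetwork:
    """Threshold all disease pairs on co-occurrence count and t value."""
    if min_t < 0 or min_pair_count < 0:
        raise ValueError("thresholds must be >= 0")
    prev = prevalence(cohort)
    X = cohort.X.astype(np.int64)
    Z = cohort.n_patients
    co = X.T @ X                       # pairwise co-occurrence counts
    Y = prev.counts
    edges = []
    F = cohort.n_features
    iu, ju = np.triu_indices(F, k=1)
    for u, v in zip(iu, ju):
        n_uv = int(co[u, v])
        if n_uv < min_pair_count:
            continue
        phi = phi_coefficient(n_uv, Z, int(Y[u]), int(Y[v]))
        if math.isnan(phi):
            continue
        t = t_value(phi, Z)
        if t >= min_t:                 # keeps +inf (perfect co-occurrence)
            edges.append(ComorbidityEdge(u=cohort.vocabulary.codes[u],
                                         v=cohort.vocabulary.codes[v],
                                         n_uv=n_uv, phi=phi, t=t))
    deg: dict = {}
    for e in edges:
        deg[e.u] = deg.get(e.u, 0) + 1
        deg[e.v] = deg.get(e.v, 0) + 1
    for e in edges:
        e.degree_u, e.degree_v = deg[e.u], deg[e.v]
    return ComorbidityNetwork(prevalence=prev, edges=edges, group=group)


def describe_groups(case: CohortTable, control: CohortTable,
                    min_t: float = 1.96, min_pair_count: int = 5) -> dict:
    """Case/control network pair plus merged tables in the standard layout."""
    if case.vocabulary.codes != control.vocabulary.codes:
        raise ValueError("case and control cohorts use different vocabularies")
    nets = {
        "case": build_comorbidity_network(case, min_t, min_pair_count, "case"),
        "control": build_comorbidity_network(control, min_t, min_pair_count,
                                             "control"),
    }
    tables = {k: v.to_frame() for k, v in nets.items()}
    parts = [t.assign(group=k) for k, t in tables.items() if len(t)]
    if parts:
        merged = pd.concat(parts, ignore_index=True)[["group"] + TABLE_COLUMNS]
    else:
        merged = pd.DataFrame(columns=["group"] + TABLE_COLUMNS)
    return {"networks": nets, "tables": tables, "merged": merged}
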