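"""Disease potential-driven graph attention (DP-GA) layers.

One layer combines three mechanisms on a patient co-diagnosis graph:

* **Fusion attention** — a feature-based attention score (projected disease
  features through LeakyReLU and two shared attention vectors) plus a
  structural score from learnable per-node position embeddings, summed
  into a fused per-edge score.
* **Difference perception** — a Bregman divergence (squared-Euclidean
  generator by default) between node pairs in feature and position space,
  mixed by a trainable weight in [0, 1]; the divergence both lowers the
  fused score and drives a parallel similarity-difference message-passing
  branch built from a relation matrix exp((C - beta*O) / tau).
* **Potential-masked attention** — a per-patient disease potential
  (sigmoid of the summed potential-feature indicators of the raw binary
  matrix) defines a per-edge mask: 1 when the receiving node's potential
  strictly exceeds the sender's, a small epsilon otherwise.  The mask
  multiplies the softmax numerator only, so masked rows deliberately sum
  to less than one unless renormalisation is switched on.

Every operation exists both as a standalone function on edge arrays
(checked against per-edge loop oracles) and composed inside
:class:`DPGAModel`'s forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import PatientGraph

__all__ = [
    "LayerConfig", "ModelParams", "AttentionState", "PotentialVector",
    "base_attention", "structural_attention", "fuse_attention",
    "bregman_divergence", "relation_scores", "aggregate_messages",
    "update_nodes", "adjust_attention", "disease_potential", "build_mask",
    "potential_attention", "aggregate_with_attention",
    "DPGAModel", "laplacian_position_init",
]


@dataclass
class LayerConfig:
    """Architecture hyperparameters of the DP-GA stack."""

    hid: int = 64
    heads: int = 4
    drop: float = 0.3
    n_layers: int = 2
    tau: float = 1.0
    eps_mask: float = 0.1
    leaky_slope: float = 0.2
    renormalize_masked_attention: bool = False
    use_sim_diff_branch: bool = True
    n_classes: int = 2

    def __post_init__(self):
        if not 0.0 <= self.drop < 1.0:
            raise ValueError("drop must be in [0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 < self.eps_mask <= 1.0:
            raise ValueError("eps_mask must be in (0, 1]")
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.hid % self.heads != 0:
            raise ValueError("hid must be divisible by heads")


@dataclass
class PotentialVector:
    """Per-patient disease potential: raw indicator sum and its sigmoid."""

    raw_sum: np.ndarray
    p: np.ndarray
    feature_set: np.ndarray


@dataclass
class AttentionState:
    """Per-edge diagnostics of one layer/head, for inspection and export."""

    edge_i: np.ndarray
    edge_j: np.ndarray
    e_base: np.ndarray
    e_pos: np.ndarray
    e_fusion: np.ndarray
    d: np.ndarray
    e_adjust: np.ndarray
    m: np.ndarray
    alpha: np.ndarray


# ---------------------------------------------------------------------------
# Standalone layer operations.  Arguments may be Tensors or plain arrays; plain
# arrays are treated as constants.  ``edge_i`` is the receiving node of each
# directed edge, ``edge_j`` the sending neighbour.
# ---------------------------------------------------------------------------

def base_attention(H, W, a_src, a_dst, edge_i, edge_j,
                   leaky_slope: float = 0.2) -> Tensor:
    """Feature attention: a_src . LReLU(W h_i) + a_dst . LReLU(W h_j)."""
    H, W = Tensor._lift(H), Tensor._lift(W)
    a_src, a_dst = Tensor._lift(a_src), Tensor._lift(a_dst)
    if H.shape[1] != W.shape[0]:
        raise ValueError(f"H has {H.shape[1]} columns but W expects {W.shape[0]}")
    L = ad.leaky_relu(H @ W, leaky_slope)
    if L.shape[1] != a_src.shape[0] or L.shape[1] != a_dst.shape[0]:
        raise ValueError("attention vector length must match projected width")
    score_src = (L * a_src).sum(axis=1)
    score_dst = (L * a_dst).sum(axis=1)
    return score_src.take_rows(edge_i) + score_dst.take_rows(edge_j)


def structural_attention(S, a_s, edge_i, edge_j) -> Tensor:
    """Structural attention: (s_i * a_s) . (s_j * a_s)."""
    S, a_s = Tensor._lift(S), Tensor._lift(a_s)
    if S.shape[1] != a_s.shape[0]:
        raise ValueError("positional attention vector length must match S width")
    T = S * a_s
    return ad.edge_dot(T, T, edge_i, edge_j)


def fuse_attention(e_base, e_pos) -> Tensor:
    return Tensor._lift(e_base) + Tensor._lift(e_pos)


def bregman_divergence(H, S, omega, edge_i, edge_j) -> Tensor:
    """omega * ||h_i - h_j||^2 + (1 - omega) * ||s_i - s_j||^2 per edge.

    Squared Euclidean distance is the Bregman divergence generated by the
    squared norm; it is symmetric, nonnegative and zero on the diagonal.
    """
    H, S, omega = Tensor._lift(H), Tensor._lift(S), Tensor._lift(omega)
    d_f = ad.edge_sqdist(H, edge_i, edge_j)
    d_s = ad.edge_sqdist(S, edge_i, edge_j)
    return omega * d_f + (1.0 - omega) * d_s


def relation_scores(C_scores, O_scores, beta, tau: float) -> Tensor:
    """Similarity-difference relation per edge: exp((C - beta*O) / tau)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    C, O = Tensor._lift(C_scores), Tensor._lift(O_scores)
    beta = Tensor._lift(beta)
    return ((C - beta * O) * (1.0 / tau)).exp()


def aggregate_messages(R, H, edge_i, edge_j, n_nodes: int) -> Tensor:
    """Normalised neighbour aggregation: M_i = sum_j R_ij / sum_k R_ik * H_j."""
    R, H = Tensor._lift(R), Tensor._lift(H)
    denom = ad.segment_sum(R, edge_i, n_nodes)
    # nodes with no edges never divide; guard keeps their (unused) entry finite
    denom_safe = denom + (denom.data == 0.0) * 1.0
    weights = R / denom_safe.take_rows(edge_i)
    return ad.edge_weighted_sum(weights, H, edge_i, edge_j, n_nodes)


def update_nodes(H, M, mu, degrees) -> Tensor:
    """Self-plus-message update: H_i' = mu * H_i / |N(i)| + M_i."""
    H, M, mu = Tensor._lift(H), Tensor._lift(M), Tensor._lift(mu)
    deg = np.maximum(np.asarray(degrees, dtype=float), 1.0)
    return mu * (H * (1.0 / deg)[:, None]) + M


def adjust_attention(e_fusion, d, delta) -> Tensor:
    """Difference-modulated score: e_fusion - delta * d."""
    return Tensor._lift(e_fusion) - Tensor._lift(delta) * Tensor._lift(d)


def disease_potential(X: np.ndarray, feature_set) -> PotentialVector:
    """Sigmoid of the per-patient sum of potential-feature indicators.

    Computed from the raw binary matrix, not hidden features, so it is
    identical at every layer.  Mask comparisons use the integer raw sums,
    which order identically to the sigmoid values but cannot saturate.
    """
    feature_set = np.asarray(feature_set, dtype=np.intp)
    if feature_set.size == 0:
        raise ValueError("potential feature set must be nonempty")
    raw = np.asarray(X)[:, feature_set].sum(axis=1).astype(float)
    return PotentialVector(raw_sum=raw, p=1.0 / (1.0 + np.exp(-raw)),
                           feature_set=feature_set)


def build_mask(potential: PotentialVector, edge_i, edge_j,
               eps_mask: float = 0.1) -> np.ndarray:
    """Directional mask: 1 where the receiver's potential strictly exceeds
    the sender's, eps_mask otherwise (ties included)."""
    if not 0.0 < eps_mask <= 1.0:
        raise ValueError("eps_mask must be in (0, 1]")
    r = potential.raw_sum
    return np.where(r[edge_i] > r[edge_j], 1.0, eps_mask)


def potential_attention(e_adjust, mask, edge_i, n_nodes: int,
                        renormalize: bool = False) -> Tensor:
    """Masked softmax: alpha_ij = exp(e_ij) * m_ij / sum_k exp(e_ik).

    The mask multiplies the numerator only, so rows containing suppressed
    edges sum to less than one; ``renormalize`` restores row sums of one.
    The softmax is shifted by the per-receiver max (constant), which leaves
    the result unchanged.
    """
    e = Tensor._lift(e_adjust)
    shift = ad.segment_max_detached(e.data, edge_i, n_nodes)
    ex = (e - shift[edge_i]).exp()
    denom = ad.segment_sum(ex, edge_i, n_nodes)
    alpha = ex * np.asarray(mask, dtype=float) / denom.take_rows(edge_i)
    if renormalize:
        row = ad.segment_sum(alpha, edge_i, n_nodes)
        row_safe = row + (row.data == 0.0) * 1.0
        alpha = alpha / row_safe.take_rows(edge_i)
    return alpha


def aggregate_with_attention(alpha, H, W, mu, edge_i, edge_j,
                             n_nodes: int) -> Tensor:
    """Attention aggregation: h_i' = mu * sum_j alpha_ij * W h_j.

    Isolated nodes (no incoming edges) pass mu * W h_i instead.
    """
    alpha, H, W, mu = (Tensor._lift(alpha), Tensor._lift(H),
                       Tensor._lift(W), Tensor._lift(mu))
    WH = H @ W
    out = ad.edge_weighted_sum(alpha, WH, edge_i, edge_j, n_nodes)
    iso = np.ones(n_nodes)
    iso[np.unique(np.asarray(edge_i, dtype=np.intp))] = 0.0
    if iso.any():
        out = out + iso[:, None] * WH
    return mu * out


# ---------------------------------------------------------------------------
# Parameters and the full model
# ---------------------------------------------------------------------------

def laplacian_position_init(adjacency: np.ndarray, k: int) -> np.ndarray:
    """Initial position embeddings: eigenvectors of the k smallest
    eigenvalues of the combinatorial Laplacian L = D - A (zero-padded
    when the graph has fewer than k nodes)."""
    A = np.asarray(adjacency, dtype=float)
    n = A.shape[0]
    L = np.diag(A.sum(axis=1)) - A
    _, vecs = np.linalg.eigh(L)
    P = np.zeros((n, k))
    m = min(k, n)
    P[:, :m] = vecs[:, :m]
    return P


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan = sum(shape) if len(shape) > 1 else shape[0] + 1
    s = np.sqrt(6.0 / fan)
    return rng.uniform(-s, s, size=shape)


@dataclass
class _LayerParams:
    W_h: Tensor
    W_p: Tensor
    W: list          # per head: shared projection for scoring and aggregation
    a_src: list      # per head
    a_dst: list      # per head
    a_s: list        # per head, positional attention vector
    sim_proj: Tensor
    beta: Tensor
    delta: Tensor
    mu_raw: Tensor    # softplus -> mu > 0
    omega_raw: Tensor  # sigmoid -> omega in [0, 1]

    @property
    def mu(self) -> Tensor:
        return ad.softplus(self.mu_raw)

    @property
    def omega(self) -> Tensor:
        return ad.sigmoid(self.omega_raw)


@dataclass
class ModelParams:
    """All learnable quantities of a DP-GA stack on one graph."""

    layers: list
    P0: Tensor        # per-node position embeddings, Z x hid
    W_out: Tensor
    b_out: Tensor
    config: LayerConfig = field(default=None)

    def parameters(self) -> list:
        out = []
        for lp in self.layers:
            out.extend([lp.W_h, lp.W_p, lp.sim_proj, lp.beta, lp.delta,
                        lp.mu_raw, lp.omega_raw])
            out.extend(lp.W)
            out.extend(lp.a_src)
            out.extend(lp.a_dst)
            out.extend(lp.a_s)
        out.extend([self.P0, self.W_out, self.b_out])
        return out

    def named_parameters(self) -> dict:
        out = {}
        for li, lp in enumerate(self.layers):
            out[f"layer{li}.W_h"] = lp.W_h
            out[f"layer{li}.W_p"] = lp.W_p
            out[f"layer{li}.sim_proj"] = lp.sim_proj
            out[f"layer{li}.beta"] = lp.beta
            out[f"layer{li}.delta"] = lp.delta
            out[f"layer{li}.mu_raw"] = lp.mu_raw
            out[f"layer{li}.omega_raw"] = lp.omega_raw
            for h in range(len(lp.W)):
                out[f"layer{li}.head{h}.W"] = lp.W[h]
                out[f"layer{li}.head{h}.a_src"] = lp.a_src[h]
                out[f"layer{li}.head{h}.a_dst"] = lp.a_dst[h]
                out[f"layer{li}.head{h}.a_s"] = lp.a_s[h]
        out["P0"] = self.P0
        out["W_out"] = self.W_out
        out["b_out"] = self.b_out
        return out

    def snapshot(self) -> list:
        return [p.data.copy() for p in self.parameters()]

    def restore(self, snap: list) -> None:
        for p, d in zip(self.parameters(), snap):
            p.data = d.copy()


def init_params(n_features: int, adjacency: np.ndarray, config: LayerConfig,
                seed: int = 0) -> ModelParams:
    rng = np.random.default_rng(seed)
    hid, heads = config.hid, config.heads
    d_sim = max(hid // heads, 1)
    layers = []
    d_in = n_features
    for layer in range(config.n_layers):
        last = layer == config.n_layers - 1
        d_head = hid if last else hid // heads
        lp = _LayerParams(
            W_h=Tensor.param(_glorot(rng, (d_in, hid))),
            W_p=Tensor.param(_glorot(rng, (hid, hid))),
            W=[Tensor.param(_glorot(rng, (hid, d_head))) for _ in range(heads)],
            a_src=[Tensor.param(_glorot(rng, (d_head,))) for _ in range(heads)],
            a_dst=[Tensor.param(_glorot(rng, (d_head,))) for _ in range(heads)],
            a_s=[Tensor.param(_glorot(rng, (hid,))) for _ in range(heads)],
            sim_proj=Tensor.param(_glorot(rng, (hid, d_sim))),
            beta=Tensor.param(np.array(1.0)),
            delta=Tensor.param(np.array(0.1)),
            mu_raw=Tensor.param(np.array(0.5413)),   # softplus -> ~1.0
            omega_raw=Tensor.param(np.array(0.0)),   # sigmoid -> 0.5
        )
        layers.append(lp)
        d_in = hid
    P0 = Tensor.param(laplacian_position_init(adjacency, hid))
    W_out = Tensor.param(_glorot(rng, (hid, config.n_classes)))
    b_out = Tensor.param(np.zeros(config.n_classes))
    return ModelParams(layers=layers, P0=P0, W_out=W_out, b_out=b_out,
                       config=config)


class DPGAModel:
    """The DP-GA stack bound to one patient graph (transductive)."""

    def __init__(self, graph: PatientGraph, config: LayerConfig,
                 potential_features=None, seed: int = 0):
        self.graph = graph
        self.config = config
        self.edge_i, self.edge_j = graph.directed_edges
        self.degrees = graph.degrees
        self.n_nodes = graph.n_nodes
        if potential_features is None:
            potential_features = np.arange(graph.cohort.n_features)
        self.potential = disease_potential(graph.cohort.X, potential_features)
        self.mask = build_mask(self.potential, self.edge_i, self.edge_j,
                               config.eps_mask)
        self.params = init_params(graph.cohort.n_features, graph.adjacency,
                                  config, seed=seed)

    # -- forward -------------------------------------------------------------

    def forward(self, training: bool = False,
                rng: np.random.Generator | None = None,
                mask_override: np.ndarray | None = None,
                collect_state: bool = False):
        """Full forward pass.

        Returns ``(logits, states, P)`` where ``states`` is a list (one per
        layer) of per-head :class:`AttentionState` lists when
        ``collect_state`` is set (else empty), and ``P`` the position
        embeddings entering the last layer.
        """
        cfg = self.config
        if training and rng is None:
            rng = np.random.default_rng(0)
        mask = self.mask if mask_override is None else mask_override
        ei, ej, Z = self.edge_i, self.edge_j, self.n_nodes
        n_heads = cfg.heads
        iso = np.ones(Z)
        iso[np.unique(ei)] = 0.0

        H = Tensor(self.graph.cohort.X.astype(float))
        P = self.params.P0
        states: list = []
        for li, lp in enumerate(self.params.layers):
            last = li == len(self.params.layers) - 1
            if training and cfg.drop > 0:
                H = H * (rng.random(H.shape) >= cfg.drop) / (1.0 - cfg.drop)
            Ht = H @ lp.W_h              # feature transform of the layer
            Pt = P @ lp.W_p              # position transform of the layer
            d = bregman_divergence(Ht, Pt, lp.omega, ei, ej)

            # All heads batched: identical numbers to the per-head ops,
            # but one large gather instead of one per head.
            d_head = lp.W[0].shape[1]
            W_stack = ad.concat(lp.W, axis=1)            # (hid, heads*d_head)
            WH = Ht @ W_stack
            L3 = ad.leaky_relu(WH, cfg.leaky_slope).reshape(Z, n_heads, d_head)
            A_src = ad.concat(lp.a_src, axis=0).reshape(n_heads, d_head)
            A_dst = ad.concat(lp.a_dst, axis=0).reshape(n_heads, d_head)
            score_src = (L3 * A_src).sum(axis=2)         # (Z, heads)
            score_dst = (L3 * A_dst).sum(axis=2)
            e_base = score_src.take_rows(ei) + score_dst.take_rows(ej)
            A_s2 = ad.concat(lp.a_s, axis=0).reshape(n_heads, cfg.hid).square()
            e_pos = ad.edge_bilinear(Pt, A_s2, ei, ej)   # (E, heads)
            e_fus = e_base + e_pos
            e_adj = e_fus - lp.delta * d.reshape(-1, 1)

            shift = ad.segment_max_detached(e_adj.data, ei, Z)
            ex = (e_adj - shift[ei]).exp()
            denom = ad.segment_sum(ex, ei, Z)
            denom_safe = denom + (denom.data == 0.0) * 1.0
            alpha = ex * mask[:, None] / denom_safe.take_rows(ei)
            if cfg.renormalize_masked_attention:
                row = ad.segment_sum(alpha, ei, Z)
                row_safe = row + (row.data == 0.0) * 1.0
                alpha = alpha / row_safe.take_rows(ei)
            if collect_state:
                layer_states = [AttentionState(
                    edge_i=ei, edge_j=ej,
                    e_base=e_base.data[:, h].copy(),
                    e_pos=e_pos.data[:, h].copy(),
                    e_fusion=e_fus.data[:, h].copy(), d=d.data.copy(),
                    e_adjust=e_adj.data[:, h].copy(),
                    m=np.asarray(mask).copy(),
                    alpha=alpha.data[:, h].copy()) for h in range(n_heads)]
            if training and cfg.drop > 0:
                alpha = alpha * (rng.random(alpha.shape) >= cfg.drop) \
                    / (1.0 - cfg.drop)
            agg = ad.multihead_edge_weighted_sum(alpha, WH, ei, ej, Z)
            if iso.any():
                # isolated nodes keep their own projected features
                agg = agg + iso[:, None] * WH
            agg = lp.mu * agg
            if last:
                agg = agg.reshape(Z, n_heads, d_head).sum(axis=1) \
                    * (1.0 / n_heads)

            if cfg.use_sim_diff_branch:
                Hs = Ht @ lp.sim_proj
                C = ad.edge_dot(Hs, Hs, ei, ej)
                # the shift cancels in the normalised aggregation
                z = (C - lp.beta * d) * (1.0 / cfg.tau)
                shift = ad.segment_max_detached(z.data, ei, Z)
                R = (z - shift[ei]).exp()
                M = aggregate_messages(R, Ht, ei, ej, Z)
                agg = agg + update_nodes(Ht, M, lp.mu, self.degrees)

            H = ad.elu(agg)
            if collect_state:
                states.append(layer_states)
            if not last:
                P = Pt

        logits = H @ self.params.W_out + self.params.b_out
        return logits, states, P

    def predict_proba(self) -> np.ndarray:
        logits, _, _ = self.forward(training=False)
        lp = ad.log_softmax(logits)
        return np.exp(lp.data)

    def attention_state(self, layer: int = 0, head: int = 0) -> AttentionState:
        _, states, _ = self.forward(training=False, collect_state=True)
        return states[layer][head]


def export_attention_tsv(state: AttentionState, path) -> None:
    """Per-edge attention diagnostics as TSV."""
    with open(path, "w") as fh:
        fh.write("i\tj\te_base\te_pos\te_fusion\td\te_adjust\tm\talpha\n")
        for k in range(len(state.edge_i)):
            fh.write(f"{state.edge_i[k]}\t{state.edge_j[k]}\t"
                     f"{state.e_base[k]:.6g}\t{state.e_pos[k]:.6g}\t"
                     f"{state.e_fusion[k]:.6g}\t{state.d[k]:.6g}\t"
                     f"{state.e_adjust[k]:.6g}\t{state.m[k]:.3g}\t"
                     f"{state.alpha[k]:.6g}\n")
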