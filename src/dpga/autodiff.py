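"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the attention layers need: broadcasted
arithmetic, matrix products, reductions, elementwise nonlinearities,
row gather and segment (scatter-add) sums.  All arithmetic is float64.

Gradient correctness is exercised end-to-end by finite-difference tests
against the full model loss.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = [
    "Tensor", "concat", "segment_sum", "segment_max_detached",
    "edge_dot", "edge_sqdist", "edge_weighted_sum", "edge_bilinear",
    "multihead_edge_weighted_sum",
    "sigmoid", "softplus", "leaky_relu", "elu", "log_softmax",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


# Scatter-adds of (E, d) edge blocks into (n, d) node blocks dominate the
# runtime; a cached sparse incidence matrix turns them into csr matmuls,
# far faster than np.add.at.  Keys are the raw index bytes, so any equal
# index vector hits the cache.
_scatter_cache: dict = {}


def _scatter_rows(ids: np.ndarray, n: int, X: np.ndarray) -> np.ndarray:
    """out[k] = sum over e with ids[e] == k of X[e] (rows or scalars)."""
    ids = np.asarray(ids, dtype=np.intp)
    if X.ndim == 1:
        return np.bincount(ids, weights=X, minlength=n)
    key = (n, ids.tobytes())
    M = _scatter_cache.get(key)
    if M is None:
        if len(_scatter_cache) > 64:
            _scatter_cache.clear()
        E = len(ids)
        M = sparse.csr_matrix((np.ones(E), (ids, np.arange(E))), shape=(n, E))
        _scatter_cache[key] = M
    return M @ X



def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum grad over broadcasted axes so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    # defer mixed ndarray/Tensor arithmetic to the Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = _as_array(data)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def param(data, name: str | None = None) -> "Tensor":
        return Tensor(data, requires_grad=True, name=name)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this tensor (typically a scalar loss)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = _as_array(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)
        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                               other.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad or self._parents:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._parents:
                other._accumulate(self.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def square(self):
        return self * self

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    # -- elementwise ----------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            self._accumulate(g / self.data)
        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    # -- indexing -------------------------------------------------------------

    def take_rows(self, idx: np.ndarray):
        """Gather rows; gradient scatter-adds back."""
        idx = np.asarray(idx, dtype=np.intp)
        out_data = self.data[idx]

        def bwd(g):
            self._accumulate(_scatter_rows(idx, self.data.shape[0], g))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)


# -- free functions -----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows (or scalars) of ``x`` into ``num_segments`` buckets."""
    x = Tensor._lift(x)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_data = _scatter_rows(segment_ids, num_segments, x.data)

    def bwd(g):
        x._accumulate(g[segment_ids])

    return Tensor(out_data, parents=(x,), backward=bwd)


def segment_max_detached(values: np.ndarray, segment_ids: np.ndarray,
                         num_segments: int) -> np.ndarray:
    """Per-segment max as a constant (for softmax shift; no gradient).

    Accepts (E,) or (E, k) values; the max is per segment (and column).
    """
    values = np.asarray(values)
    shape = (num_segments,) + values.shape[1:]
    out = np.full(shape, -np.inf)
    np.maximum.at(out, np.asarray(segment_ids, dtype=np.intp), values)
    out[~np.isfinite(out)] = 0.0
    return out


# For a fixed directed edge set, per-edge weighted neighbour sums are csr
# matmuls with a Z x Z matrix whose sparsity pattern never changes; the
# template (indices plus the permutation from edge order to csr data order)
# is cached on the index bytes.
_edge_csr_cache: dict = {}


def _edge_csr_template(edge_i: np.ndarray, edge_j: np.ndarray, n: int):
    ei = np.asarray(edge_i, dtype=np.intp)
    ej = np.asarray(edge_j, dtype=np.intp)
    key = (n, ei.tobytes(), ej.tobytes())
    tpl = _edge_csr_cache.get(key)
    if tpl is None:
        if len(_edge_csr_cache) > 64:
            _edge_csr_cache.clear()
        E = len(ei)
        tag = np.arange(1, E + 1, dtype=np.float64)
        A = sparse.csr_matrix((tag, (ei, ej)), shape=(n, n))
        perm = A.data.astype(np.intp) - 1          # A.data = w[perm]
        AT = sparse.csr_matrix((tag, (ej, ei)), shape=(n, n))
        perm_T = AT.data.astype(np.intp) - 1
        tpl = (A, perm, AT, perm_T)
        _edge_csr_cache[key] = tpl
    return tpl


def _edge_matvec(w: np.ndarray, H: np.ndarray, edge_i, edge_j, n: int,
                 transpose: bool = False) -> np.ndarray:
    """out[i] = sum_e w_e H[j_e]  (or the transposed scatter)."""
    A, perm, AT, perm_T = _edge_csr_template(edge_i, edge_j, n)
    M, p = (AT, perm_T) if transpose else (A, perm)
    M.data = w[p]
    return M @ H


def edge_dot(X: Tensor, Y: Tensor, edge_i: np.ndarray,
             edge_j: np.ndarray) -> Tensor:
    """Per-edge inner product sum_k X[i, k] * Y[j, k].

    Fused so the autodiff graph holds only the (n_edges,) result; the
    gathered (n_edges, d) blocks are transient.
    """
    X, Y = Tensor._lift(X), Tensor._lift(Y)
    ei = np.asarray(edge_i, dtype=np.intp)
    ej = np.asarray(edge_j, dtype=np.intp)
    out_data = np.einsum("ed,ed->e", X.data[ei], Y.data[ej])

    def bwd(g):
        if X.requires_grad or X._parents:
            X._accumulate(_scatter_rows(ei, X.data.shape[0],
                                        g[:, None] * Y.data[ej]))
        if Y.requires_grad or Y._parents:
            Y._accumulate(_scatter_rows(ej, Y.data.shape[0],
                                        g[:, None] * X.data[ei]))

    return Tensor(out_data, parents=(X, Y), backward=bwd)


def edge_sqdist(X: Tensor, edge_i: np.ndarray, edge_j: np.ndarray) -> Tensor:
    """Per-edge squared Euclidean distance ||X[i] - X[j]||^2 (fused)."""
    X = Tensor._lift(X)
    ei = np.asarray(edge_i, dtype=np.intp)
    ej = np.asarray(edge_j, dtype=np.intp)
    diff = X.data[ei] - X.data[ej]            # kept for the backward pass
    out_data = np.einsum("ed,ed->e", diff, diff)

    def bwd(g):
        if X.requires_grad or X._parents:
            gd = 2.0 * g[:, None] * diff
            n = X.data.shape[0]
            X._accumulate(_scatter_rows(ei, n, gd) - _scatter_rows(ej, n, gd))

    return Tensor(out_data, parents=(X,), backward=bwd)


def edge_weighted_sum(w: Tensor, H: Tensor, edge_i: np.ndarray,
                      edge_j: np.ndarray, num_segments: int) -> Tensor:
    """Per-receiver weighted neighbour sum: out[i] = sum_e w_e * H[j_e] (fused)."""
    w, H = Tensor._lift(w), Tensor._lift(H)
    ei = np.asarray(edge_i, dtype=np.intp)
    ej = np.asarray(edge_j, dtype=np.intp)
    out_data = _edge_matvec(w.data, H.data, ei, ej, num_segments)

    def bwd(g):
        if w.requires_grad or w._parents:
            w._accumulate(np.einsum("ed,ed->e", g[ei], H.data[ej]))
        if H.requires_grad or H._parents:
            H._accumulate(_edge_matvec(w.data, g, ei, ej,
                                       H.data.shape[0], transpose=True))

    return Tensor(out_data, parents=(w, H), backward=bwd)


def edge_bilinear(S: Tensor, A2: Tensor, edge_i: np.ndarray,
                  edge_j: np.ndarray) -> Tensor:
    """Multi-vector bilinear edge scores: out[e, h] = sum_k S[i,k] S[j,k] A2[h,k].

    One gather pair serves every attention head; ``A2`` stacks the per-head
    coefficient vectors (already squared for the structural-attention use).
    """
    S, A2 = Tensor._lift(S), Tensor._lift(A2)
    ei = np.asarray(edge_i, dtype=np.intp)
    ej = np.asarray(edge_j, dtype=np.intp)
    Si, Sj = S.data[ei], S.data[ej]
    out_data = (Si * Sj) @ A2.data.T

    def bwd(g):
        if A2.requires_grad or A2._parents:
            A2._accumulate(g.T @ (Si * Sj))
        if S.requires_grad or S._parents:
            gP = g @ A2.data               # (E, k)
            n = S.data.shape[0]
            S._accumulate(_scatter_rows(ei, n, gP * Sj) +
                          _scatter_rows(ej, n, gP * Si))

    return Tensor(out_data, parents=(S, A2), backward=bwd)


def multihead_edge_weighted_sum(alpha: Tensor, H: Tensor, edge_i: np.ndarray,
                                edge_j: np.ndarray, num_segments: int) -> Tensor:
    """Per-head weighted sums: out[i, h*d:(h+1)*d] = sum_e alpha[e,h] H[j_e, h-block].

    ``alpha`` is (E, heads); ``H`` stacks the per-head projections
    column-blockwise, width heads * d.
    """
    alpha, H = Tensor._lift(alpha), Tensor._lift(H)
    ei = np.asarray(edge_i, dtype=np.intp)
    ej = np.asarray(edge_j, dtype=np.intp)
    E, heads = alpha.data.shape
    width = H.data.shape[1]
    if width % heads:
        raise ValueError("H width must be divisible by the head count")
    d = width // heads
    out_data = np.empty((num_segments, width))
    for h in range(heads):
        out_data[:, h * d:(h + 1) * d] = _edge_matvec(
            np.ascontiguousarray(alpha.data[:, h]), H.data[:, h * d:(h + 1) * d],
            ei, ej, num_segments)

    def bwd(g):
        if alpha.requires_grad or alpha._parents:
            gi = g[ei].reshape(E, heads, d)
            Hj = H.data[ej].reshape(E, heads, d)
            alpha._accumulate(np.einsum("ehd,ehd->eh", gi, Hj))
        if H.requires_grad or H._parents:
            acc = np.empty_like(H.data)
            for h in range(heads):
                acc[:, h * d:(h + 1) * d] = _edge_matvec(
                    np.ascontiguousarray(alpha.data[:, h]),
                    g[:, h * d:(h + 1) * d], ei, ej, H.data.shape[0],
                    transpose=True)
            H._accumulate(acc)

    return Tensor(out_data, parents=(alpha, H), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=bwd)


def softplus(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    out_data = np.logaddexp(0.0, x.data)

    def bwd(g):
        x._accumulate(g / (1.0 + np.exp(-x.data)))

    return Tensor(out_data, parents=(x,), backward=bwd)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    x = Tensor._lift(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, slope * x.data)

    def bwd(g):
        x._accumulate(g * np.where(mask, 1.0, slope))

    return Tensor(out_data, parents=(x,), backward=bwd)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    x = Tensor._lift(x)
    mask = x.data > 0
    expm1 = alpha * np.expm1(np.minimum(x.data, 0.0))
    out_data = np.where(mask, x.data, expm1)

    def bwd(g):
        x._accumulate(g * np.where(mask, 1.0, expm1 + alpha))

    return Tensor(out_data, parents=(x,), backward=bwd)


def log_softmax(logits: Tensor) -> Tensor:
    """Row-wise log-softmax, stabilised by a detached max shift."""
    shift = logits.data.max(axis=1, keepdims=True)
    shifted = logits - shift
    lse = shifted.exp().sum(axis=1, keepdims=True).log()
    return shifted - lse


class Adam:
    """Adaptive-moment optimiser over a flat list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
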