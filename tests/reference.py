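"""Straight-line per-edge / per-node reference implementations.

Everything here is written as plain Python loops over edges and nodes,
directly transcribing the attention and message-passing definitions, and
is deliberately independent of the vectorised implementation it checks.
"""

import numpy as np


def leaky(x, slope=0.2):
    return np.where(x > 0, x, slope * x)


def ref_base_attention(H, W, a_src, a_dst, edges, slope=0.2):
    out = []
    for (i, j) in edges:
        out.append(float(a_src @ leaky(W.T @ H[i], slope)
                         + a_dst @ leaky(W.T @ H[j], slope)))
    return np.array(out)


def ref_structural_attention(S, a_s, edges):
    out = []
    for (i, j) in edges:
        out.append(float(sum(S[i, k] * S[j, k] * a_s[k] ** 2
                             for k in range(S.shape[1]))))
    return np.array(out)


def ref_bregman(H, S, omega, edges):
    out = []
    for (i, j) in edges:
        df = float(((H[i] - H[j]) ** 2).sum())
        ds = float(((S[i] - S[j]) ** 2).sum())
        out.append(omega * df + (1 - omega) * ds)
    return np.array(out)


def ref_relation(C, O, beta, tau, edges):
    return np.array([np.exp((C[k] - beta * O[k]) / tau)
                     for k in range(len(edges))])


def ref_aggregate_messages(R, H, edges, n):
    M = np.zeros((n, H.shape[1]))
    for i in range(n):
        idx = [k for k, (a, _) in enumerate(edges) if a == i]
        tot = sum(R[k] for k in idx)
        if tot == 0:
            continue
        for k in idx:
            M[i] += R[k] / tot * H[edges[k][1]]
    return M


def ref_update_nodes(H, M, mu, degrees):
    out = np.zeros_like(H)
    for i in range(H.shape[0]):
        deg = max(degrees[i], 1)
        out[i] = mu * H[i] / deg + M[i]
    return out


def ref_mask(raw_sum, edges, eps):
    return np.array([1.0 if raw_sum[i] > raw_sum[j] else eps
                     for (i, j) in edges])


def ref_potential_attention(e_adjust, mask, edges, n, renormalize=False):
    alpha = np.zeros(len(edges))
    for i in range(n):
        idx = [k for k, (a, _) in enumerate(edges) if a == i]
        if not idx:
            continue
        denom = sum(np.exp(e_adjust[k]) for k in idx)
        for k in idx:
            alpha[k] = np.exp(e_adjust[k]) * mask[k] / denom
        if renormalize:
            s = sum(alpha[k] for k in idx)
            if s > 0:
                for k in idx:
                    alpha[k] /= s
    return alpha


def ref_aggregate_with_attention(alpha, H, W, mu, edges, n):
    out = np.zeros((n, W.shape[1]))
    receivers = {i for (i, _) in edges}
    for k, (i, j) in enumerate(edges):
        out[i] += alpha[k] * (W.T @ H[j])
    for i in range(n):
        if i not in receivers:
            out[i] = W.T @ H[i]
    return mu * out


def ref_forward(model):
    """Whole-stack forward in loop form; mirrors the composition contract:
    per layer, Eq-5 transforms, fusion scores, divergence adjustment,
    potential-masked attention, attention aggregation (heads concatenated
    on hidden layers, averaged on the last), plus the similarity-difference
    branch, ELU, then the linear classifier."""
    cfg = model.config
    edges = list(zip(model.edge_i.tolist(), model.edge_j.tolist()))
    n = model.n_nodes
    degrees = model.degrees
    mask = ref_mask(model.potential.raw_sum, edges, cfg.eps_mask)

    H = model.graph.cohort.X.astype(float)
    P = model.params.P0.data.copy()
    for li, lp in enumerate(model.params.layers):
        last = li == len(model.params.layers) - 1
        Ht = H @ lp.W_h.data
        Pt = P @ lp.W_p.data
        omega = 1.0 / (1.0 + np.exp(-lp.omega_raw.data))
        mu = np.logaddexp(0.0, lp.mu_raw.data)
        d = ref_bregman(Ht, Pt, float(omega), edges)
        head_outs = []
        for h in range(cfg.heads):
            e_base = ref_base_attention(Ht, lp.W[h].data, lp.a_src[h].data,
                                        lp.a_dst[h].data, edges,
                                        cfg.leaky_slope)
            e_pos = ref_structural_attention(Pt, lp.a_s[h].data, edges)
            e_adj = e_base + e_pos - lp.delta.data * d
            alpha = ref_potential_attention(
                e_adj, mask, edges, n,
                renormalize=cfg.renormalize_masked_attention)
            head_outs.append(ref_aggregate_with_attention(
                alpha, Ht, lp.W[h].data, float(mu), edges, n))
        if last:
            agg = np.mean(head_outs, axis=0)
        else:
            agg = np.concatenate(head_outs, axis=1)
        if cfg.use_sim_diff_branch:
            Hs = Ht @ lp.sim_proj.data
            C = np.array([float(Hs[i] @ Hs[j]) for (i, j) in edges])
            R = ref_relation(C, d, float(lp.beta.data), cfg.tau, edges)
            M = ref_aggregate_messages(R, Ht, edges, n)
            agg = agg + ref_update_nodes(Ht, M, float(mu), degrees)
        H = np.where(agg > 0, agg, np.expm1(np.minimum(agg, 0)))
        if not last:
            P = Pt
    return H @ model.params.W_out.data + model.params.b_out.data
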