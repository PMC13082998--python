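import numpy as np
import pytest

import dpga.autodiff as ad
from dpga.model import (DPGAModel, LayerConfig, PotentialVector,
                        adjust_attention, aggregate_messages,
                        aggregate_with_attention, base_attention,
                        bregman_divergence, build_mask, disease_potential,
                        fuse_attention, potential_attention, relation_scores,
                        structural_attention, update_nodes)
from dpga.simulate import generate_toy_graph

from reference import (ref_aggregate_messages, ref_aggregate_with_attention,
                       ref_base_attention, ref_bregman, ref_forward,
                       ref_mask, ref_potential_attention, ref_relation,
                       ref_structural_attention, ref_update_nodes)


def data(x):
    return x.data if isinstance(x, ad.Tensor) else np.asarray(x)


class TestBaseAttention:
    def test_hand_example(self):
        """W=I, a_src=(1,0), a_dst=(0,1), slope 0.2, h_i=(2,-1), h_j=(1,3):
        score = 2 + 3 = 5."""
        H = np.array([[2.0, -1.0], [1.0, 3.0]])
        e = base_attention(H, np.eye(2), np.array([1.0, 0.0]),
                           np.array([0.0, 1.0]), [0], [1], leaky_slope=0.2)
        assert data(e) == pytest.approx([5.0])

    def test_zero_features_give_zero(self):
        H = np.zeros((3, 2))
        e = base_attention(H, np.eye(2), np.ones(2), np.ones(2),
                           [0, 1], [1, 2])
        assert np.allclose(data(e), 0.0)

    def test_zero_attention_vectors_give_zero(self, rng):
        H = rng.normal(size=(4, 3))
        e = base_attention(H, rng.normal(size=(3, 2)), np.zeros(2),
                           np.zeros(2), [0, 2], [1, 3])
        assert np.allclose(data(e), 0.0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            base_attention(np.ones((2, 3)), np.eye(2), np.ones(2),
                           np.ones(2), [0], [1])


class TestStructuralAttention:
    def test_hand_example(self):
        """s_i=(1,2), s_j=(3,1), a_s=(1,0.5): 1*3*1 + 2*1*0.25 = 3.5."""
        S = np.array([[1.0, 2.0], [3.0, 1.0]])
        e = structural_attention(S, np.array([1.0, 0.5]), [0], [1])
        assert data(e) == pytest.approx([3.5])

    def test_zero_vector_gives_zero(self, rng):
        S = rng.normal(size=(3, 4))
        e = structural_attention(S, np.zeros(4), [0, 1], [1, 2])
        assert np.allclose(data(e), 0.0)

    def test_equal_embeddings_squared_norm(self):
        S = np.ones((2, 2))
        e = structural_attention(S, np.ones(2), [0], [1])
        assert data(e) == pytest.approx([2.0])


class TestFusionAndAdjustment:
    def test_fusion_is_elementwise_sum(self):
        assert data(fuse_attention(np.array([0.3]), np.array([0.7]))) == \
            pytest.approx([1.0])

    def test_fusion_commutative(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert np.allclose(data(fuse_attention(a, b)),
                           data(fuse_attention(b, a)))

    @pytest.mark.parametrize("e,delta,d,expected", [
        (2.0, 0.5, 1.0, 1.5),
        (2.0, 0.0, 3.0, 2.0),
        (2.0, 0.7, 0.0, 2.0),
    ])
    def test_adjustment_arithmetic(self, e, delta, d, expected):
        out = adjust_attention(np.array([e]), np.array([d]), delta)
        assert data(out) == pytest.approx([expected])


class TestBregman:
    def test_hand_example(self):
        """h=(0,0) vs (1,1), s=(0) vs (2), omega=0.5: 0.5*2 + 0.5*4 = 3."""
        H = np.array([[0.0, 0.0], [1.0, 1.0]])
        S = np.array([[0.0], [2.0]])
        out = bregman_divergence(H, S, 0.5, [0], [1])
        assert data(out) == pytest.approx([3.0])

    def test_identical_nodes_zero_for_any_omega(self, rng):
        H = np.tile(rng.normal(size=(1, 3)), (2, 1))
        S = np.tile(rng.normal(size=(1, 2)), (2, 1))
        for omega in (0.0, 0.3, 1.0):
            assert data(bregman_divergence(H, S, omega, [0], [1])) == \
                pytest.approx([0.0])

    def test_omega_one_is_feature_distance(self, rng):
        H = rng.normal(size=(2, 4))
        S = rng.normal(size=(2, 2))
        out = bregman_divergence(H, S, 1.0, [0], [1])
        assert data(out) == pytest.approx([((H[0] - H[1]) ** 2).sum()])


class TestRelationAndMessages:
    def test_zero_scores_give_one(self):
        out = relation_scores(np.zeros(3), np.zeros(3), 1.0, 1.0)
        assert np.allclose(data(out), 1.0)

    def test_hand_example(self):
        out = relation_scores(np.array([1.0]), np.array([1.0]), 1.0, 1.0)
        assert data(out) == pytest.approx([1.0])

    def test_nonpositive_temperature_raises(self):
        with pytest.raises(ValueError):
            relation_scores(np.zeros(1), np.zeros(1), 1.0, 0.0)

    def test_single_neighbor_copies_features(self):
        H = np.array([[1.0, 2.0], [5.0, 6.0]])
        M = aggregate_messages(np.array([2.0]), H, [0], [1], 2)
        assert data(M)[0] == pytest.approx(H[1])

    def test_weighted_mean(self):
        """Weights (1,3) on neighbours with features e1, e2 -> (0.25, 0.75)."""
        H = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        M = aggregate_messages(np.array([1.0, 3.0]), H, [0, 0], [1, 2], 3)
        assert data(M)[0] == pytest.approx([0.25, 0.75])

    def test_update_nodes_hand_example(self):
        """mu=1, deg=2, H_i=(2,2), M_i=(1,1) -> (2,2)."""
        out = update_nodes(np.array([[2.0, 2.0]]), np.array([[1.0, 1.0]]),
                           1.0, [2])
        assert data(out)[0] == pytest.approx([2.0, 2.0])

    def test_update_linear_in_inputs(self, rng):
        H, M = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        deg = [1, 2, 3]
        a = data(update_nodes(2 * H, 2 * M, 1.5, deg))
        b = 2 * data(update_nodes(H, M, 1.5, deg))
        assert np.allclose(a, b)


class TestPotentialAndMask:
    def test_sigmoid_values(self):
        X = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 1]])
        pot = disease_potential(X, [0, 1, 2])
        assert pot.p[0] == pytest.approx(0.5)
        assert pot.p[1] == pytest.approx(1 / (1 + np.exp(-1)))
        assert pot.raw_sum.tolist() == [0, 1, 3]

    def test_monotone_in_diagnosis_set(self):
        X = np.array([[1, 0, 0], [1, 1, 0]])   # row 0 subset of row 1
        pot = disease_potential(X, [0, 1, 2])
        assert pot.p[0] <= pot.p[1]

    def test_empty_feature_set_raises(self):
        with pytest.raises(ValueError):
            disease_potential(np.ones((2, 2)), [])

    def test_strict_inequality_and_ties(self):
        pot = PotentialVector(raw_sum=np.array([9.0, 4.0, 4.0]),
                              p=np.zeros(3), feature_set=np.array([0]))
        m = build_mask(pot, [0, 1, 1, 2], [1, 0, 2, 1], eps_mask=0.1)
        assert m.tolist() == [1.0, 0.1, 0.1, 0.1]

    def test_never_one_both_directions(self, rng):
        """(m_ij, m_ji) is never (1, 1): strict order is antisymmetric."""
        raw = rng.integers(0, 4, size=10).astype(float)
        pot = PotentialVector(raw_sum=raw, p=raw, feature_set=np.array([0]))
        ei, ej = np.repeat(np.arange(10), 10), np.tile(np.arange(10), 10)
        m = build_mask(pot, ei, ej, 0.1)
        m_rev = build_mask(pot, ej, ei, 0.1)
        assert not np.any((m == 1.0) & (m_rev == 1.0))


class TestPotentialAttention:
    def test_single_neighbor_full_mask(self):
        a = potential_attention(np.array([3.0]), np.array([1.0]), [0], 1)
        assert data(a) == pytest.approx([1.0])

    def test_equal_scores_full_masks(self):
        a = potential_attention(np.zeros(2), np.ones(2), [0, 0], 1)
        assert data(a) == pytest.approx([0.5, 0.5])

    def test_suppressed_edge_scales_numerator_only(self):
        """Masks (1, 0.1) with equal scores give (0.5, 0.05): the printed
        form divides by the unmasked normaliser, so rows sum to 0.55."""
        a = potential_attention(np.zeros(2), np.array([1.0, 0.1]), [0, 0], 1)
        assert data(a) == pytest.approx([0.5, 0.05])
        assert data(a).sum() == pytest.approx(0.55)

    def test_renormalization_restores_unit_rows(self):
        a = potential_attention(np.zeros(2), np.array([1.0, 0.1]), [0, 0], 1,
                                renormalize=True)
        assert data(a).sum() == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        """Adding a constant to all of a node's scores leaves alpha fixed."""
        e = rng.normal(size=4)
        mask = np.array([1.0, 0.1, 1.0, 0.1])
        a1 = data(potential_attention(e, mask, [0, 0, 0, 0], 1))
        a2 = data(potential_attention(e + 37.5, mask, [0, 0, 0, 0], 1))
        assert np.allclose(a1, a2)


class TestAggregateWithAttention:
    def test_single_neighbor_identity(self):
        H = np.array([[9.0, 9.0], [1.0, 2.0]])
        out = aggregate_with_attention(np.array([1.0]), H, np.eye(2), 1.0,
                                       [0], [1], 2)
        assert data(out)[0] == pytest.approx([1.0, 2.0])

    def test_hand_example_mu_two(self):
        """mu=2, alpha=(0.5,0.5), neighbours e1 and e2 -> (1,1)."""
        H = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        out = aggregate_with_attention(np.array([0.5, 0.5]), H, np.eye(2),
                                       2.0, [0, 0], [1, 2], 3)
        assert data(out)[0] == pytest.approx([1.0, 1.0])

    def test_zero_alpha_gives_zero(self):
        H = np.ones((2, 2))
        out = aggregate_with_attention(np.array([0.0]), H, np.eye(2), 1.0,
                                       [0], [1], 2)
        assert data(out)[0] == pytest.approx([0.0, 0.0])


def _random_edge_setup(seed, n=10, d=4):
    rng = np.random.default_rng(seed)
    g = generate_toy_graph(n, 5, seed=seed)
    ei, ej = g.directed_edges
    edges = list(zip(ei.tolist(), ej.tolist()))
    H = rng.normal(size=(n, d))
    S = rng.normal(size=(n, 3))
    return rng, g, ei, ej, edges, H, S


@pytest.mark.parametrize("seed", range(12))
def test_ops_match_loop_oracles(seed):
    """Vectorised per-edge operations agree with straight-line loop
    implementations on random toy graphs."""
    rng, g, ei, ej, edges, H, S = _random_edge_setup(seed)
    n = g.n_nodes
    W = rng.normal(size=(4, 3))
    a_src, a_dst = rng.normal(size=3), rng.normal(size=3)
    a_s = rng.normal(size=3)
    omega = float(rng.random())

    assert np.allclose(data(base_attention(H, W, a_src, a_dst, ei, ej)),
                       ref_base_attention(H, W, a_src, a_dst, edges),
                       atol=1e-6)
    assert np.allclose(data(structural_attention(S, a_s, ei, ej)),
                       ref_structural_attention(S, a_s, edges), atol=1e-6)
    d = data(bregman_divergence(H, S, omega, ei, ej))
    assert np.allclose(d, ref_bregman(H, S, omega, edges), atol=1e-6)
    assert (d >= -1e-12).all()

    C, O = rng.normal(size=len(edges)), np.abs(rng.normal(size=len(edges)))
    R = data(relation_scores(C, O, 0.8, 1.3))
    assert np.allclose(R, ref_relation(C, O, 0.8, 1.3, edges), atol=1e-6)
    assert np.allclose(data(aggregate_messages(R, H, ei, ej, n)),
                       ref_aggregate_messages(R, H, edges, n), atol=1e-6)

    raw = rng.integers(0, 3, size=n).astype(float)
    pot = PotentialVector(raw_sum=raw, p=raw, feature_set=np.array([0]))
    mask = build_mask(pot, ei, ej, 0.1)
    assert np.allclose(mask, ref_mask(raw, edges, 0.1))
    e_adj = rng.normal(size=len(edges))
    alpha = data(potential_attention(e_adj, mask, ei, n))
    assert np.allclose(alpha, ref_potential_attention(e_adj, mask, edges, n),
                       atol=1e-6)
    assert np.allclose(
        data(aggregate_with_attention(alpha, H, W, 1.7, ei, ej, n)),
        ref_aggregate_with_attention(alpha, H, W, 1.7, edges, n), atol=1e-6)


class TestForward:
    def test_matches_loop_reference(self):
        """Whole-stack logits equal a straight-line per-edge reference."""
        for seed in (0, 1, 2):
            g = generate_toy_graph(6, 6, seed=seed)
            m = DPGAModel(g, LayerConfig(hid=8, heads=2, drop=0.0),
                          seed=seed + 10)
            logits, _, _ = m.forward()
            assert np.allclose(logits.data, ref_forward(m), atol=1e-6)

    def test_deterministic_without_dropout(self, toy_graph):
        m = DPGAModel(toy_graph, LayerConfig(hid=8, heads=2, drop=0.0),
                      seed=0)
        a, _, _ = m.forward()
        b, _, _ = m.forward()
        assert np.array_equal(a.data, b.data)

    def test_permutation_equivariance(self):
        """Permuting patients permutes the logits identically."""
        from dpga.graph import CohortTable, build_graph
        g = generate_toy_graph(7, 6, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(7)
        cohort2 = CohortTable(X=g.cohort.X[perm], y=g.cohort.y[perm],
                              vocabulary=g.cohort.vocabulary)
        g2 = build_graph(cohort2, min_shared=1)
        cfg = LayerConfig(hid=8, heads=2, drop=0.0)
        m1 = DPGAModel(g, cfg, seed=3)
        m2 = DPGAModel(g2, cfg, seed=3)
        # copy parameters, permuting the per-node position embeddings
        for (k1, t1), (k2, t2) in zip(
                m1.params.named_parameters().items(),
                m2.params.named_parameters().items()):
            t2.data = t1.data[perm] if k1 == "P0" else t1.data.copy()
        l1, _, _ = m1.forward()
        l2, _, _ = m2.forward()
        assert np.allclose(l1.data[perm], l2.data, atol=1e-8)

    def test_reduction_to_standard_attention(self, toy_graph):
        """All-ones mask, delta=0, branch off: attention rows are exact
        probability distributions."""
        cfg = LayerConfig(hid=8, heads=2, drop=0.0,
                          use_sim_diff_branch=False)
        m = DPGAModel(toy_graph, cfg, seed=1)
        for lp in m.params.layers:
            lp.delta.data = np.array(0.0)
        ones = np.ones_like(m.mask)
        _, states, _ = m.forward(mask_override=ones, collect_state=True)
        for layer_states in states:
            for st in layer_states:
                sums = np.bincount(st.edge_i, weights=st.alpha,
                                   minlength=toy_graph.n_nodes)
                active = np.bincount(st.edge_i,
                                     minlength=toy_graph.n_nodes) > 0
                assert np.allclose(sums[active], 1.0, atol=1e-6)

    def test_mask_antisymmetry_on_model(self, toy_graph):
        m = DPGAModel(toy_graph, LayerConfig(hid=8, heads=2), seed=0)
        lookup = dict(zip(zip(m.edge_i.tolist(), m.edge_j.tolist()), m.mask))
        for (i, j), v in lookup.items():
            assert (v, lookup[(j, i)]) != (1.0, 1.0)

    def test_dropout_training_deterministic_given_rng(self, toy_graph):
        m = DPGAModel(toy_graph, LayerConfig(hid=8, heads=2, drop=0.3),
                      seed=0)
        a, _, _ = m.forward(training=True, rng=np.random.default_rng(5))
        b, _, _ = m.forward(training=True, rng=np.random.default_rng(5))
        assert np.array_equal(a.data, b.data)
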