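import numpy as np
import pytest
from scipy.special import expit

from rxnuq.chemio import MolecularGraph, ReactionRecord, featurize_molecule
from rxnuq.gnn_core import (
    ModelDims,
    ModelParams,
    embed_nodes,
    graph_repr,
    load_checkpoint,
    message_passing,
    reaction_forward,
    save_checkpoint,
    set2set_readout,
)

from conftest import SMILES_POOL, random_graph, random_record


# --- independent dense oracle for the message-passing recurrence -----------

def dense_message_passing(graph, h0, params, steps):
    """Brute-force per-node evaluation: m_v = sum_{w in N(v)} A(e_vw) h_w,
    h_v <- GRU(h_v, m_v), with the GRU gate equations written out."""
    w = params.weights
    d = params.dims.node_dim
    n = graph.n_nodes
    # per-edge matrices through the two-layer edge network
    A = {}
    for (j, k), e in graph.edge_features.items():
        hid = np.maximum(e @ w["enet_W1"] + w["enet_b1"], 0.0)
        A[(j, k)] = (hid @ w["enet_W2"] + w["enet_b2"]).reshape(d, d)
        A[(k, j)] = A[(j, k)]
    neighbors = {v: [] for v in range(n)}
    for (j, k) in graph.edge_features:
        neighbors[j].append(k)
        neighbors[k].append(j)
    h = np.array(h0, dtype=float)
    for _ in range(steps):
        h_next = np.zeros_like(h)
        for v in range(n):
            m = np.zeros(d)
            for u in neighbors[v]:
                m = m + A[(v, u)] @ h[u]
            r = expit(m @ w["gru_Wr"] + h[v] @ w["gru_Ur"] + w["gru_br"])
            z = expit(m @ w["gru_Wz"] + h[v] @ w["gru_Uz"] + w["gru_bz"])
            c = np.tanh(m @ w["gru_Wn"] + w["gru_bn"]
                        + r * (h[v] @ w["gru_Un"] + w["gru_bhn"]))
            h_next[v] = (1.0 - z) * c + z * h[v]
        h = h_next
    return h


class TestEmbedNodes:
    def test_zero_params_zero_states(self, tiny_dims):
        params = ModelParams.init(tiny_dims, 0)
        params.weights["emb_W"][:] = 0.0
        params.weights["emb_b"][:] = 0.0
        g = random_graph(np.random.default_rng(0))
        assert np.all(embed_nodes(g, params) == 0.0)

    def test_single_node_shape(self, tiny_params, tiny_dims):
        g = MolecularGraph(np.random.default_rng(1).normal(size=(1, tiny_dims.p)), {})
        states = embed_nodes(g, tiny_params)
        assert states.shape == (1, tiny_dims.node_dim)

    def test_identical_features_identical_states(self, tiny_params, tiny_dims):
        row = np.random.default_rng(2).normal(size=tiny_dims.p)
        g = MolecularGraph(np.vstack([row, row]), {(0, 1): np.zeros(tiny_dims.q)})
        states = embed_nodes(g, tiny_params)
        assert np.allclose(states[0], states[1])

    def test_dimension_mismatch(self, tiny_params):
        g = MolecularGraph(np.zeros((2, 99)), {})
        with pytest.raises(ValueError):
            embed_nodes(g, tiny_params)


class TestMessagePassing:
    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_dense_oracle(self, tiny_params, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng)
        h0 = embed_nodes(g, tiny_params)
        got = message_passing(g, h0, tiny_params)
        want = dense_message_passing(g, h0, tiny_params, tiny_params.dims.message_steps)
        assert np.allclose(got, want, rtol=1e-6, atol=1e-9)

    def test_isolated_node_evolves_through_gru_only(self, tiny_params, tiny_dims):
        g = MolecularGraph(np.random.default_rng(3).normal(size=(1, tiny_dims.p)), {})
        h0 = embed_nodes(g, tiny_params)
        got = message_passing(g, h0, tiny_params)
        want = dense_message_passing(g, h0, tiny_params, tiny_dims.message_steps)
        assert np.allclose(got, want)
        assert not np.allclose(got, h0)  # GRU(h, 0) still updates the state

    def test_equivariance_under_relabeling(self, tiny_params):
        rng = np.random.default_rng(4)
        g = random_graph(rng, max_nodes=5)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        edges = {}
        for (j, k), e in g.edge_features.items():
            a, b = inv[j], inv[k]
            edges[(min(a, b), max(a, b))] = e
        g_perm = MolecularGraph(g.node_features[perm], edges)
        h0 = embed_nodes(g, tiny_params)
        h = message_passing(g, h0, tiny_params)
        h_perm = message_passing(g_perm, embed_nodes(g_perm, tiny_params), tiny_params)
        assert np.allclose(h[perm], h_perm, rtol=1e-6, atol=1e-12)


class TestSet2Set:
    def test_single_node_read_equals_state(self, tiny_params, tiny_dims):
        d = tiny_dims.node_dim
        state = np.random.default_rng(5).normal(size=(1, d))
        pooled = set2set_readout(state, tiny_params)
        assert pooled.shape == (2 * d,)
        assert np.allclose(pooled[d:], state[0])  # softmax over one element

    def test_identical_states_read_is_common_state(self, tiny_params, tiny_dims):
        d = tiny_dims.node_dim
        row = np.random.default_rng(6).normal(size=d)
        pooled = set2set_readout(np.tile(row, (4, 1)), tiny_params)
        assert np.allclose(pooled[d:], row)  # convex combination of equal vectors

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_invariance(self, tiny_params, seed):
        rng = np.random.default_rng(seed)
        states = rng.normal(size=(6, tiny_params.dims.node_dim))
        a = set2set_readout(states, tiny_params)
        b = set2set_readout(states[rng.permutation(6)], tiny_params)
        assert np.allclose(a, b, rtol=1e-6, atol=1e-12)

    def test_empty_states_error(self, tiny_params, tiny_dims):
        with pytest.raises(ValueError):
            set2set_readout(np.zeros((0, tiny_dims.node_dim)), tiny_params)


class TestGraphRepr:
    def test_output_length(self, feature_config):
        # full-size configuration: graph representation vector has length 1024
        dims = ModelDims(p=feature_config.p, q=feature_config.q)
        params = ModelParams.init(dims, 0)
        g = featurize_molecule("CCO", feature_config)
        assert graph_repr(g, params).shape == (1024,)

    def test_isomorphism_invariance_smiles_spellings(self, feature_config):
        dims = ModelDims.reduced(p=feature_config.p, q=feature_config.q)
        params = ModelParams.init(dims, 1)
        r1 = graph_repr(featurize_molecule("CCO", feature_config), params)
        r2 = graph_repr(featurize_molecule("OCC", feature_config), params)
        np.testing.assert_allclose(r1, r2, rtol=1e-6, atol=1e-12)


class TestReactionForward:
    def test_reactant_permutation_invariance(self, tiny_params):
        rng = np.random.default_rng(7)
        rec = random_record(rng, m_max=3)
        rec2 = ReactionRecord(list(reversed(rec.reactants)), rec.product,
                              rec.yield_percent)
        a = reaction_forward(rec, tiny_params)
        b = reaction_forward(rec2, tiny_params)
        assert abs(a.mu - b.mu) <= 1e-6 * max(1.0, abs(a.mu))
        assert abs(a.log_var - b.log_var) <= 1e-6 * max(1.0, abs(a.log_var))

    def test_deterministic_without_dropout(self, tiny_params):
        rec = random_record(np.random.default_rng(8))
        a = reaction_forward(rec, tiny_params)
        b = reaction_forward(rec, tiny_params)
        assert a.mu == b.mu and a.log_var == b.log_var

    def test_dropout_streams_differ(self, tiny_params):
        rec = random_record(np.random.default_rng(9))
        a = reaction_forward(rec, tiny_params, dropout_active=True,
                             rng=np.random.default_rng(1))
        b = reaction_forward(rec, tiny_params, dropout_active=True,
                             rng=np.random.default_rng(2))
        assert (a.mu, a.log_var) != (b.mu, b.log_var)

    def test_dropout_requires_rng(self, tiny_params):
        rec = random_record(np.random.default_rng(10))
        with pytest.raises(ValueError):
            reaction_forward(rec, tiny_params, dropout_active=True)

    def test_duplicate_reactant_changes_representation(self, tiny_params):
        # sum aggregation over reactants is deliberately not idempotent
        rng = np.random.default_rng(11)
        g, prod = random_graph(rng), random_graph(rng)
        a = reaction_forward(ReactionRecord([g], prod, 10.0), tiny_params)
        b = reaction_forward(ReactionRecord([g, g], prod, 10.0), tiny_params)
        assert (a.mu, a.log_var) != (b.mu, b.log_var)

    def test_scalar_outputs_and_clamp(self, tiny_params):
        rec = random_record(np.random.default_rng(12))
        out = reaction_forward(rec, tiny_params)
        assert isinstance(out.mu, float) and isinstance(out.log_var, float)
        forced = ModelParams(tiny_params.dims,
                             {k: v.copy() for k, v in tiny_params.weights.items()})
        forced.weights["fnn_b3"][1] = 100.0
        assert reaction_forward(rec, forced).log_var == 10.0
        forced.weights["fnn_b3"][1] = -100.0
        assert reaction_forward(rec, forced).log_var == -10.0


def test_invariance_over_random_parameter_draws(feature_config):
    """Reactant-order and atom-order invariance across many random models."""
    from rdkit import Chem

    dims = ModelDims(p=feature_config.p, q=feature_config.q, node_dim=8,
                     edge_hidden=8, graph_dim=12, fnn_hidden=10, dropout=0.1)
    rng = np.random.default_rng(0)
    for trial in range(50):
        params = ModelParams.init(dims, trial)
        smis = list(rng.choice(SMILES_POOL, size=3, replace=False))
        graphs = [featurize_molecule(s, feature_config) for s in smis[:2]]
        product = featurize_molecule(smis[2], feature_config)
        rec = ReactionRecord(graphs, product, 50.0)
        base = reaction_forward(rec, params)

        shuffled = ReactionRecord(graphs[::-1], product, 50.0)
        # atom relabeling through RDKit's atom renumbering
        mol = Chem.MolFromSmiles(smis[2])
        order = [int(x) for x in rng.permutation(mol.GetNumAtoms())]
        relabeled_smi = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
        relabeled = ReactionRecord(
            graphs, featurize_molecule(relabeled_smi, feature_config), 50.0)

        for variant in (shuffled, relabeled):
            out = reaction_forward(variant, params)
            assert abs(out.mu - base.mu) <= 1e-6 * max(1.0, abs(base.mu))
            assert abs(out.log_var - base.log_var) <= 1e-6 * max(1.0, abs(base.log_var))


def test_checkpoint_roundtrip(tmp_path, feature_config):
    from rxnuq.training import StandardizationStats

    dims = ModelDims.reduced(p=feature_config.p, q=feature_config.q)
    params = ModelParams.init(dims, 3)
    stats = StandardizationStats(50.0, 25.0)
    path = tmp_path / "model.npz"
    save_checkpoint(path, params, feature_config, stats)
    params2, fc2, stats2 = load_checkpoint(path)
    assert fc2 == feature_config
    assert stats2 == stats
    assert params2.dims == dims
    for k, v in params.weights.items():
        assert np.array_equal(params2.weights[k], v)
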