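"""Dense NumPy implementation of the reaction-yield network.

The network maps a set of molecular graphs to a Gaussian predictive
distribution (mu, log sigma^2) for the reaction yield:

* a shared graph encoder: linear node embedding, 3 message-passing steps
  with an edge-network message function (a two-layer perceptron mapping the
  bond feature vector to a d x d matrix) and a GRU update, a set2set
  attention readout (3 processing steps), and a sparsifying linear+ReLU
  projection to the graph representation vector r;
* reaction assembly: r-vectors of the reactants are summed (permutation
  invariant) and concatenated with the product's r-vector;
* a feed-forward head with two hidden ReLU layers (dropout on both) and a
  two-unit output: predictive mean and log predictive variance.

Everything here operates on batches: the unique molecules of a batch are
packed into one :class:`GraphBatch` (concatenated node/edge arrays with
graph ids), encoded once, and reactions gather their molecule
representations through a sparse assembly matrix.  Reverse-mode gradients
for every module are hand-derived (`backward_batch`) and checked against
central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

LOG_VAR_MIN = -10.0
LOG_VAR_MAX = 10.0


@dataclass(frozen=True)
class ModelDims:
    """Architecture sizes.  Defaults follow the reference configuration:
    node dim 64, graph dim 1024, FNN 2x512, 3 message-passing and 3 set2set
    steps, dropout 0.1 on the FNN hidden layers.  The edge network's hidden
    width is not pinned down by the reference description; it is set to the
    node dimension."""

    p: int
    q: int
    node_dim: int = 64
    edge_hidden: int = 64
    graph_dim: int = 1024
    fnn_hidden: int = 512
    message_steps: int = 3
    s2s_steps: int = 3
    dropout: float = 0.1

    @classmethod
    def reduced(cls, p: int, q: int, **kwargs) -> "ModelDims":
        """A ~4x narrower model for desk-scale experiments."""
        defaults = dict(node_dim=16, edge_hidden=16, graph_dim=256, fnn_hidden=128)
        defaults.update(kwargs)
        return cls(p=p, q=q, **defaults)


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, shape)


class ModelParams:
    """All learnable arrays, keyed by name.  One shared graph encoder is
    used for reactants and product."""

    def __init__(self, dims: ModelDims, weights: dict):
        self.dims = dims
        self.weights = weights

    @classmethod
    def init(cls, dims: ModelDims, seed) -> "ModelParams":
        rng = np.random.default_rng(seed)
        p, q, d = dims.p, dims.q, dims.node_dim
        eh, D, H = dims.edge_hidden, dims.graph_dim, dims.fnn_hidden
        w = {
            "emb_W": _glorot(rng, (p, d)), "emb_b": np.zeros(d),
            "enet_W1": _glorot(rng, (q, eh)), "enet_b1": np.zeros(eh),
            "enet_W2": _glorot(rng, (eh, d * d)), "enet_b2": np.zeros(d * d),
            "gru_Wr": _glorot(rng, (d, d)), "gru_Ur": _glorot(rng, (d, d)),
            "gru_br": np.zeros(d),
            "gru_Wz": _glorot(rng, (d, d)), "gru_Uz": _glorot(rng, (d, d)),
            "gru_bz": np.zeros(d),
            "gru_Wn": _glorot(rng, (d, d)), "gru_bn": np.zeros(d),
            "gru_Un": _glorot(rng, (d, d)), "gru_bhn": np.zeros(d),
            "s2s_W": _glorot(rng, (2 * d, 4 * d)), "s2s_U": _glorot(rng, (d, 4 * d)),
            "s2s_b": np.zeros(4 * d),
            "proj_W": _glorot(rng, (2 * d, D)), "proj_b": np.zeros(D),
            "fnn_W1": _glorot(rng, (2 * D, H)), "fnn_b1": np.zeros(H),
            "fnn_W2": _glorot(rng, (H, H)), "fnn_b2": np.zeros(H),
            "fnn_W3": _glorot(rng, (H, 2)), "fnn_b3": np.zeros(2),
        }
        # standard LSTM trick: start with an open forget gate
        w["s2s_b"][dims.node_dim:2 * dims.node_dim] = 1.0
        return cls(dims, w)

    def copy(self) -> "ModelParams":
        return ModelParams(self.dims, {k: v.copy() for k, v in self.weights.items()})

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.weights.values()))


@dataclass
class GraphBatch:
    """A set of molecular graphs packed into flat arrays.

    Nodes of all graphs are concatenated; ``gid`` maps each node to its
    graph.  Each undirected bond is stored as two directed edges (both with
    the same bond feature vector) so that message aggregation is a single
    scatter-add over ``dst``.
    """

    node_x: np.ndarray       # (n, p)
    gid: np.ndarray          # (n,)
    src: np.ndarray          # (E,)
    dst: np.ndarray          # (E,)
    edge_x: np.ndarray       # (E, q); (0, 0) when the batch has no bonds
    n_graphs: int

    @property
    def n_nodes(self) -> int:
        return self.node_x.shape[0]

    @property
    def n_edges(self) -> int:
        return self.src.shape[0]

    @classmethod
    def from_graphs(cls, graphs: Sequence) -> "GraphBatch":
        xs, gids, srcs, dsts, efeats = [], [], [], [], []
        off = 0
        for gi, g in enumerate(graphs):
            n = g.n_nodes
            xs.append(g.node_features)
            gids.extend([gi] * n)
            for (j, k), feat in g.edge_features.items():
                srcs.extend((off + j, off + k))
                dsts.extend((off + k, off + j))
                efeats.extend((feat, feat))
            off += n
        node_x = np.vstack(xs)
        edge_x = np.array(efeats) if efeats else np.zeros((0, 0))
        return cls(
            node_x=node_x,
            gid=np.asarray(gids, dtype=np.intp),
            src=np.asarray(srcs, dtype=np.intp),
            dst=np.asarray(dsts, dtype=np.intp),
            edge_x=edge_x,
            n_graphs=len(graphs),
        )


def assemble_reactions(records: Sequence):
    """Collect the unique molecule graphs of ``records`` (by object
    identity) and build the reaction assembly: a sparse (B, n_graphs)
    matrix whose row i counts each graph's multiplicity among reaction i's
    reactants, plus the product graph index per reaction.  Summation (not
    averaging) over reactants follows the model definition."""
    index: dict = {}
    graphs: list = []

    def gidx(g):
        key = id(g)
        if key not in index:
            index[key] = len(graphs)
            graphs.append(g)
        return index[key]

    rows, cols, vals = [], [], []
    prod_idx = np.empty(len(records), dtype=np.intp)
    for i, rec in enumerate(records):
        counts: dict = {}
        for g in rec.reactants:
            j = gidx(g)
            counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(float(c))
        prod_idx[i] = gidx(rec.product)
    rsum = sp.csr_matrix((vals, (rows, cols)), shape=(len(records), len(graphs)))
    return graphs, rsum, prod_idx


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _segment_softmax(e, gid, n_graphs):
    mx = np.full(n_graphs, -np.inf)
    np.maximum.at(mx, gid, e)
    ex = np.exp(e - mx[gid])
    s = np.zeros(n_graphs)
    np.add.at(s, gid, ex)
    return ex / s[gid]


def _edge_net_forward(w, edge_x, d):
    pre = edge_x @ w["enet_W1"] + w["enet_b1"]
    hid = np.maximum(pre, 0.0)
    flat = hid @ w["enet_W2"] + w["enet_b2"]
    return flat.reshape(edge_x.shape[0], d, d), (pre > 0, hid)


def _gru_forward(w, h, m):
    r = expit(m @ w["gru_Wr"] + h @ w["gru_Ur"] + w["gru_br"])
    z = expit(m @ w["gru_Wz"] + h @ w["gru_Uz"] + w["gru_bz"])
    u = h @ w["gru_Un"] + w["gru_bhn"]
    c = np.tanh(m @ w["gru_Wn"] + w["gru_bn"] + r * u)
    h_new = (1.0 - z) * c + z * h
    return h_new, (h, m, r, z, u, c)


def _mp_forward(params, batch, h0, steps=None):
    """Message passing: m_v = sum_w A(e_{vw}) h_w, then h_v <- GRU(h_v, m_v).
    Edge-network and GRU weights are shared across steps."""
    w, d = params.weights, params.dims.node_dim
    steps = params.dims.message_steps if steps is None else steps
    if batch.n_edges:
        A, ecache = _edge_net_forward(w, batch.edge_x, d)
    else:
        A, ecache = np.zeros((0, d, d)), None
    h = h0
    step_caches = []
    for _ in range(steps):
        if batch.n_edges:
            msg_e = np.einsum("eij,ej->ei", A, h[batch.src])
            m = np.zeros((batch.n_nodes, d))
            np.add.at(m, batch.dst, msg_e)
        else:
            m = np.zeros((batch.n_nodes, d))
        h, gc = _gru_forward(w, h, m)
        step_caches.append(gc)
    return h, (A, ecache, step_caches)


def _s2s_forward(params, node_h, gid, n_graphs, steps=None):
    """set2set readout: an LSTM produces a query; attention over node states
    (unscaled dot-product logits, softmax per graph) produces a read vector;
    [query, read] feeds the next step.  Query initialised to zeros."""
    w, d = params.weights, params.dims.node_dim
    steps = params.dims.s2s_steps if steps is None else steps
    qstar = np.zeros((n_graphs, 2 * d))
    hS = np.zeros((n_graphs, d))
    cS = np.zeros((n_graphs, d))
    caches = []
    for _ in range(steps):
        gates = qstar @ w["s2s_W"] + hS @ w["s2s_U"] + w["s2s_b"]
        i = expit(gates[:, :d])
        f = expit(gates[:, d:2 * d])
        g = np.tanh(gates[:, 2 * d:3 * d])
        o = expit(gates[:, 3 * d:])
        cS_new = f * cS + i * g
        tc = np.tanh(cS_new)
        hS_new = o * tc
        e = (node_h * hS_new[gid]).sum(axis=1)
        a = _segment_softmax(e, gid, n_graphs)
        read = np.zeros((n_graphs, d))
        np.add.at(read, gid, a[:, None] * node_h)
        caches.append((qstar, hS, cS, i, f, g, o, tc, hS_new, a))
        qstar = np.concatenate([hS_new, read], axis=1)
        hS, cS = hS_new, cS_new
    return qstar, caches


def _graphs_forward(params, batch, steps=None, s2s_steps=None):
    w = params.weights
    h0 = batch.node_x @ w["emb_W"] + w["emb_b"]
    hN, mp_cache = _mp_forward(params, batch, h0, steps=steps)
    qstar, s2s_cache = _s2s_forward(params, hN, batch.gid, batch.n_graphs,
                                    steps=s2s_steps)
    pre = qstar @ w["proj_W"] + w["proj_b"]
    rg = np.maximum(pre, 0.0)
    return rg, (hN, mp_cache, s2s_cache, qstar, pre > 0)


def draw_dropout_masks(rng, n_rows, dims: ModelDims):
    """Inverted-dropout masks for the two FNN hidden layers (already scaled
    by 1/keep so the expected activation is unchanged)."""
    if dims.dropout <= 0.0:
        return None
    keep = 1.0 - dims.dropout
    m1 = (rng.random((n_rows, dims.fnn_hidden)) >= dims.dropout) / keep
    m2 = (rng.random((n_rows, dims.fnn_hidden)) >= dims.dropout) / keep
    return m1, m2


def _head_forward(params, rg, rsum, prod_idx, masks):
    w, D = params.weights, params.dims.graph_dim
    Hsum = np.asarray(rsum @ rg)
    Hr = np.concatenate([Hsum, rg[prod_idx]], axis=1)
    m1, m2 = masks if masks is not None else (1.0, 1.0)
    a1p = Hr @ w["fnn_W1"] + w["fnn_b1"]
    a1d = np.maximum(a1p, 0.0) * m1
    a2p = a1d @ w["fnn_W2"] + w["fnn_b2"]
    a2d = np.maximum(a2p, 0.0) * m2
    out = a2d @ w["fnn_W3"] + w["fnn_b3"]
    mu = out[:, 0]
    lv_raw = out[:, 1]
    lv = np.clip(lv_raw, LOG_VAR_MIN, LOG_VAR_MAX)
    cache = (Hr, a1p > 0, a1d, a2p > 0, a2d, m1, m2, lv_raw)
    return mu, lv, cache


def forward_batch(params: ModelParams, batch: GraphBatch, rsum, prod_idx,
                  masks=None):
    """Full forward pass for a batch of reactions.

    Returns ``(mu, log_var, cache)`` in standardized-yield units; ``cache``
    feeds :func:`backward_batch`.
    """
    if batch.node_x.shape[1] != params.dims.p:
        raise ValueError(
            f"node feature length {batch.node_x.shape[1]} != model p {params.dims.p}")
    if batch.n_edges and batch.edge_x.shape[1] != params.dims.q:
        raise ValueError(
            f"bond feature length {batch.edge_x.shape[1]} != model q {params.dims.q}")
    rg, gcache = _graphs_forward(params, batch)
    mu, lv, hcache = _head_forward(params, rg, rsum, prod_idx, masks)
    return mu, lv, (gcache, hcache)


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def backward_batch(params, batch, rsum, prod_idx, cache, dmu, dlv_raw):
    """Hand-derived reverse-mode gradients of the full forward pass.

    ``dmu`` / ``dlv_raw`` are the loss gradients w.r.t. the head outputs
    (the caller zeroes ``dlv_raw`` where the log-variance clamp is active).
    Returns a dict of gradients keyed like ``params.weights``.
    """
    w, dims = params.weights, params.dims
    d, D = dims.node_dim, dims.graph_dim
    (hN, mp_cache, s2s_cache, qstar_final, proj_mask), hcache = cache
    (Hr, a1_mask, a1d, a2_mask, a2d, m1, m2, _lv_raw) = hcache
    grads = {k: np.zeros_like(v) for k, v in w.items()}

    # FNN head
    dout = np.stack([dmu, dlv_raw], axis=1)
    grads["fnn_W3"] += a2d.T @ dout
    grads["fnn_b3"] += dout.sum(axis=0)
    da2 = (dout @ w["fnn_W3"].T) * m2 * a2_mask
    grads["fnn_W2"] += a1d.T @ da2
    grads["fnn_b2"] += da2.sum(axis=0)
    da1 = (da2 @ w["fnn_W2"].T) * m1 * a1_mask
    grads["fnn_W1"] += Hr.T @ da1
    grads["fnn_b1"] += da1.sum(axis=0)
    dHr = da1 @ w["fnn_W1"].T

    # reaction assembly
    drg = np.asarray(rsum.T @ dHr[:, :D])
    np.add.at(drg, prod_idx, dHr[:, D:])

    # graph projection
    dpre = drg * proj_mask
    grads["proj_W"] += qstar_final.T @ dpre
    grads["proj_b"] += dpre.sum(axis=0)
    dqstar = dpre @ w["proj_W"].T

    # set2set (reverse through the processing steps)
    gid = batch.gid
    dnode_h = np.zeros_like(hN)
    dhS_carry = np.zeros((batch.n_graphs, d))
    dcS_carry = np.zeros((batch.n_graphs, d))
    for (qstar_prev, hS_prev, cS_prev, i, f, g, o, tc, hS_new, a) in reversed(s2s_cache):
        dhS = dqstar[:, :d] + dhS_carry
        dread = dqstar[:, d:]
        # read = sum_v a_v h_v
        dr_rows = dread[gid]
        da = (dr_rows * hN).sum(axis=1)
        dnode_h += a[:, None] * dr_rows
        # softmax over logits e_v = <h_v, q>
        inner = np.zeros(batch.n_graphs)
        np.add.at(inner, gid, a * da)
        de = a * (da - inner[gid])
        dnode_h += de[:, None] * hS_new[gid]
        np.add.at(dhS, gid, de[:, None] * hN)
        # LSTM cell
        do = dhS * tc
        dc = dhS * o * (1.0 - tc ** 2) + dcS_carry
        df = dc * cS_prev
        dcS_carry = dc * f
        di = dc * g
        dg = dc * i
        dgates = np.concatenate(
            [di * i * (1.0 - i), df * f * (1.0 - f),
             dg * (1.0 - g ** 2), do * o * (1.0 - o)], axis=1)
        grads["s2s_W"] += qstar_prev.T @ dgates
        grads["s2s_U"] += hS_prev.T @ dgates
        grads["s2s_b"] += dgates.sum(axis=0)
        dqstar = dgates @ w["s2s_W"].T
        dhS_carry = dgates @ w["s2s_U"].T
    # initial qstar / hS / cS are constants (zeros): remaining carries drop.

    # message passing (reverse through the shared-weight steps)
    A, ecache, step_caches = mp_cache
    dh = dnode_h
    dA = np.zeros_like(A)
    for (h_prev, m, r, z, u, c) in reversed(step_caches):
        dz = dh * (h_prev - c)
        dc_ = dh * (1.0 - z)
        dh_prev = dh * z
        dn_pre = dc_ * (1.0 - c ** 2)
        grads["gru_Wn"] += m.T @ dn_pre
        grads["gru_bn"] += dn_pre.sum(axis=0)
        dm = dn_pre @ w["gru_Wn"].T
        dr = dn_pre * u
        du = dn_pre * r
        grads["gru_Un"] += h_prev.T @ du
        grads["gru_bhn"] += du.sum(axis=0)
        dh_prev += du @ w["gru_Un"].T
        dz_pre = dz * z * (1.0 - z)
        grads["gru_Wz"] += m.T @ dz_pre
        grads["gru_Uz"] += h_prev.T @ dz_pre
        grads["gru_bz"] += dz_pre.sum(axis=0)
        dm += dz_pre @ w["gru_Wz"].T
        dh_prev += dz_pre @ w["gru_Uz"].T
        dr_pre = dr * r * (1.0 - r)
        grads["gru_Wr"] += m.T @ dr_pre
        grads["gru_Ur"] += h_prev.T @ dr_pre
        grads["gru_br"] += dr_pre.sum(axis=0)
        dm += dr_pre @ w["gru_Wr"].T
        dh_prev += dr_pre @ w["gru_Ur"].T
        if batch.n_edges:
            dmsg_e = dm[batch.dst]
            hs = h_prev[batch.src]
            dA += dmsg_e[:, :, None] * hs[:, None, :]
            dhs = np.einsum("eij,ei->ej", A, dmsg_e)
            np.add.at(dh_prev, batch.src, dhs)
        dh = dh_prev

    # node embedding
    grads["emb_W"] += batch.node_x.T @ dh
    grads["emb_b"] += dh.sum(axis=0)

    # edge network (A reused across steps; gradients accumulated above)
    if batch.n_edges:
        pre_mask, hid = ecache
        dA_flat = dA.reshape(batch.n_edges, d * d)
        grads["enet_W2"] += hid.T @ dA_flat
        grads["enet_b2"] += dA_flat.sum(axis=0)
        dpre_e = (dA_flat @ w["enet_W2"].T) * pre_mask
        grads["enet_W1"] += batch.edge_x.T @ dpre_e
        grads["enet_b1"] += dpre_e.sum(axis=0)
    return grads


def blended_loss_and_output_grads(y_std, mu, lv, lv_raw, lam):
    """Per-batch blended objective (standardized units) and its gradients
    w.r.t. the head outputs: (1-lam)*mean((y-mu)^2) + lam*mean((y-mu)^2 *
    exp(-lv) + lv).  The gradient w.r.t. the raw log-variance is zeroed
    where the clamp is active."""
    resid = y_std - mu
    inv = np.exp(-lv)
    loss = float(np.mean((1.0 - lam) * resid ** 2
                         + lam * (resid ** 2 * inv + lv)))
    n = len(y_std)
    dmu = (-2.0 * (1.0 - lam) * resid - 2.0 * lam * resid * inv) / n
    dlv = lam * (1.0 - resid ** 2 * inv) / n
    clamp_open = (lv_raw > LOG_VAR_MIN) & (lv_raw < LOG_VAR_MAX)
    return loss, dmu, dlv * clamp_open


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, weights, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for k, gk in grads.items():
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * gk
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * gk ** 2
            weights[k] -= lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2)
                                                      + self.eps)
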