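"""Permutation-invariant reaction representation and the (mu, log sigma^2) head.

Public, single-graph/single-reaction views over the batched network in
:mod:`rxnuq.nnet`.  The graph encoder is shared between reactants and the
product; the reaction representation is the sum of reactant graph vectors
concatenated with the product graph vector, which makes the output
invariant both to reactant order and to atom relabeling within each
molecule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .chemio import FeatureConfig, MolecularGraph, ReactionRecord
from .nnet import (
    LOG_VAR_MAX,
    LOG_VAR_MIN,
    Adam,
    GraphBatch,
    ModelDims,
    ModelParams,
    assemble_reactions,
    draw_dropout_masks,
    forward_batch,
    _graphs_forward,
    _mp_forward,
    _s2s_forward,
)

__all__ = [
    "ModelDims", "ModelParams", "PredictiveOutput",
    "embed_nodes", "message_passing", "set2set_readout", "graph_repr",
    "reaction_forward", "save_checkpoint", "load_checkpoint",
]


@dataclass
class PredictiveOutput:
    """One stochastic forward pass: predictive mean and log variance in
    standardized-yield units.  ``log_var`` is clamped to [-10, 10]."""

    mu: float
    log_var: float

    @property
    def var(self) -> float:
        return float(np.exp(self.log_var))


def embed_nodes(graph: MolecularGraph, params: ModelParams) -> np.ndarray:
    """Initial node states: a learned affine map of the atom features."""
    if graph.node_features.shape[1] != params.dims.p:
        raise ValueError(
            f"node feature length {graph.node_features.shape[1]} "
            f"!= model p {params.dims.p}")
    w = params.weights
    return graph.node_features @ w["emb_W"] + w["emb_b"]


def message_passing(graph: MolecularGraph, node_states: np.ndarray,
                    params: ModelParams, steps: int | None = None) -> np.ndarray:
    """Run the edge-network/GRU message-passing recurrence on one graph."""
    batch = GraphBatch.from_graphs([graph])
    h, _ = _mp_forward(params, batch, np.asarray(node_states, dtype=float),
                       steps=steps)
    return h


def set2set_readout(node_states: np.ndarray, params: ModelParams,
                    steps: int | None = None) -> np.ndarray:
    """Order-invariant pooled vector (length 2d) over a set of node states."""
    node_states = np.asarray(node_states, dtype=float)
    if node_states.ndim != 2 or node_states.shape[0] < 1:
        raise ValueError("set2set_readout needs at least one node state")
    gid = np.zeros(node_states.shape[0], dtype=np.intp)
    qstar, _ = _s2s_forward(params, node_states, gid, 1, steps=steps)
    return qstar[0]


def graph_repr(graph: MolecularGraph, params: ModelParams) -> np.ndarray:
    """Graph representation vector r = proj(set2set(MP(embed(G)))); invariant
    to node relabeling."""
    batch = GraphBatch.from_graphs([graph])
    rg, _ = _graphs_forward(params, batch)
    return rg[0]


def reaction_forward(record: ReactionRecord, params: ModelParams,
                     dropout_active: bool = False,
                     rng=None) -> PredictiveOutput:
    """One forward pass of a reaction through the full network.

    With ``dropout_active`` the two FNN hidden layers are dropped at the
    configured rate using ``rng`` (a seeded ``numpy.random.Generator``),
    giving a stochastic pass for MC-dropout; otherwise the pass is
    deterministic.
    """
    graphs, rsum, prod_idx = assemble_reactions([record])
    batch = GraphBatch.from_graphs(graphs)
    masks = None
    if dropout_active:
        if rng is None:
            raise ValueError("dropout_active requires a seeded rng")
        masks = draw_dropout_masks(rng, 1, params.dims)
    mu, lv, _ = forward_batch(params, batch, rsum, prod_idx, masks=masks)
    return PredictiveOutput(float(mu[0]), float(lv[0]))


def save_checkpoint(path, params: ModelParams, feature_config: FeatureConfig,
                    stats=None) -> None:
    """Serialize model weights with the feature config (and optional yield
    standardization stats) embedded, so a checkpoint is self-describing."""
    from dataclasses import asdict

    meta = {
        "dims": asdict(params.dims),
        "feature_config": feature_config.to_dict(),
        "stats": None if stats is None else {"mean_percent": stats.mean_percent,
                                             "std_percent": stats.std_percent},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **params.weights)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`.  Returns
    ``(params, feature_config, stats_or_None)``."""
    from .training import StandardizationStats

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        weights = {k: data[k] for k in data.files if k != "__meta__"}
    dims = ModelDims(**meta["dims"])
    params = ModelParams(dims, weights)
    fc = FeatureConfig.from_dict(meta["feature_config"])
    stats = None
    if meta["stats"] is not None:
        stats = StandardizationStats(meta["stats"]["mean_percent"],
                                     meta["stats"]["std_percent"])
    return params, fc, stats
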