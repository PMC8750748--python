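"""MC-dropout prediction with aleatoric/epistemic variance decomposition.

At inference, dropout stays active and the network is sampled T times
(default 30).  With per-pass outputs (mu_t, sigma_t^2):

    prediction      mean      = (1/T) sum_t mu_t
    aleatoric var             = (1/T) sum_t sigma_t^2
    epistemic var             = (1/T) sum_t (mu_t - mean)^2
    total predictive variance = aleatoric + epistemic

The aleatoric part reflects irreducible data noise (what the variance head
learned); the epistemic part reflects model disagreement across dropout
masks.  All quantities are reported on the percent scale: means via
``mu * std + mean``, variances via ``var * std^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nnet import (
    GraphBatch,
    ModelParams,
    assemble_reactions,
    draw_dropout_masks,
    _graphs_forward,
    _head_forward,
)
from .training import StandardizationStats

__all__ = ["MCPredictive", "decompose", "destandardize",
           "mc_predict", "mc_predict_records"]


@dataclass
class MCPredictive:
    """T sampled (mu, sigma^2) pairs (percent scale) and the derived
    prediction and uncertainty decomposition.  ``total`` equals
    ``aleatoric + epistemic`` exactly (same floating summation)."""

    mu_samples: np.ndarray
    var_samples: np.ndarray
    mean: float
    aleatoric: float
    epistemic: float
    total: float

    @property
    def T(self) -> int:
        return len(self.mu_samples)


def decompose(mu_samples, var_samples):
    """Split MC samples into (aleatoric, epistemic, total) variances using
    the population (1/T) convention for the epistemic term."""
    mu = np.asarray(mu_samples, dtype=float)
    var = np.asarray(var_samples, dtype=float)
    if mu.shape != var.shape:
        raise ValueError("mu_samples and var_samples must have equal length")
    if mu.size == 0:
        raise ValueError("need at least one sample")
    aleatoric = float(np.mean(var))
    if np.all(mu == mu[0]):
        epistemic = 0.0  # exact, regardless of mean rounding
    else:
        epistemic = float(np.mean((mu - np.mean(mu)) ** 2))
    return aleatoric, epistemic, aleatoric + epistemic


def destandardize(mu_std: float, var_std: float, stats: StandardizationStats):
    """Map a standardized (mean, variance) pair back to the percent scale."""
    return (mu_std * stats.std_percent + stats.mean_percent,
            var_std * stats.std_percent ** 2)


def _pass_seed_rng(base_seed: int, t: int):
    # deterministic child stream (base_seed, t): full MC runs are reproducible
    return np.random.default_rng(np.random.SeedSequence(base_seed).spawn(t + 1)[t])


def mc_predict_records(records: Sequence, params: ModelParams,
                       stats: StandardizationStats, T: int = 30,
                       seed: int = 0) -> list:
    """MC-dropout prediction for a batch of reactions.

    The graph encoder carries no dropout, so molecule representations are
    computed once; the stochastic FNN head is then sampled T times with
    independent, seed-derived mask streams.  Returns one
    :class:`MCPredictive` per record (percent scale).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    graphs, rsum, prod_idx = assemble_reactions(records)
    batch = GraphBatch.from_graphs(graphs)
    rg, _ = _graphs_forward(params, batch)

    B = len(records)
    mu_s = np.empty((T, B))
    var_s = np.empty((T, B))
    for t in range(T):
        masks = draw_dropout_masks(_pass_seed_rng(seed, t), B, params.dims)
        mu, lv, _ = _head_forward(params, rg, rsum, prod_idx, masks)
        mu_s[t] = mu
        var_s[t] = np.exp(lv)

    # percent scale first, then decompose, so the additive identity holds
    # exactly on the reported scale
    mu_pct = mu_s * stats.std_percent + stats.mean_percent
    var_pct = var_s * stats.std_percent ** 2
    out = []
    for b in range(B):
        aleatoric, epistemic, total = decompose(mu_pct[:, b], var_pct[:, b])
        out.append(MCPredictive(
            mu_samples=mu_pct[:, b].copy(),
            var_samples=var_pct[:, b].copy(),
            mean=float(np.mean(mu_pct[:, b])),
            aleatoric=aleatoric,
            epistemic=epistemic,
            total=total,
        ))
    return out


def mc_predict(record, params: ModelParams, stats: StandardizationStats,
               T: int = 30, seed: int = 0) -> MCPredictive:
    """MC-dropout prediction for a single reaction (see
    :func:`mc_predict_records`)."""
    return mc_predict_records([record], params, stats, T=T, seed=seed)[0]
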