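"""Yield standardization, the blended Gaussian objective, and model fitting.

The training objective blends a homoscedastic term (plain MSE, which
stabilises the predictive mean) with the heteroscedastic Gaussian negative
log-likelihood (which lets the predicted variance absorb input-dependent
noise):

    J = (1 - lambda) * mean_i (y_i - mu_i)^2
        + lambda * mean_i [ (y_i - mu_i)^2 / sigma_i^2 + log sigma_i^2 ]

with lambda in [0, 1] (default 0.1).  The constant -log(2 pi)/2 of the
exact Gaussian log-density is dropped; it does not affect the optimum.
Yields are standardized to zero mean / unit variance over the training set
before optimisation, so the objective operates on standardized units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chemio import FeatureConfig
from .nnet import (
    Adam,
    GraphBatch,
    ModelDims,
    ModelParams,
    assemble_reactions,
    backward_batch,
    blended_loss_and_output_grads,
    draw_dropout_masks,
    forward_batch,
)

__all__ = [
    "StandardizationStats", "TrainConfig",
    "standardize", "nll_term", "objective", "fit",
]


@dataclass(frozen=True)
class StandardizationStats:
    """Population mean and standard deviation of training yields (percent)."""

    mean_percent: float
    std_percent: float

    def __post_init__(self):
        if not (self.std_percent > 0):
            raise ValueError("std_percent must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.  Defaults follow the reference schedule:
    lambda 0.1, 500 epochs, batch size 128, Adam at 1e-3 decayed to 1e-4 and
    1e-5 over the last fifth of training, L2 factor 1e-5 on weights,
    dropout 0.1 on the FNN hidden layers."""

    lam: float = 0.1
    epochs: int = 500
    batch_size: int = 128
    lr_levels: tuple = (1e-3, 1e-4, 1e-5)
    lr_boundaries: tuple = (0.8, 0.9)  # fractions of total epochs
    l2_factor: float = 1e-5
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must be in [0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    def lr_at(self, epoch: int) -> float:
        frac = epoch / self.epochs
        if frac < self.lr_boundaries[0]:
            return self.lr_levels[0]
        if frac < self.lr_boundaries[1]:
            return self.lr_levels[1]
        return self.lr_levels[2]


def standardize(yields_percent: Sequence[float],
                stats: Optional[StandardizationStats] = None):
    """Map yields to zero mean / unit variance units.

    Fit mode (``stats is None``) computes the population mean and standard
    deviation from the given values; apply mode reuses training-set stats.
    Returns ``(standardized_array, stats)``.
    """
    y = np.asarray(yields_percent, dtype=float)
    if stats is None:
        if y.size < 2:
            raise ValueError("need at least 2 values to fit standardization")
        std = float(np.std(y))  # population (1/N) convention
        if std == 0.0:
            raise ValueError("zero variance: yields are constant")
        stats = StandardizationStats(float(np.mean(y)), std)
    return (y - stats.mean_percent) / stats.std_percent, stats


def nll_term(y: float, mu: float, log_var: float) -> float:
    """Heteroscedastic Gaussian NLL contribution (constant dropped):
    (y - mu)^2 / sigma^2 + log sigma^2."""
    return float((y - mu) ** 2 * math.exp(-log_var) + log_var)


def objective(batch: Sequence, lam: float) -> float:
    """Blended objective over a batch of ``(y, mu, log_var)`` triples:
    (1 - lam) * mean squared error + lam * mean NLL term."""
    if len(batch) == 0:
        raise ValueError("objective of an empty batch is undefined")
    mse = float(np.mean([(y - mu) ** 2 for y, mu, _ in batch]))
    nll = float(np.mean([nll_term(y, mu, lv) for y, mu, lv in batch]))
    return (1.0 - lam) * mse + lam * nll


def fit(train: Sequence, config: TrainConfig, feature_config: FeatureConfig,
        dims: Optional[ModelDims] = None):
    """Fit model parameters on a training set of reaction records.

    Yields are standardized (population convention) and the blended
    objective is minimised with Adam under the piecewise-constant learning
    rate schedule; the L2 penalty (weights only, not biases) enters the
    gradients but never the reported history.  All randomness — parameter
    initialisation, epoch shuffling, dropout — derives from ``config.seed``.

    Returns ``(params, stats, history)`` where ``history[e]`` is the
    sample-weighted mean of the pre-update minibatch data losses of epoch
    ``e`` (standardized units); it trends downward but is not guaranteed
    monotone.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    for rec in train:
        if rec.yield_percent is None:
            raise ValueError("every training record needs a yield")

    y = np.array([rec.yield_percent for rec in train], dtype=float)
    y_std, stats = standardize(y)

    if dims is None:
        dims = ModelDims(p=feature_config.p, q=feature_config.q,
                         dropout=config.dropout)
    if dims.p != feature_config.p or dims.q != feature_config.q:
        raise ValueError("model dims do not match the feature config")

    init_ss, shuffle_ss, drop_ss = np.random.SeedSequence(config.seed).spawn(3)
    params = ModelParams.init(dims, init_ss)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    drop_rng = np.random.default_rng(drop_ss)

    graphs, rsum_all, prod_all = assemble_reactions(train)
    batch_graphs = GraphBatch.from_graphs(graphs)

    adam = Adam(params.weights)
    n = len(train)
    history = []
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            rsum = rsum_all[idx]
            prod = prod_all[idx]
            masks = draw_dropout_masks(drop_rng, len(idx), dims)
            mu, lv, cache = forward_batch(params, batch_graphs, rsum, prod,
                                          masks=masks)
            lv_raw = cache[1][-1]
            loss, dmu, dlv = blended_loss_and_output_grads(
                y_std[idx], mu, lv, lv_raw, config.lam)
            grads = backward_batch(params, batch_graphs, rsum, prod, cache,
                                   dmu, dlv)
            if config.l2_factor:
                for k, wk in params.weights.items():
                    if "_b" not in k:  # weights only, not biases
                        grads[k] = grads[k] + 2.0 * config.l2_factor * wk
            adam.step(params.weights, grads, lr)
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    return params, stats, history
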