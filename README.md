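# rxnuq — uncertainty-aware reaction yield prediction

`rxnuq` predicts the yield of an organic reaction (0–100 %) from the
structures of its reactants and product, and says **how much to trust each
prediction**. It is aimed at synthesis planning over high-throughput
reaction datasets (e.g. Pd-catalyzed cross-coupling screens), where a model
that can *abstain* on its most uncertain predictions is far more useful
than one that only returns a point estimate.

## Model

A reaction is a set of molecular graphs `(R = {G1..Gm}, P)` plus a yield
`y`. The predictive distribution is Gaussian,

    p_θ(y | R, P) = N(y | μ, σ²),     (μ, log σ²) = f(R, P; θ)

where `f` is a graph neural network:

* **Graph encoder** (shared by reactants and product): atoms and bonds are
  featurized with RDKit (element, charge, degree, hybridization, H-count,
  valence, chirality, donor/acceptor, aromaticity, ring membership and ring
  sizes; bond type, stereo, ring, conjugation). Three message-passing steps
  use an *edge network* (bond features → d×d matrix) as message function
  and a GRU as update; a *set2set* attention readout (3 steps) pools node
  states order-invariantly; a linear+ReLU layer produces the graph vector
  `r` (node dim 64, graph dim 1024 by default).
* **Reaction representation**: `h = [Σ_l r^{R,l}, r^P]` — summing over
  reactants makes the output invariant to reactant order; the GNN makes it
  invariant to atom relabeling.
* **Head**: a feed-forward network (2×512, ReLU, dropout 0.1) with two
  outputs: the predictive mean μ and log-variance log σ².

**Training** minimises a blend of homoscedastic and heteroscedastic losses,

    J(θ) = (1−λ)·mean (y−μ)² + λ·mean [ (y−μ)²/σ² + log σ² ],   λ = 0.1

on yields standardized to zero mean / unit variance (Adam, 500 epochs,
batch 128, lr 1e-3→1e-4→1e-5, L2 1e-5).

**Inference** uses MC dropout: T = 30 stochastic passes give

    mean      = (1/T) Σ μ̂_t
    aleatoric = (1/T) Σ σ̂²_t            (data noise)
    epistemic = (1/T) Σ (μ̂_t − mean)²   (model uncertainty)
    total     = aleatoric + epistemic

The total predictive variance is the uncertainty score for **selective
prediction**: at coverage c the ⌈c·n⌉ least-uncertain predictions are kept
and the rest rejected for human review.

The whole network, including reverse-mode gradients, is implemented
directly on NumPy arrays and verified against finite differences in the
test suite.

## Worked example

```bash
rxnuq synth --n 2000 --seed 1 --out reactions.csv --truth truth.csv
rxnuq train --data reactions.csv --lam 0.1 --epochs 100 --seed 0 \
            --node-dim 16 --graph-dim 256 --fnn-hidden 128 --out model.npz
rxnuq predict --model model.npz --data reactions.csv --t 30 --seed 0 \
              --out predictions.csv
rxnuq evaluate --pred predictions.csv --truth reactions.csv
```

The synthetic generator emulates a combinatorial screen (8 aryl cores × 4
ligands × 3 bases) whose noise depends on the base (σ = 2, 2, 12 %p).
Equivalent library code on a held-out 30 % split (600 reactions, seed 1)
prints:

```
n=600  MAE=4.560  RMSE=7.508  R2=0.747  Spearman rho=0.541
 coverage   kept      MAE     RMSE
     100%    600    4.560    7.508
      50%    300    1.685    2.135
      30%    180    1.735    2.223
```

Read: across all 600 test reactions the mean absolute error is 4.6 yield
points, and the error–uncertainty rank correlation (ρ = 0.54) means the
model knows *which* predictions are bad — keeping only the more certain
half drops the MAE to 1.7. The predicted aleatoric SD per designed noise
group comes out at 2.5 and 11.7 against the true 2 and 12.

## Layout

| module | contents |
|---|---|
| `rxnuq.chemio` | SMILES → featurized graphs, reaction CSV reader, random and out-of-sample splits |
| `rxnuq.gnn_core` | model parameters, message passing, set2set, reaction forward pass, checkpoints |
| `rxnuq.nnet` | batched NumPy forward/backward passes, Adam |
| `rxnuq.training` | yield standardization, blended objective, `fit` |
| `rxnuq.uq_inference` | MC-dropout prediction and variance decomposition |
| `rxnuq.evaluation` | MAE/RMSE/R², Spearman ρ, coverage sweep |
| `rxnuq.synthdata` | synthetic combinatorial datasets with known noise groups |
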