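# Methods

## Model

A reaction is `(R, P, y)`: a set of `m ≥ 1` reactant graphs, one product
graph, and a yield in percent. The predictive distribution is a Gaussian
whose mean and log-variance are produced jointly by one network. The
architecture, in evaluation order:

1. **Featurization.** One node per heavy atom (hydrogens are implicit,
   encoded as a capped H-count one-hot), one undirected edge per bond.
   Atom vector (`p` entries): element one-hot over a configurable
   vocabulary with a fallback slot, formal charge (−2…+2 + other), degree
   (0–5 + overflow), hybridization, H-count (0–4), total valence (0–6 +
   overflow), chiral tag, donor/acceptor flags (RDKit's pharmacophore
   feature definitions), aromatic and in-ring flags, and ring-size
   membership flags for sizes 3–8 plus a larger-ring flag. Bond vector
   (`q = 12`): bond-type and stereo one-hots (each with a fallback slot),
   in-ring and conjugation flags. The element vocabulary is frozen when the
   config is created (`FeatureConfig.from_smiles`), so `p` is
   data-determined but cannot drift between training and test.
2. **Node embedding**: affine map `p → d`, `d = 64` by default.
3. **Message passing**, 3 steps with shared weights:
   `m_v = Σ_{w∈N(v)} A(e_{vw}) h_w`, where the edge network `A` is a
   two-layer ReLU perceptron mapping the bond vector to a `d × d` matrix
   (hidden width set to `d`; not pinned down by the reference
   description), followed by a GRU update `h_v ← GRU(h_v, m_v)`. Bond
   features do not change between steps, so `A` is computed once per pass.
4. **set2set readout**, 3 steps: an LSTM (input `2d`, state `d`,
   forget-gate bias initialised to 1) produces a query from the previous
   `[query, read]`; attention weights are a per-graph softmax of unscaled
   dot products between the query and node states; the read vector is the
   attention-weighted sum. The query starts at zero. Output: the final
   `[query, read]` (length `2d`), invariant to node order.
5. **Graph projection**: linear + ReLU, `2d → 1024` ("sparsifying" layer).
6. **Reaction representation**: `h = [Σ_l r^{R,l}, r^P]` (length 2048).
   Summation — not averaging — over reactants is deliberate: duplicating a
   reactant changes the representation. One graph encoder is shared by
   reactants and product; the concatenation already separates the roles,
   and sharing halves the parameter count.
7. **Head**: 2048 → 512 → 512 → 2 with ReLU and dropout 0.1 on both hidden
   layers (the only dropout in the model). Outputs: μ and log σ² in
   standardized-yield units. No output activation or clipping is applied
   to μ. log σ² is clamped to [−10, 10] before exponentiation — the
   heteroscedastic objective is unstable early in training when σ² can
   collapse or explode; the clamp gradient is zeroed where active.

## Training

Yields are standardized to zero mean and unit variance using the
**population** (1/N) standard deviation of the training split only. The
objective blends the homoscedastic and heteroscedastic losses,

    J = (1−λ)·mean (y−μ)² + λ·mean [(y−μ)² e^{−log σ²} + log σ²],

computed on the standardized scale (training operates on standardized
targets throughout), with λ = 0.1 by default: the MSE term stabilises the
mean, the NLL term lets σ² absorb input-dependent noise. The Gaussian
log-density constant −½·log 2π is dropped; it shifts the objective without
moving its optimum.

Optimisation: Adam, 500 epochs, batch size 128 (the last incomplete batch
is kept — small-training-set regimes matter), learning rate piecewise
constant at 1e-3 for the first 80 % of epochs, 1e-4 for the next 10 %, and
1e-5 for the last 10 % (for 500 epochs: 1–400 / 401–450 / 451–500). L2
regularization (factor 1e-5) is applied to weight matrices, not biases,
and enters the gradients only — the reported per-epoch history is the
sample-weighted mean of the *pre-update* minibatch data losses, so it is a
pure data term. All randomness (initialisation, shuffling, dropout masks)
derives from a single seed via spawned generator streams; identical seeds
reproduce identical histories and parameters. No early stopping, no
hyperparameter search, no warmup, no gradient clipping beyond the
log-variance clamp.

The network and its reverse-mode gradients are implemented directly on
NumPy arrays (scipy.sparse assembles reactant sums). Each batch packs its
unique molecules — by object identity, so combinatorial datasets with few
distinct molecules encode each molecule once per step — into flat node and
directed-edge arrays. The hand-derived backward pass is verified against
central finite differences (relative error < 1e-6 over every parameter
array) in `tests/test_nnet.py`.

## Inference and uncertainty

MC dropout: T = 30 stochastic forward passes with dropout active, each
pass using a deterministic child stream of the base seed (pass t uses
spawn-key t), so a full MC prediction is reproducible. The graph encoder
carries no dropout, so molecule representations are computed once and only
the head is resampled. From the per-pass `(μ̂_t, σ̂²_t)`:

    prediction = mean of μ̂_t
    aleatoric  = mean of σ̂²_t
    epistemic  = population variance of μ̂_t
    total      = aleatoric + epistemic   (same floating summation order,
                                          so the identity is exact)

All three are mapped to the percent scale before decomposition (means via
μ·s + m̄, variances via ·s²; a positive affine map preserves uncertainty
rankings, so rank-based scores are unaffected). When every μ̂_t is equal —
dropout disabled or T = 1 — the epistemic term is set to exactly zero
rather than left to mean-rounding noise.

Selective prediction keeps, at coverage c, the ⌈c·n⌉ predictions with the
smallest uncertainty score (total variance by default; aleatoric-only and
epistemic-only are available as ablations). Keep-count was chosen over
score thresholding because it realises exact coverage fractions regardless
of ties; ties are broken by original index via a stable sort. Spearman ρ
between |error| and the score uses average ranks for ties
(scipy.stats.spearmanr). R² is undefined for a constant truth vector and
is reported as NaN with a warning rather than a crash.

## Synthetic data generator

Real yield benchmarks are combinatorial screens: a few reusable component
molecules crossed over roles. The generator mirrors that structure at toy
scale — 8 aryl cores × 4 ligand stand-ins × 3 base stand-ins drawn from a
fixed list of small valid molecules, the product keyed to the aryl index —
with a known yield surface and known noise:

* base yield = 50 + additive per-component effects (aryl ±15, ligand ±7,
  base ±3) + one ±5 aryl–ligand parity interaction, hence always within
  [20, 80] so that clipping to [0, 100] stays rare and the Gaussian noise
  model is only mildly truncated;
* noise σ depends on the base component: (2, 2, 12) percent points by
  default — two clearly separated noise groups, which is exactly what a
  variance-recovery test needs;
* yield = clip(base + N(0, σ_group), 0, 100), sampled with a seeded
  generator; every record carries the ground truth (component indices,
  base yield, σ, the drawn noise) in its annotations. The CSV writer puts
  ground truth in a sibling file, never in the training file.

What the generator does **not** emulate: real chemistry (no mechanism, no
structure–activity relationship between the component molecules and the
effect table), yield distributions with mass piled at 0/100, correlated
noise, or out-of-vocabulary molecules at test time. Passing the recovery
tests therefore shows the estimator recovers the statistical structure the
model assumes — heteroscedastic Gaussian noise over a combinatorial
design — not that it matches published benchmark accuracy.

## Desk-scale study conditions

The end-to-end protocol (`rxnuq.experiment.run_recovery_experiment`, also
behind `scripts/acceptance.py`) uses 2000 synthetic reactions, a 70/30
random split, the reduced model (node dim 16, graph dim 256, FNN width
128 — about 4× narrower than the full configuration), λ = 0.1, 100 epochs
of the standard schedule, and T = 30. One run takes ~10 s on one CPU
core. Under these conditions the predicted per-group aleatoric SDs land
near the designed (2, 12), the error–uncertainty Spearman ρ is ~0.5, and
halving coverage roughly halves the MAE (the desk-scale ρ is higher than
typical real-data values because the synthetic noise groups are far
apart and the yield surface is exactly learnable).

## Known limitations

* Single-product reactions only; no atom mapping; no reaction-SMILES
  (`A.B>>C`) parsing; no 3D information.
* μ is unclipped, so predictions can leave [0, 100] for extreme inputs.
* MC dropout here resamples only the head (the model's only dropout
  layers); epistemic variance therefore reflects head uncertainty, not
  encoder uncertainty.
* The NumPy implementation is CPU-bound and aimed at datasets of the
  benchmark scale (10³–10⁴ reactions over tens of unique molecules); it
  re-encodes every unique molecule of the batch each step.
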