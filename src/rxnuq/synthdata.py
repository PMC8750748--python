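"""Self-contained synthetic reaction datasets with known heteroscedastic noise.

Real high-throughput yield benchmarks are combinatorial: a few reusable
component molecules (aryl cores, ligands, bases, ...) are combined and each
combination's yield is measured with noise.  The generator reproduces that
statistical structure at toy scale: reactions sample one component per role
uniformly, the noiseless yield is an additive table of per-component
effects plus one pairwise interaction (kept within [20, 80] so boundary
clipping stays mild), and Gaussian noise with a group-dependent standard
deviation (set by one designated role) is added before clipping to
[0, 100].  The generator makes no attempt to simulate reaction chemistry;
it exists to give the statistical structure the model assumes —
y ~ N(base, sigma_group^2) — with ground truth recorded per record so that
variance recovery is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .chemio import FeatureConfig, ReactionRecord, featurize_molecule

__all__ = ["SynthSpec", "make_toy_molecules", "generate_synthetic_reactions",
           "feature_config_for", "write_synthetic_csv", "TOY_MOLECULES"]

#: Small, chemically valid, mutually distinct molecules: substituted
#: benzenes, heteroaromatics, alcohols, amines, alkanes.
TOY_MOLECULES = (
    "c1ccccc1", "c1ccncc1", "Cc1ccccc1", "Clc1ccccc1",
    "Brc1ccccc1", "Oc1ccccc1", "Nc1ccccc1", "COc1ccccc1",
    "CCO", "CCN", "CC(C)O", "CCOCC",
    "CC(=O)O", "CC#N", "CCS",
    "Cc1ccncc1", "Oc1ccncc1", "CCc1ccccc1", "OCc1ccccc1",
    "NCc1ccccc1", "C1CCCCC1", "C1CCOC1", "CC(C)C", "OCCO",
)


def make_toy_molecules(k: int) -> list:
    """The first ``k`` molecules of the fixed built-in list (deterministic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(TOY_MOLECULES):
        raise ValueError(f"only {len(TOY_MOLECULES)} built-in molecules available")
    return list(TOY_MOLECULES[:k])


def _default_pools():
    mols = make_toy_molecules(15)
    return {
        "aryl": mols[0:8],
        "ligand": mols[8:12],
        "base": mols[12:15],
    }


def _default_product_pool():
    return list(TOY_MOLECULES[15:23])


def _default_yield_function(indices: dict) -> float:
    """Additive per-component effects plus one aryl-ligand interaction;
    values lie in [20, 80] by construction."""
    aryl_eff = np.linspace(-15.0, 15.0, 8)
    ligand_eff = np.linspace(-7.0, 7.0, 4)
    base_eff = np.linspace(-3.0, 3.0, 3)
    inter = 5.0 if (indices["aryl"] + indices["ligand"]) % 2 == 0 else -5.0
    return float(50.0 + aryl_eff[indices["aryl"]] + ligand_eff[indices["ligand"]]
                 + base_eff[indices["base"]] + inter)


@dataclass
class SynthSpec:
    """Study conditions for one synthetic dataset.

    Defaults: 8 aryl cores x 4 ligand stand-ins x 3 base stand-ins, one
    product molecule keyed to the aryl index, additive yield surface in
    [20, 80], and noise grouped by the base component with standard
    deviations (2, 2, 12) percent points — two clearly separated noise
    levels, as a variance-recovery test needs.
    """

    component_pools: dict = field(default_factory=_default_pools)
    product_pool: list = field(default_factory=_default_product_pool)
    product_role: str = "aryl"
    yield_function: Optional[Callable[[dict], float]] = None
    noise_role: str = "base"
    noise_sigmas: tuple = (2.0, 2.0, 12.0)
    n: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.noise_role not in self.component_pools:
            raise ValueError(f"noise_role {self.noise_role!r} not a pool")
        if len(self.noise_sigmas) != len(self.component_pools[self.noise_role]):
            raise ValueError("one noise sigma per component of the noise role")
        if len(set(self.noise_sigmas)) < 2:
            raise ValueError("need at least two distinct noise levels")
        if len(self.product_pool) != len(self.component_pools[self.product_role]):
            raise ValueError("product_pool must parallel the product_role pool")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def all_smiles(self) -> list:
        smis = []
        for pool in self.component_pools.values():
            smis.extend(pool)
        smis.extend(self.product_pool)
        return smis


def feature_config_for(spec: SynthSpec) -> FeatureConfig:
    """Feature config whose atom vocabulary covers every molecule the spec
    can emit."""
    return FeatureConfig.from_smiles(spec.all_smiles())


def generate_synthetic_reactions(spec: SynthSpec,
                                 config: Optional[FeatureConfig] = None) -> list:
    """Sample ``spec.n`` reactions with the seeded rng.

    Yield = clip(base + N(0, sigma_group), 0, 100).  Each record's
    annotations carry the ground truth (component SMILES and indices, base
    yield, noise sigma, the drawn unclipped noise) for testing only — the
    CSV writer never emits them into the training file.
    """
    if config is None:
        config = feature_config_for(spec)
    yield_fn = spec.yield_function or _default_yield_function
    rng = np.random.default_rng(spec.seed)
    roles = list(spec.component_pools)

    memo: dict = {}

    def graph(smi):
        if smi not in memo:
            memo[smi] = featurize_molecule(smi, config)
        return memo[smi]

    records = []
    for _ in range(spec.n):
        indices = {role: int(rng.integers(len(pool)))
                   for role, pool in spec.component_pools.items()}
        base = yield_fn(indices)
        if not (0.0 <= base <= 100.0):
            raise ValueError(f"yield_function produced {base} outside [0, 100]")
        sigma = float(spec.noise_sigmas[indices[spec.noise_role]])
        noise = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
        y = float(np.clip(base + noise, 0.0, 100.0))
        reactant_smis = [spec.component_pools[r][indices[r]] for r in roles]
        product_smi = spec.product_pool[indices[spec.product_role]]
        ann = {f"{r}_smiles": spec.component_pools[r][indices[r]] for r in roles}
        ann.update({f"{r}_index": indices[r] for r in roles})
        ann.update({
            "true_base_yield": base,
            "true_sigma": sigma,
            "true_noise": noise,
        })
        records.append(ReactionRecord(
            reactants=[graph(s) for s in reactant_smis],
            product=graph(product_smi),
            yield_percent=y,
            annotations=ann,
        ))
    return records


def write_synthetic_csv(spec: SynthSpec, csv_path, truth_path=None) -> list:
    """Write the dataset in the same CSV dialect :func:`read_reaction_csv`
    consumes (reactant_1..k, product, yield, plus the component SMILES as
    plain annotation columns).  Ground-truth columns go to ``truth_path``
    (a sibling file), never into the training CSV.  Returns the records."""
    records = generate_synthetic_reactions(spec)
    roles = list(spec.component_pools)
    rows = []
    for rec in records:
        row = {f"reactant_{i + 1}": rec.annotations[f"{role}_smiles"]
               for i, role in enumerate(roles)}
        row["product"] = spec.product_pool[rec.annotations[f"{spec.product_role}_index"]]
        row["yield"] = rec.yield_percent
        for role in roles:
            row[role] = rec.annotations[f"{role}_smiles"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if truth_path is not None:
        truth = pd.DataFrame([{
            "true_base_yield": rec.annotations["true_base_yield"],
            "true_sigma": rec.annotations["true_sigma"],
            "true_noise": rec.annotations["true_noise"],
            **{f"{role}_index": rec.annotations[f"{role}_index"] for role in roles},
        } for rec in records])
        truth.to_csv(truth_path, index=False)
    return records
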