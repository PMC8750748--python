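"""Reaction tables, molecular graph featurization, and dataset splits.

A reaction is a set of reactant molecules, one product molecule, and a
measured yield in percent (0-100).  Each molecule is an undirected graph
over heavy atoms: hydrogens are folded into a per-atom hydrogen-count
feature and never appear as nodes.  Atom and bond feature vectors are
one-hot/flag encodings whose layout is fully determined by a
:class:`FeatureConfig`, so every graph produced under one config has node
vectors of the same length ``p`` and bond vectors of the same length ``q``.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDConfig
from rdkit.Chem import ChemicalFeatures

logger = logging.getLogger(__name__)

__all__ = [
    "SmilesParseError",
    "FeatureConfig",
    "MolecularGraph",
    "ReactionRecord",
    "featurize_molecule",
    "featurize_reaction",
    "read_reaction_csv",
    "random_split",
    "out_of_sample_split",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


# Fixed (config-independent) categorical ranges.
_CHARGES = (-2, -1, 0, 1, 2)
_MAX_DEGREE = 5          # one-hot 0..5 plus an overflow slot
_MAX_NUM_H = 4           # one-hot 0..4 (capped)
_MAX_VALENCE = 6         # one-hot 0..6 plus an overflow slot
_CHIRAL_TAGS = ("CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW", "CHI_TETRAHEDRAL_CCW")

#: Elements common in organic / cross-coupling chemistry, used by
#: :meth:`FeatureConfig.default`.
DEFAULT_ATOM_VOCAB = ("B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I")


@dataclass(frozen=True)
class FeatureConfig:
    """Vocabularies that fix the atom/bond feature layout.

    Categorical features are one-hot encoded against an ordered vocabulary
    with a trailing fallback slot, so an out-of-vocabulary value (e.g. an
    exotic element) maps to the fallback rather than raising.  ``p`` and
    ``q`` are derived and constant for a given config.
    """

    atom_type_vocab: tuple = DEFAULT_ATOM_VOCAB
    hybridization_vocab: tuple = ("SP", "SP2", "SP3", "SP3D", "SP3D2")
    ring_size_bins: tuple = (3, 4, 5, 6, 7, 8)
    bond_type_vocab: tuple = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")
    stereo_vocab: tuple = ("STEREONONE", "STEREOANY", "STEREOZ", "STEREOE")

    def __post_init__(self):
        for name in ("atom_type_vocab", "hybridization_vocab", "ring_size_bins",
                     "bond_type_vocab", "stereo_vocab"):
            if len(getattr(self, name)) < 1:
                raise ValueError(f"{name} must have at least one entry")

    @classmethod
    def default(cls) -> "FeatureConfig":
        return cls()

    @classmethod
    def from_smiles(cls, smiles_iter: Iterable[str], **kwargs) -> "FeatureConfig":
        """Build a config whose atom-type vocabulary is the set of elements
        observed in ``smiles_iter`` (sorted), frozen at creation time so the
        feature length cannot drift between training and test data."""
        elements = set()
        for smi in smiles_iter:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise SmilesParseError(f"cannot parse SMILES: {smi!r}")
            for atom in mol.GetAtoms():
                elements.add(atom.GetSymbol())
        if not elements:
            raise ValueError("no heavy atoms observed; cannot build vocabulary")
        return cls(atom_type_vocab=tuple(sorted(elements)), **kwargs)

    @property
    def atom_slices(self) -> dict:
        return _atom_layout(self)[0]

    @property
    def bond_slices(self) -> dict:
        return _bond_layout(self)[0]

    @property
    def p(self) -> int:
        """Atom feature vector length."""
        return _atom_layout(self)[1]

    @property
    def q(self) -> int:
        """Bond feature vector length."""
        return _bond_layout(self)[1]

    def to_dict(self) -> dict:
        return {
            "atom_type_vocab": list(self.atom_type_vocab),
            "hybridization_vocab": list(self.hybridization_vocab),
            "ring_size_bins": list(self.ring_size_bins),
            "bond_type_vocab": list(self.bond_type_vocab),
            "stereo_vocab": list(self.stereo_vocab),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**{k: tuple(v) for k, v in d.items()})


@lru_cache(maxsize=None)
def _atom_layout(config: FeatureConfig):
    sections = [
        ("atom_type", len(config.atom_type_vocab) + 1),
        ("formal_charge", len(_CHARGES) + 1),
        ("degree", _MAX_DEGREE + 2),
        ("hybridization", len(config.hybridization_vocab) + 1),
        ("num_hydrogens", _MAX_NUM_H + 1),
        ("valence", _MAX_VALENCE + 2),
        ("chirality", len(_CHIRAL_TAGS) + 1),
        ("donor", 1),
        ("acceptor", 1),
        ("aromatic", 1),
        ("in_ring", 1),
        ("ring_size", len(config.ring_size_bins) + 1),
    ]
    return _build_slices(sections)


@lru_cache(maxsize=None)
def _bond_layout(config: FeatureConfig):
    sections = [
        ("bond_type", len(config.bond_type_vocab) + 1),
        ("stereo", len(config.stereo_vocab) + 1),
        ("in_ring", 1),
        ("conjugated", 1),
    ]
    return _build_slices(sections)


def _build_slices(sections):
    slices, off = {}, 0
    for name, width in sections:
        slices[name] = slice(off, off + width)
        off += width
    return slices, off


@dataclass
class MolecularGraph:
    """Featurized heavy-atom graph of a single molecule.

    ``node_features`` is an ``(n, p)`` array, one row per heavy atom.
    ``edge_features`` maps each unordered atom-index pair ``(j, k)`` with
    ``j < k`` to a length-``q`` vector; the graph is undirected so the pair
    is stored once.
    """

    node_features: np.ndarray
    edge_features: dict

    def __post_init__(self):
        if self.node_features.ndim != 2 or self.node_features.shape[0] < 1:
            raise ValueError("graph must have at least one node")
        for (j, k) in self.edge_features:
            if j == k:
                raise ValueError("self-loops are not allowed")
            if not (0 <= j < k < self.n_nodes):
                raise ValueError(f"edge key {(j, k)} must satisfy 0 <= j < k < n")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edge_features)


@dataclass
class ReactionRecord:
    """One reaction: ``m >= 1`` reactant graphs, a product graph, and an
    optional measured yield in percent.  ``annotations`` carries pass-through
    columns from the source table (e.g. the additive SMILES used by
    out-of-sample splits) and, for synthetic data, hidden ground truth."""

    reactants: list
    product: MolecularGraph
    yield_percent: Optional[float] = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.reactants) < 1:
            raise ValueError("a reaction needs at least one reactant")
        if self.yield_percent is not None:
            y = float(self.yield_percent)
            if not (0.0 <= y <= 100.0) or not math.isfinite(y):
                raise ValueError(f"yield {y} outside [0, 100]")
            self.yield_percent = y

    @property
    def m(self) -> int:
        return len(self.reactants)


_FEATURE_FACTORY = None


def _feature_factory():
    # Pharmacophore feature definitions shipped with RDKit; provides the
    # donor/acceptor atom assignments.
    global _FEATURE_FACTORY
    if _FEATURE_FACTORY is None:
        fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        _FEATURE_FACTORY = ChemicalFeatures.BuildFeatureFactory(fdef)
    return _FEATURE_FACTORY


def _donor_acceptor_ids(mol):
    donors, acceptors = set(), set()
    for feat in _feature_factory().GetFeaturesForMol(mol):
        if feat.GetFamily() == "Donor":
            donors.update(feat.GetAtomIds())
        elif feat.GetFamily() == "Acceptor":
            acceptors.update(feat.GetAtomIds())
    return donors, acceptors


def _one_hot(vec, sl, vocab, value):
    """Set the one-hot slot for ``value`` inside slice ``sl``; out-of-vocab
    values go to the trailing fallback slot."""
    try:
        idx = vocab.index(value)
    except ValueError:
        idx = len(vocab)
    vec[sl.start + idx] = 1.0


def featurize_molecule(smiles: str, config: FeatureConfig) -> MolecularGraph:
    """Convert a SMILES string into a featurized heavy-atom graph.

    Raises :class:`SmilesParseError` (naming the offending string) if the
    SMILES does not parse or has no heavy atom.  Elements outside the
    configured vocabulary map to the fallback atom-type slot.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")

    asl = config.atom_slices
    donors, acceptors = _donor_acceptor_ids(mol)
    X = np.zeros((mol.GetNumAtoms(), config.p))
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        row = X[i]
        _one_hot(row, asl["atom_type"], list(config.atom_type_vocab), atom.GetSymbol())
        _one_hot(row, asl["formal_charge"], list(_CHARGES), atom.GetFormalCharge())
        deg = atom.GetDegree()
        row[asl["degree"].start + (deg if deg <= _MAX_DEGREE else _MAX_DEGREE + 1)] = 1.0
        _one_hot(row, asl["hybridization"], list(config.hybridization_vocab),
                 str(atom.GetHybridization()))
        row[asl["num_hydrogens"].start + min(atom.GetTotalNumHs(), _MAX_NUM_H)] = 1.0
        val = atom.GetTotalValence()
        row[asl["valence"].start + (val if val <= _MAX_VALENCE else _MAX_VALENCE + 1)] = 1.0
        _one_hot(row, asl["chirality"], list(_CHIRAL_TAGS), str(atom.GetChiralTag()))
        row[asl["donor"].start] = float(i in donors)
        row[asl["acceptor"].start] = float(i in acceptors)
        row[asl["aromatic"].start] = float(atom.GetIsAromatic())
        row[asl["in_ring"].start] = float(atom.IsInRing())
        in_bin = False
        for b, size in enumerate(config.ring_size_bins):
            if atom.IsInRingSize(size):
                row[asl["ring_size"].start + b] = 1.0
                in_bin = True
        if atom.IsInRing() and not in_bin:
            row[asl["ring_size"].stop - 1] = 1.0  # larger-ring flag

    bsl = config.bond_slices
    edges = {}
    for bond in mol.GetBonds():
        j, k = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        key = (j, k) if j < k else (k, j)
        vec = np.zeros(config.q)
        _one_hot(vec, bsl["bond_type"], list(config.bond_type_vocab),
                 str(bond.GetBondType()))
        _one_hot(vec, bsl["stereo"], list(config.stereo_vocab), str(bond.GetStereo()))
        vec[bsl["in_ring"].start] = float(bond.IsInRing())
        vec[bsl["conjugated"].start] = float(bond.GetIsConjugated())
        edges[key] = vec
    return MolecularGraph(X, edges)


def featurize_reaction(
    reactant_smiles: Sequence[str],
    product_smiles: str,
    yield_percent: Optional[float],
    config: FeatureConfig,
) -> ReactionRecord:
    """Featurize a full reaction.  Reactant order is preserved in the record
    but carries no meaning downstream (the model sums over reactants)."""
    if len(reactant_smiles) < 1:
        raise ValueError("a reaction needs at least one reactant SMILES")
    reactants = [featurize_molecule(s, config) for s in reactant_smiles]
    product = featurize_molecule(product_smiles, config)
    return ReactionRecord(reactants, product, yield_percent)


def read_reaction_csv(
    path,
    config: FeatureConfig,
    *,
    reactant_prefix: str = "reactant",
    product_col: str = "product",
    yield_col: str = "yield",
) -> list:
    """Read a reaction table (comma-separated, UTF-8, header required).

    Reactant columns are identified by ``reactant_prefix``; blank reactant
    cells are skipped, so rows may have a variable number of reactants.
    Every other column (besides product and yield) is preserved verbatim in
    each record's ``annotations``.  Malformed rows are rejected with a
    logged row number rather than aborting the whole file; a per-file
    summary (rows read / rejected) is logged.
    """
    df = pd.read_csv(path, dtype=str)
    reactant_cols = [c for c in df.columns if c.startswith(reactant_prefix)]
    if not reactant_cols:
        raise ValueError(f"no columns with prefix {reactant_prefix!r} in {path}")
    for col in (product_col, yield_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    extra_cols = [c for c in df.columns
                  if c not in reactant_cols and c not in (product_col, yield_col)]

    memo: dict = {}

    def _graph(smi: str) -> MolecularGraph:
        if smi not in memo:
            memo[smi] = featurize_molecule(smi, config)
        return memo[smi]

    records, rejected = [], 0
    for i, row in df.iterrows():
        try:
            smis = [row[c] for c in reactant_cols
                    if isinstance(row[c], str) and row[c].strip()]
            if not smis:
                raise ValueError("no reactants")
            y = float(row[yield_col])
            rec = ReactionRecord(
                reactants=[_graph(s) for s in smis],
                product=_graph(row[product_col]),
                yield_percent=y,
                annotations={c: row[c] for c in extra_cols},
            )
        except Exception as exc:  # malformed row: reject, keep going
            rejected += 1
            logger.warning("rejected row %d of %s: %s", i, path, exc)
            continue
        records.append(rec)
    logger.info("%s: read %d rows, rejected %d", path, len(records), rejected)
    return records


def random_split(records: list, train_fraction: float, seed: int):
    """Deterministic random partition into (train, test).

    ``|train| = round(train_fraction * n)``; the same (records, fraction,
    seed) always produces the identical split.  Original record order is
    preserved within each side.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction {train_fraction} outside (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(round(train_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return ([records[i] for i in train_idx], [records[i] for i in test_idx])


def out_of_sample_split(records: list, holdout_key: str, holdout_values: Sequence[str]):
    """Hold out all records whose annotation ``holdout_key`` is in
    ``holdout_values`` as the test set; train on the complement.  No key
    value occurs on both sides.  A holdout value matching zero records is a
    warning, not an error; an empty side is an error."""
    values = set(holdout_values)
    for rec in records:
        if holdout_key not in rec.annotations:
            raise ValueError(f"record missing annotation {holdout_key!r}")
    present = {rec.annotations[holdout_key] for rec in records}
    for v in values:
        if v not in present:
            warnings.warn(f"holdout value {v!r} matches no record", stacklevel=2)
    test = [r for r in records if r.annotations[holdout_key] in values]
    train = [r for r in records if r.annotations[holdout_key] not in values]
    if not test:
        raise ValueError("out-of-sample split produced an empty test set")
    if not train:
        raise ValueError("out-of-sample split produced an empty training set")
    return train, test
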