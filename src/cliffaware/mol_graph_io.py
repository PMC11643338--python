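"""Molecule tables and molecular-graph featurization.

Molecules enter the package as SMILES strings with a continuous activity
label on the pChEMBL scale (−log10 molar potency, typically 2–12).  Each
molecule is converted to a heavy-atom graph with a fixed 39-dimensional
atom feature vector and a 10-dimensional feature vector per directed
bond, the input expected by the graph encoders.

The atom scheme: one-hot element over a declared 15-element vocabulary
plus an "other" slot (16), heavy-atom degree 0–5 (6), formal charge
−2…+2 (5), hybridization {sp, sp2, sp3, sp3d, sp3d2, other} (6),
aromatic flag (1), in-ring flag (1), total-H count 0–3 (4) — 39 columns.
The bond scheme: bond type {single, double, triple, aromatic} (4),
conjugated (1), in-ring (1), stereo {none, Z, E, other} (4) — 10 columns.
Out-of-range ordinal values (degree > 5, |charge| > 2, H count > 3) are
clamped to the boundary bucket; unknown categorical values land in the
"other" slot, so the column counts never change with element content.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.error")

__all__ = [
    "MoleculeRecord",
    "MolecularGraph",
    "GraphBatch",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
    "ELEMENT_VOCABULARY",
    "read_molecule_table",
    "featurize",
    "featurize_batch",
    "collate_graphs",
    "feature_descriptor",
    "write_feature_descriptor",
]

# Declared element vocabulary; anything else maps to the trailing "other" slot.
ELEMENT_VOCABULARY: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "Se", "As", "Na", "K",
)
_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
_STEREO_Z = (Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOCIS)
_STEREO_E = (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOTRANS)

ATOM_FEATURE_DIM = len(ELEMENT_VOCABULARY) + 1 + 6 + 5 + 6 + 1 + 1 + 4  # 39
BOND_FEATURE_DIM = 4 + 1 + 1 + 4  # 10


@dataclass
class MoleculeRecord:
    """One molecule: SMILES plus its activity label in pChEMBL units."""

    smiles: str
    y: float
    group_id: Optional[str] = None
    cliff_flag: Optional[bool] = None

    def __post_init__(self):
        if not np.isfinite(self.y):
            raise ValueError(f"activity label must be finite, got {self.y!r}")


@dataclass
class MolecularGraph:
    """Featurized molecule: nodes, directed edges, and their features."""

    node_features: np.ndarray  # [n_atoms, 39]
    edge_index: np.ndarray  # [2, n_directed_edges], both directions per bond
    edge_features: np.ndarray  # [n_directed_edges, 10]

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]


@dataclass
class GraphBatch:
    """A batch of molecular graphs concatenated into flat arrays.

    ``node_graph`` maps every node row to the index of its source molecule;
    edge indices are offset so they address rows of the concatenated node
    matrix.  ``y`` holds one label per molecule, aligned with graph order.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    node_graph: np.ndarray
    y: np.ndarray
    n_graphs: int
    cliff_flags: Optional[np.ndarray] = None
    node_counts: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.node_counts is None:
            self.node_counts = np.bincount(self.node_graph, minlength=self.n_graphs)


def _parse_smiles(smiles: str) -> Optional[Chem.Mol]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        # largest-fragment selection (salt / counter-ion stripping)
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    # round-trip through canonical SMILES so atom ordering is deterministic
    # across input dialects
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def _one_hot(index: int, size: int) -> list[float]:
    v = [0.0] * size
    v[index] = 1.0
    return v


def _atom_features(atom: Chem.Atom) -> list[float]:
    symbol = atom.GetSymbol()
    try:
        elem = ELEMENT_VOCABULARY.index(symbol)
    except ValueError:
        elem = len(ELEMENT_VOCABULARY)
    feats = _one_hot(elem, len(ELEMENT_VOCABULARY) + 1)
    feats += _one_hot(min(atom.GetDegree(), 5), 6)
    feats += _one_hot(int(np.clip(atom.GetFormalCharge(), -2, 2)) + 2, 5)
    hyb = atom.GetHybridization()
    feats += _one_hot(
        _HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else 5, 6
    )
    feats.append(1.0 if atom.GetIsAromatic() else 0.0)
    feats.append(1.0 if atom.IsInRing() else 0.0)
    feats += _one_hot(min(atom.GetTotalNumHs(), 3), 4)
    return feats


def _bond_features(bond: Chem.Bond) -> list[float]:
    btype = bond.GetBondType()
    feats = [1.0 if btype == t else 0.0 for t in _BOND_TYPES]
    feats.append(1.0 if bond.GetIsConjugated() else 0.0)
    feats.append(1.0 if bond.IsInRing() else 0.0)
    stereo = bond.GetStereo()
    if stereo == Chem.BondStereo.STEREONONE:
        s = 0
    elif stereo in _STEREO_Z:
        s = 1
    elif stereo in _STEREO_E:
        s = 2
    else:
        s = 3
    feats += _one_hot(s, 4)
    return feats


def featurize(smiles: str) -> MolecularGraph:
    """Convert a SMILES string into a featurized heavy-atom graph.

    Deterministic: the molecule is canonicalized first, so any SMILES
    dialect of the same structure yields bit-identical arrays.  Every
    bond contributes two directed edges with identical features;
    single-atom molecules have zero edges.
    """
    mol = _parse_smiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    node_features = np.array(
        [_atom_features(a) for a in mol.GetAtoms()], dtype=np.float64
    ).reshape(mol.GetNumAtoms(), ATOM_FEATURE_DIM)
    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = _bond_features(bond)
        src += [i, j]
        dst += [j, i]
        efeat += [f, f]
    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, len(src))
    edge_features = np.array(efeat, dtype=np.float64).reshape(
        len(src), BOND_FEATURE_DIM
    )
    return MolecularGraph(node_features, edge_index, edge_features)


def collate_graphs(
    graphs: Sequence[MolecularGraph],
    labels: Sequence[float],
    cliff_flags: Optional[Sequence[bool]] = None,
) -> GraphBatch:
    """Concatenate pre-featurized graphs into one batch."""
    if len(graphs) == 0:
        raise ValueError("cannot collate an empty list of graphs")
    if len(graphs) != len(labels):
        raise ValueError("graphs and labels must have matching lengths")
    node_blocks, edge_blocks, efeat_blocks, membership = [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        node_blocks.append(g.node_features)
        edge_blocks.append(g.edge_index + offset)
        efeat_blocks.append(g.edge_features)
        membership.append(np.full(g.n_atoms, gi, dtype=np.int64))
        offset += g.n_atoms
    flags = None
    if cliff_flags is not None:
        flags = np.array([bool(c) for c in cliff_flags])
    return GraphBatch(
        node_features=np.concatenate(node_blocks, axis=0),
        edge_index=np.concatenate(edge_blocks, axis=1),
        edge_features=np.concatenate(efeat_blocks, axis=0),
        node_graph=np.concatenate(membership),
        y=np.asarray(labels, dtype=np.float64),
        n_graphs=len(graphs),
        cliff_flags=flags,
    )


def featurize_batch(records: Sequence[MoleculeRecord]) -> GraphBatch:
    """Featurize a list of records into one batched graph collection."""
    if len(records) == 0:
        raise ValueError("cannot featurize an empty list of records")
    graphs, bad = [], []
    for i, rec in enumerate(records):
        try:
            graphs.append(featurize(rec.smiles))
        except ValueError:
            bad.append(i)
    if bad:
        raise ValueError(f"unfeaturizable records at indices {bad}")
    flags = [rec.cliff_flag for rec in records]
    has_flags = any(f is not None for f in flags)
    return collate_graphs(
        graphs,
        [rec.y for rec in records],
        cliff_flags=[bool(f) for f in flags] if has_flags else None,
    )


def read_molecule_table(
    path,
    smiles_column: str = "smiles",
    label_column: str = "y",
    group_column: Optional[str] = None,
    cliff_column: Optional[str] = None,
    return_skipped: bool = False,
):
    """Read a molecule CSV into :class:`MoleculeRecord` objects.

    Rows whose SMILES do not parse are skipped with a warning; the
    returned records plus the skipped count always add up to the number
    of data rows.  A table with no rows, a missing column, or a table
    where every SMILES fails is a hard error.
    """
    df = pd.read_csv(path)
    for col in filter(None, (smiles_column, label_column, group_column, cliff_column)):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if len(df) == 0:
        raise ValueError(f"no data rows in {path}")
    records, skipped = [], []
    for i, row in df.iterrows():
        smiles = str(row[smiles_column])
        if _parse_smiles(smiles) is None:
            skipped.append(i)
            continue
        records.append(
            MoleculeRecord(
                smiles=smiles,
                y=float(row[label_column]),
                group_id=str(row[group_column]) if group_column else None,
                cliff_flag=bool(row[cliff_column]) if cliff_column else None,
            )
        )
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} rows with unparseable SMILES: {skipped}"
        )
    if not records:
        raise ValueError(f"all {len(df)} rows in {path} have unparseable SMILES")
    if return_skipped:
        return records, len(skipped)
    return records


def feature_descriptor() -> dict:
    """Names of every atom/bond feature column, for provenance."""
    atom = [f"element_{e}" for e in ELEMENT_VOCABULARY] + ["element_other"]
    atom += [f"degree_{d}" for d in range(6)]
    atom += [f"formal_charge_{c:+d}" for c in range(-2, 3)]
    atom += ["hyb_sp", "hyb_sp2", "hyb_sp3", "hyb_sp3d", "hyb_sp3d2", "hyb_other"]
    atom += ["is_aromatic", "in_ring"]
    atom += [f"total_h_{h}" for h in range(4)]
    bond = ["bond_single", "bond_double", "bond_triple", "bond_aromatic"]
    bond += ["conjugated", "in_ring"]
    bond += ["stereo_none", "stereo_z", "stereo_e", "stereo_other"]
    assert len(atom) == ATOM_FEATURE_DIM and len(bond) == BOND_FEATURE_DIM
    return {"atom_features": atom, "bond_features": bond}


def write_feature_descriptor(path) -> None:
    with open(path, "w") as fh:
        json.dump(feature_descriptor(), fh, indent=2)
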