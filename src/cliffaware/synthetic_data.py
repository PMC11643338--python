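"""Synthetic scaffold-family datasets with planted activity cliffs.

Real narrow-scaffold activity series contain close structural analogs
of a shared core whose potencies mostly cluster, with occasional
analogs whose potency jumps by orders of magnitude (activity cliffs).
The generator emulates exactly that label structure on real, parseable
chemistry: each scaffold from a built-in library of parent rings is
decorated with one or two substituents from a fixed fragment library
(deduplicated by canonical SMILES), every family receives a base
activity, and each analog's label is

    y = base + (± cliff_magnitude  if it carries a switching substituent) + N(0, noise_sd)

in pChEMBL units.  Cliffs follow a substituent rule — per family, each
library substituent is an "activity switch" with probability
``cliff_fraction`` — so the planted cliffs are a learnable
structure-activity relationship, not unlearnable label noise; the
realized fraction of cliff analogs tracks ``cliff_fraction``
approximately (doubly substituted analogs switch if either substituent
does).  Activity is assigned by rule, not simulated physics:
the point is controllable label structure for testing the mining,
losses, metrics and training machinery, not a realistic SAR model.

Every planted (ordinary analog, cliff analog) pair within a family is
recorded with its realized label gap, so tests can check mined triplet
counts and MMP labels against ground truth exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from rdkit import Chem

from .activity_math import MMPLabel, MMPRecord, label_mmp
from .mol_graph_io import MoleculeRecord

__all__ = [
    "SyntheticConfig",
    "SCAFFOLD_LIBRARY",
    "SUBSTITUENT_LIBRARY",
    "enumerate_analogs",
    "generate_dataset",
    "generate_mmp_pairs",
    "generate_embedding_fixture",
]

logger = logging.getLogger(__name__)

# parent cores: small aromatic systems typical of lead series
SCAFFOLD_LIBRARY: tuple[tuple[str, str], ...] = (
    ("benzene", "c1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("pyrimidine", "c1cncnc1"),
    ("thiophene", "c1ccsc1"),
    ("furan", "c1ccoc1"),
    ("pyrrole", "c1cc[nH]c1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("quinoline", "c1ccc2ncccc2c1"),
    ("benzofuran", "c1ccc2occc2c1"),
)

# substituents attached through their first atom by a single bond
SUBSTITUENT_LIBRARY: tuple[str, ...] = (
    "C", "CC", "C(C)C", "O", "OC", "N", "NC", "F", "Cl", "Br", "I",
    "C#N", "C(F)(F)F", "[N+](=O)[O-]", "C=C", "CO", "SC", "C(=O)O",
)


@dataclass
class SyntheticConfig:
    """Study conditions of the generated dataset."""

    n_scaffolds: int = 5
    analogs_per_scaffold: int = 40
    base_activity_range: tuple[float, float] = (5.0, 9.0)
    cliff_fraction: float = 0.2
    cliff_magnitude: float = 2.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_scaffolds < 1 or self.n_scaffolds > len(SCAFFOLD_LIBRARY):
            raise ValueError(
                f"n_scaffolds must be in [1, {len(SCAFFOLD_LIBRARY)}]"
            )
        if self.analogs_per_scaffold < 1:
            raise ValueError("analogs_per_scaffold must be positive")
        lo, hi = self.base_activity_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("base_activity_range must be a finite interval")
        if not 0.0 <= self.cliff_fraction <= 1.0:
            raise ValueError("cliff_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.cliff_magnitude <= self.noise_sd:
            raise ValueError("cliff_magnitude must exceed noise_sd")


def _attach(scaffold: Chem.Mol, attachments: tuple[tuple[int, str], ...]):
    """Attach substituent fragments at the given scaffold atom indices."""
    mol = scaffold
    for atom_idx, sub_smiles in attachments:
        frag = Chem.MolFromSmiles(sub_smiles)
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        combined.AddBond(
            atom_idx, mol.GetNumAtoms(), order=Chem.BondType.SINGLE
        )
        try:
            out = combined.GetMol()
            Chem.SanitizeMol(out)
        except Exception:
            return None
        mol = out
    return Chem.MolToSmiles(mol)


def enumerate_analogs(scaffold_smiles: str, n_analogs: int) -> list[tuple[str, tuple[str, ...]]]:
    """Deterministically enumerate distinct substituted analogs.

    Mono-substitutions first, then double substitutions, deduplicated
    by canonical SMILES (symmetric positions collapse), in a fixed
    enumeration order.  Returns ``(smiles, substituents)`` per analog so
    callers can apply substituent-based activity rules.
    """
    scaffold = Chem.MolFromSmiles(scaffold_smiles)
    if scaffold is None:
        raise ValueError(f"unparseable scaffold {scaffold_smiles!r}")
    positions = [
        a.GetIdx() for a in scaffold.GetAtoms() if a.GetTotalNumHs() >= 1
    ]
    seen: set[str] = set()
    analogs: list[tuple[str, tuple[str, ...]]] = []

    def consider(attachments) -> bool:
        smi = _attach(scaffold, attachments)
        if smi is not None and smi not in seen:
            seen.add(smi)
            analogs.append((smi, tuple(sub for _, sub in attachments)))
        return len(analogs) >= n_analogs

    for sub in SUBSTITUENT_LIBRARY:
        for pos in positions:
            if consider(((pos, sub),)):
                return analogs
    for sub1, sub2 in combinations(SUBSTITUENT_LIBRARY, 2):
        for pos1, pos2 in combinations(positions, 2):
            if consider(((pos1, sub1), (pos2, sub2))):
                return analogs
    raise ValueError(
        f"could only enumerate {len(analogs)} analogs of {scaffold_smiles!r}, "
        f"{n_analogs} requested"
    )


def generate_dataset(config: SyntheticConfig):
    """Generate molecule records with planted cliffs and the pair table.

    Returns ``(records, cliff_pairs)`` where ``cliff_pairs`` is a
    DataFrame with one row per (ordinary analog, cliff analog) pair
    within a family: indices, SMILES, the realized label gap, and the
    planted magnitude.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.base_activity_range
    records: list[MoleculeRecord] = []
    pair_rows: list[dict] = []
    for name, scaffold_smiles in SCAFFOLD_LIBRARY[: config.n_scaffolds]:
        analogs = enumerate_analogs(scaffold_smiles, config.analogs_per_scaffold)
        base = rng.uniform(lo, hi)
        # cliffs are substituent-determined (a learnable SAR rule): each
        # substituent switches activity in this family with probability
        # cliff_fraction, shifting the label by ± cliff_magnitude
        switch_sign = {
            sub: float(rng.choice([-1.0, 1.0]))
            for sub in SUBSTITUENT_LIBRARY
            if rng.random() < config.cliff_fraction
        }
        noise = rng.normal(0.0, config.noise_sd, size=len(analogs))
        is_cliff = np.zeros(len(analogs), dtype=bool)
        start = len(records)
        for i, (smi, subs) in enumerate(analogs):
            switching = [s for s in subs if s in switch_sign]
            offset = 0.0
            if switching:
                is_cliff[i] = True
                # first switching substituent (library order) sets the sign,
                # so every cliff analog sits exactly one magnitude away
                first = min(switching, key=SUBSTITUENT_LIBRARY.index)
                offset = switch_sign[first] * config.cliff_magnitude
            records.append(
                MoleculeRecord(smiles=smi, y=float(base + offset + noise[i]),
                               group_id=name, cliff_flag=bool(is_cliff[i]))
            )
        for i in np.flatnonzero(~is_cliff):
            for j in np.flatnonzero(is_cliff):
                pair_rows.append(
                    {
                        "family": name,
                        "idx_a": start + int(i),
                        "idx_b": start + int(j),
                        "smiles_a": analogs[i][0],
                        "smiles_b": analogs[j][0],
                        "delta_y": abs(records[start + i].y - records[start + j].y),
                        "planted_magnitude": config.cliff_magnitude,
                    }
                )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "family", "idx_a", "idx_b", "smiles_a", "smiles_b",
            "delta_y", "planted_magnitude",
        ],
    )
    return records, pairs


def generate_mmp_pairs(config: SyntheticConfig) -> list[MMPRecord]:
    """Same-family analog pairs labeled cliff / non-cliff by their
    realized label gap; pairs in the excluded (1, 2) band are dropped."""
    records, _ = generate_dataset(config)
    families: dict[str, list[MoleculeRecord]] = {}
    for rec in records:
        families.setdefault(rec.group_id, []).append(rec)
    for name, members in families.items():
        if len(members) < 2:
            raise ValueError(f"family {name!r} has fewer than 2 analogs")
    out: list[MMPRecord] = []
    n_excluded = 0
    for members in families.values():
        for a, b in combinations(members, 2):
            delta = abs(a.y - b.y)
            label = label_mmp(delta)
            if label is MMPLabel.EXCLUDED:
                n_excluded += 1
                continue
            out.append(MMPRecord(a.smiles, b.smiles, delta, label))
    if not out:
        raise ValueError(
            f"no labeled pairs remain: all {n_excluded} candidate pairs fall "
            "in the excluded (1, 2) band"
        )
    n_cliff = sum(1 for r in out if r.label is MMPLabel.CLIFF)
    logger.info(
        "generated %d MMPs: %d cliff, %d non-cliff, %d excluded",
        len(out), n_cliff, len(out) - n_cliff, n_excluded,
    )
    return out


def generate_embedding_fixture(labels, alignment: float, seed: int, d: int = 8):
    """Embeddings with controllable label alignment.

    f_i = alignment · y_i · u + (1 − alignment) · ε_i with u the first
    coordinate direction and ε_i isotropic Gaussian noise scaled to the
    label spread.  alignment = 1 with d = 1 reproduces the zero-loss
    geometry of the triplet soft-margin loss (latent distances equal
    ground-truth label distances).

    For d ≥ 2 a constant anchor component (alignment-weighted, in the
    second coordinate) is added so the label also controls the vector's
    *direction*: under cosine distance a purely collinear embedding
    carries no neighborhood information, and the anchor makes the
    cosine k-nearest-neighbor structure tighten monotonically as
    alignment grows — the behavior the label-incoherence analyses rely
    on.
    """
    if not 0.0 <= alignment <= 1.0:
        raise ValueError("alignment must be in [0, 1]")
    y = np.asarray(labels, dtype=np.float64).ravel()
    rng = np.random.default_rng(seed)
    scale = y.std() if y.std() > 0 else 1.0
    noise = rng.normal(0.0, scale, size=(y.shape[0], d))
    out = (1.0 - alignment) * noise
    out[:, 0] += alignment * y
    if d >= 2:
        out[:, 1] += alignment * scale
    return out
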