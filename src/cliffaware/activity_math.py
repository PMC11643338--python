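"""Activity-label arithmetic: pChEMBL conversion, cliff magnitude, fold
change, and matched-molecular-pair (MMP) cliff labeling.

A potency x in nanomolar units converts to the pChEMBL scale as
y = −log10(x · 1e−9).  The "cliff" between two compounds is the L1
distance of their pChEMBL values, |y_i − y_j| = |log10(x_i / x_j)|, and
the nanomolar fold change is 10^cliff — cliff values of 0.3, 1 and 2
correspond to roughly 2-, 10- and 100-fold potency changes.

MMPs carry a binary cliff label from their |ΔpKi|: cliff if ≥ 2,
non-cliff if ≤ 1; the uncovered band (1, 2) is excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "MMPLabel",
    "MMPRecord",
    "pchembl_from_nanomolar",
    "cliff_value",
    "fold_change",
    "label_mmp",
]


class MMPLabel(str, Enum):
    CLIFF = "cliff"
    NON_CLIFF = "non-cliff"
    EXCLUDED = "excluded"


@dataclass
class MMPRecord:
    """A matched molecular pair with its ΔpKi-derived cliff label."""

    smiles_a: str
    smiles_b: str
    delta_pki: float
    label: MMPLabel

    def __post_init__(self):
        if self.delta_pki < 0:
            raise ValueError("delta_pki must be nonnegative")
        if self.label != label_mmp(self.delta_pki):
            raise ValueError(
                f"label {self.label} inconsistent with delta_pki={self.delta_pki}"
            )


def pchembl_from_nanomolar(x: float) -> float:
    """Convert a nanomolar potency to the pChEMBL scale, −log10(x·1e−9)."""
    x = float(x)
    if not math.isfinite(x) or x <= 0:
        raise ValueError(f"potency must be a finite positive value in nM, got {x!r}")
    return -math.log10(x * 1e-9)


def cliff_value(y_i: float, y_j: float) -> float:
    """Cliff magnitude between two pChEMBL labels, |y_i − y_j|."""
    y_i, y_j = float(y_i), float(y_j)
    if not (math.isfinite(y_i) and math.isfinite(y_j)):
        raise ValueError("labels must be finite")
    return abs(y_i - y_j)


def fold_change(cliff: float) -> float:
    """Nanomolar fold change for a cliff magnitude: 10**cliff."""
    cliff = float(cliff)
    if not math.isfinite(cliff) or cliff < 0:
        raise ValueError(f"cliff must be a finite nonnegative value, got {cliff!r}")
    return 10.0**cliff


def label_mmp(delta_pki: float) -> MMPLabel:
    """Binary cliff label for an MMP: cliff iff ΔpKi ≥ 2, non-cliff iff ≤ 1."""
    delta_pki = float(delta_pki)
    if not math.isfinite(delta_pki) or delta_pki < 0:
        raise ValueError(f"delta_pki must be finite and nonnegative, got {delta_pki!r}")
    if delta_pki >= 2.0:
        return MMPLabel.CLIFF
    if delta_pki <= 1.0:
        return MMPLabel.NON_CLIFF
    return MMPLabel.EXCLUDED
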