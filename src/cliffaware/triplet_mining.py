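"""Online, batch-wise mining of activity-cliff triplets (ACTs).

Within a training batch, a conditional ACT is an ordered triple of
distinct molecules (anchor A, positive P, negative N) whose ground-truth
labels satisfy |y_A − y_P| ≤ cl and |y_A − y_N| > cu, where cl ("cliff
lower") and cu ("cliff upper") are the cliff cut-off hyperparameters.
Each triplet carries a soft margin m = |y_A − y_N| − |y_A − y_P| taken
from the labels, not a fixed constant.

High-value ACTs (HV-ACTs) are the conditional ACTs whose triplet hinge
loss is currently positive under the model's latent vectors; their count
M′ ≤ M shrinks as the latent space becomes activity-coherent, which is
the quantity monitored during training.

Mining is batch-all: every qualifying ordered triple is enumerated (no
subsampling), in lexicographic (A, P, N) order, so M and M′ are exactly
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CliffCutoffs",
    "Triplet",
    "TripletSet",
    "MiningResult",
    "mine_conditional_triplets",
    "soft_margin",
    "flag_high_value",
]


@dataclass(frozen=True)
class CliffCutoffs:
    """Cliff cut-offs in pChEMBL units; cl ≤ cu (equality allowed)."""

    cl: float
    cu: float

    def __post_init__(self):
        if not (np.isfinite(self.cl) and np.isfinite(self.cu)):
            raise ValueError("cutoffs must be finite")
        if self.cl < 0 or self.cu < 0:
            raise ValueError("cutoffs must be nonnegative")
        if self.cl > self.cu:
            raise ValueError(f"cliff lower ({self.cl}) must not exceed cliff upper ({self.cu})")


@dataclass(frozen=True)
class Triplet:
    """(anchor, positive, negative) batch indices with their soft margin."""

    anchor: int
    positive: int
    negative: int
    margin: float


class TripletSet:
    """A set of mined triplets stored as flat index/margin arrays.

    Behaves as a sequence of :class:`Triplet`; the array attributes
    (``anchor``, ``positive``, ``negative``, ``margin``) are the fast
    path used by the losses and the training loop.
    """

    def __init__(self, anchor, positive, negative, margin, gap_ap=None, gap_an=None):
        self.anchor = np.asarray(anchor, dtype=np.int64)
        self.positive = np.asarray(positive, dtype=np.int64)
        self.negative = np.asarray(negative, dtype=np.int64)
        self.margin = np.asarray(margin, dtype=np.float64)
        # ground-truth label gaps |y_A−y_P| and |y_A−y_N|, needed for the
        # squared margin m² = gap_an² − gap_ap²
        self.gap_ap = None if gap_ap is None else np.asarray(gap_ap, dtype=np.float64)
        self.gap_an = None if gap_an is None else np.asarray(gap_an, dtype=np.float64)
        if not (
            self.anchor.shape == self.positive.shape == self.negative.shape == self.margin.shape
        ):
            raise ValueError("triplet arrays must share one length")

    def __len__(self) -> int:
        return self.anchor.shape[0]

    def __getitem__(self, j: int) -> Triplet:
        return Triplet(
            int(self.anchor[j]),
            int(self.positive[j]),
            int(self.negative[j]),
            float(self.margin[j]),
        )

    def __iter__(self):
        for j in range(len(self)):
            yield self[j]

    def __repr__(self):
        return f"TripletSet(M={len(self)})"

    @classmethod
    def empty(cls) -> "TripletSet":
        return cls([], [], [], [], [], [])


@dataclass
class MiningResult:
    """Conditional triplets (count M) and the high-value mask (count M′)."""

    conditional_triplets: TripletSet
    hv_mask: np.ndarray

    @property
    def m(self) -> int:
        return len(self.conditional_triplets)

    @property
    def m_prime(self) -> int:
        return int(self.hv_mask.sum())


def soft_margin(y_a: float, y_p: float, y_n: float) -> float:
    """Per-triplet soft margin |y_A − y_N| − |y_A − y_P| from the labels."""
    vals = (float(y_a), float(y_p), float(y_n))
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("labels must be finite")
    y_a, y_p, y_n = vals
    return abs(y_a - y_n) - abs(y_a - y_p)


def mine_conditional_triplets(labels, cutoffs: CliffCutoffs) -> TripletSet:
    """Enumerate every conditional ACT in a batch of labels.

    Returns all ordered triples (A, P, N) of distinct indices with
    |y_A − y_P| ≤ cl and |y_A − y_N| > cu, each with its soft margin, in
    lexicographic (A, P, N) order.  Batches smaller than 3 yield an
    empty set with a warning.
    """
    labels = np.asarray(labels, dtype=np.float64).ravel()
    if not np.isfinite(labels).all():
        raise ValueError("labels must be finite")
    n = labels.shape[0]
    if n < 3:
        warnings.warn(f"batch of size {n} < 3 cannot contain triplets")
        return TripletSet.empty()
    diff = np.abs(labels[:, None] - labels[None, :])
    off_diag = ~np.eye(n, dtype=bool)
    pos_mask = (diff <= cutoffs.cl) & off_diag
    neg_mask = (diff > cutoffs.cu) & off_diag
    anchors, positives, negatives = [], [], []
    for a in range(n):
        p_idx = np.flatnonzero(pos_mask[a])
        n_idx = np.flatnonzero(neg_mask[a])
        if p_idx.size == 0 or n_idx.size == 0:
            continue
        anchors.append(np.full(p_idx.size * n_idx.size, a, dtype=np.int64))
        positives.append(np.repeat(p_idx, n_idx.size))
        negatives.append(np.tile(n_idx, p_idx.size))
    if not anchors:
        return TripletSet.empty()
    a = np.concatenate(anchors)
    p = np.concatenate(positives)
    neg = np.concatenate(negatives)
    gap_ap = diff[a, p]
    gap_an = diff[a, neg]
    return TripletSet(a, p, neg, gap_an - gap_ap, gap_ap, gap_an)


def _latent_distances(latents: np.ndarray, i: np.ndarray, j: np.ndarray, p: float):
    d = latents[i] - latents[j]
    if p == 2:
        return np.sqrt((d * d).sum(axis=1))
    return (np.abs(d) ** p).sum(axis=1) ** (1.0 / p)


def flag_high_value(
    triplets: TripletSet,
    latents: np.ndarray,
    squared: bool = False,
    p: float = 2,
) -> MiningResult:
    """Mark the conditional triplets whose hinge term is currently positive.

    Plain form: [d(A,P) − d(A,N) + m]_+ with the latent p-norm distance.
    Squared form: [d²(A,P) − d²(A,N) + m²]_+ with squared Euclidean
    latent distances and the squared margin m² = |y_A−y_N|² − |y_A−y_P|²
    from the label gaps stored on the triplet set.
    """
    latents = np.asarray(latents, dtype=np.float64)
    if latents.ndim != 2:
        raise ValueError("latents must be a 2-D matrix [n, d]")
    if len(triplets) == 0:
        return MiningResult(triplets, np.zeros(0, dtype=bool))
    for idx in (triplets.anchor, triplets.positive, triplets.negative):
        if idx.max(initial=-1) >= latents.shape[0]:
            raise ValueError("triplet index outside the latent matrix")
    a, pi, ni = triplets.anchor, triplets.positive, triplets.negative
    # unique-pair distances: O(batch²) instead of O(M) memory
    n = latents.shape[0]
    m_count = len(triplets)
    ids = np.concatenate([a * n + pi, a * n + ni])
    uniq, inverse = np.unique(ids, return_inverse=True)
    if squared:
        pair_d = ((latents[uniq // n] - latents[uniq % n]) ** 2).sum(axis=1)
        margin = _squared_margins(triplets)
    else:
        pair_d = _latent_distances(latents, uniq // n, uniq % n, p)
        margin = triplets.margin
    bracket = pair_d[inverse[:m_count]] - pair_d[inverse[m_count:]] + margin
    return MiningResult(triplets, bracket > 0)


def _squared_margins(triplets: TripletSet) -> np.ndarray:
    """m² = |y_A−y_N|² − |y_A−y_P|² from the stored label gaps."""
    if triplets.gap_an is None or triplets.gap_ap is None:
        raise ValueError(
            "squared margins need the per-triplet label gaps; "
            "mine triplets with mine_conditional_triplets()"
        )
    return triplets.gap_an**2 - triplets.gap_ap**2
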