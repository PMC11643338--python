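"""The activity-cliff-awareness (ACA) loss family.

For regression the ACA loss is

    L_aca  = L_mae + α · L_tsm            (plain)
    L_aca2 = L_mse + α · L_tsm2           (squared)

where L_tsm is the triplet loss with soft margin over the high-value
activity-cliff triplets mined in the batch:

    L_tsm  = (1/M′) Σ_j [ ‖f_A − f_P‖₂ − ‖f_A − f_N‖₂ + m_j ]_+
    m_j    = |y_A − y_N| − |y_A − y_P|

and the squared variant replaces distances and margins by their squares
so its scale matches the MSE term.  M′ counts the triplets whose hinge
is positive; when no triplet is violated (or none is mined) the
contrastive term is zero and the ACA loss reduces to the regression
loss.  α ≥ 0 is the awareness factor: α = 0 is the AC-agnostic model.

For cliff classification on matched molecular pairs, a paired
contrastive loss pushes cliff pairs apart and pulls non-cliff pairs
together in cosine similarity,

    L_pcl = Σ_i [ y_i (1 + sim(f_Ai, f_Bi)) + (1 − y_i)(1 − sim(f_Ai, f_Bi)) ],

combined with the binary cross-entropy classification loss as
L = L_cls + α · L_pcl.

Every function accepts either plain NumPy arrays (returning floats) or
:class:`~cliffaware.nn.tensor.Tensor` values (returning tensors wired
into the autodiff graph), so the same code path serves evaluation and
training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .nn.tensor import Tensor, as_tensor, gather_rows
from .triplet_mining import (
    CliffCutoffs,
    TripletSet,
    _squared_margins,
    mine_conditional_triplets,
)

__all__ = [
    "ACALossConfig",
    "LossBreakdown",
    "mae_loss",
    "mse_loss",
    "tsm_loss",
    "tsm_loss_squared",
    "aca_loss",
    "pair_contrastive_loss",
    "classification_total_loss",
]

ArrayOrTensor = Union[np.ndarray, Tensor]


@dataclass
class ACALossConfig:
    """Hyperparameters of the ACA loss.

    alpha — awareness factor weighting the contrastive term (default 0.1);
    cl / cu — cliff lower / upper cut-offs in pChEMBL units (default 1.0
    each, the single-cut-off setting that maximizes the number of mined
    triplets); squared — use the MSE + squared-triplet variant; p — norm
    order for the latent distance in the plain triplet term (default 2,
    Euclidean).
    """

    alpha: float = 0.1
    cl: float = 1.0
    cu: float = 1.0
    squared: bool = False
    p: float = 2

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        self.cutoffs  # validate cl <= cu

    @property
    def cutoffs(self) -> CliffCutoffs:
        return CliffCutoffs(self.cl, self.cu)


@dataclass
class LossBreakdown:
    """ACA loss split into its parts plus the mining counts of the batch."""

    total: ArrayOrTensor
    regression_term: ArrayOrTensor
    contrastive_term: ArrayOrTensor
    m_conditional: int
    m_high_value: int


def _pair(predictions, labels):
    pred = as_tensor(predictions)
    lab = as_tensor(labels)
    if pred.data.shape != lab.data.shape:
        raise ValueError(
            f"shape mismatch: predictions {pred.data.shape} vs labels {lab.data.shape}"
        )
    if pred.data.size == 0:
        raise ValueError("empty prediction vector")
    return pred, lab


def _maybe_float(value: Tensor, like_inputs) -> ArrayOrTensor:
    if any(isinstance(x, Tensor) for x in like_inputs):
        return value
    return float(value.data)


def mae_loss(predictions, labels) -> ArrayOrTensor:
    """Mean absolute error (1/N) Σ |y_i − ŷ_i|."""
    pred, lab = _pair(predictions, labels)
    return _maybe_float((pred - lab).abs().mean(), (predictions,))


def mse_loss(predictions, labels) -> ArrayOrTensor:
    """Mean squared error (1/N) Σ (y_i − ŷ_i)²."""
    pred, lab = _pair(predictions, labels)
    return _maybe_float(((pred - lab) ** 2).mean(), (predictions,))


def _tsm(latents, triplets: TripletSet, squared: bool, p: float):
    lat = as_tensor(latents)
    if lat.data.ndim != 2:
        raise ValueError("latents must be a 2-D matrix [n, d]")
    if len(triplets) == 0:
        return Tensor(0.0), 0
    # many triplets share (A,P)/(A,N) pairs, so compute each unique pair
    # distance once and gather — O(batch²) work instead of O(M)
    n = lat.data.shape[0]
    m_count = len(triplets)
    ids = np.concatenate(
        [
            triplets.anchor * n + triplets.positive,
            triplets.anchor * n + triplets.negative,
        ]
    )
    uniq, inverse = np.unique(ids, return_inverse=True)
    delta = gather_rows(lat, uniq // n) - gather_rows(lat, uniq % n)
    if squared:
        pair_d = (delta**2).sum(axis=1)
        margin = _squared_margins(triplets)
    else:
        if p == 2:
            pair_d = ((delta * delta).sum(axis=1)).sqrt()
        else:
            pair_d = (delta.abs() ** p).sum(axis=1) ** (1.0 / p)
        margin = triplets.margin
    d_ap = gather_rows(pair_d, inverse[:m_count])
    d_an = gather_rows(pair_d, inverse[m_count:])
    bracket = d_ap - d_an + Tensor(margin)
    m_prime = int((bracket.data > 0).sum())
    if m_prime == 0:
        # every conditional triplet already satisfied
        return Tensor(0.0), 0
    # non-violated brackets are clipped by the hinge, so summing the
    # ReLU over all triplets equals summing over the high-value subset
    return bracket.relu().sum() / float(m_prime), m_prime


def tsm_loss(latents, triplets: TripletSet, p: float = 2):
    """Triplet soft-margin loss averaged over high-value triplets.

    Returns ``(loss, m_prime)``; the loss is 0 when no conditional
    triplet exists or none is violated.
    """
    loss, m_prime = _tsm(latents, triplets, squared=False, p=p)
    return _maybe_float(loss, (latents,)), m_prime


def tsm_loss_squared(latents, triplets: TripletSet):
    """Squared triplet loss with squared margins (scale of the MSE loss)."""
    loss, m_prime = _tsm(latents, triplets, squared=True, p=2)
    return _maybe_float(loss, (latents,)), m_prime


def aca_loss(predictions, labels, latents, config: ACALossConfig) -> LossBreakdown:
    """Full ACA loss of one batch: mine triplets from the labels, combine
    the regression and contrastive terms per the configuration."""
    labels_np = labels.data if isinstance(labels, Tensor) else np.asarray(labels, float)
    triplets = mine_conditional_triplets(labels_np, config.cutoffs)
    pred, lab = _pair(predictions, labels)
    if config.squared:
        regression = ((pred - lab) ** 2).mean()
    else:
        regression = (pred - lab).abs().mean()
    contrastive, m_prime = _tsm(latents, triplets, squared=config.squared, p=config.p)
    total = regression + float(config.alpha) * contrastive
    inputs = (predictions, latents)
    return LossBreakdown(
        total=_maybe_float(total, inputs),
        regression_term=_maybe_float(regression, inputs),
        contrastive_term=_maybe_float(contrastive, inputs),
        m_conditional=len(triplets),
        m_high_value=m_prime,
    )


def _cosine_similarity(a: Tensor, b: Tensor) -> Tensor:
    norm_a = ((a * a).sum(axis=1)).sqrt()
    norm_b = ((b * b).sum(axis=1)).sqrt()
    if (norm_a.data == 0).any() or (norm_b.data == 0).any():
        raise ValueError("cosine similarity undefined for zero-norm latent vectors")
    return (a * b).sum(axis=1) / (norm_a * norm_b)


def pair_contrastive_loss(
    latents_a, latents_b, pair_labels, reduction: str = "sum"
) -> ArrayOrTensor:
    """Paired contrastive loss for MMP cliff classification.

    Each pair contributes y(1 + sim) + (1 − y)(1 − sim) ∈ [0, 2] with
    cosine similarity; cliff pairs (y = 1) are pushed to sim = −1,
    non-cliff pairs to sim = +1.  Reduction: "sum" (printed form) or
    "mean".
    """
    a, b = as_tensor(latents_a), as_tensor(latents_b)
    y = np.asarray(
        pair_labels.data if isinstance(pair_labels, Tensor) else pair_labels,
        dtype=np.float64,
    )
    if a.data.shape != b.data.shape:
        raise ValueError("latents_a and latents_b must have matching shapes")
    if y.shape[0] != a.data.shape[0]:
        raise ValueError("pair_labels length must match the number of pairs")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("pair_labels must be binary (1 = cliff)")
    if reduction not in ("sum", "mean"):
        raise ValueError(f"unknown reduction {reduction!r}")
    sim = _cosine_similarity(a, b)
    contrib = Tensor(y) * (1.0 + sim) + Tensor(1.0 - y) * (1.0 - sim)
    out = contrib.sum() if reduction == "sum" else contrib.mean()
    return _maybe_float(out, (latents_a, latents_b))


def _binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    # stable softplus(z) - y*z = relu(z) - y*z + log(1 + exp(-|z|))
    z = logits
    softplus = z.relu() + ((-(z.abs())).exp() + 1.0).log()
    return (softplus - Tensor(targets) * z).mean()


def classification_total_loss(
    class_logits,
    class_labels,
    latents_a,
    latents_b,
    pair_labels,
    alpha: float,
    reduction: str = "sum",
) -> ArrayOrTensor:
    """L_cls + α·L_pcl: binary cross-entropy on the cliff logit plus the
    paired contrastive term."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    logits = as_tensor(class_logits)
    targets = np.asarray(
        class_labels.data if isinstance(class_labels, Tensor) else class_labels,
        dtype=np.float64,
    )
    if logits.data.shape != targets.shape:
        raise ValueError("class_logits and class_labels must have matching shapes")
    cls = _binary_cross_entropy_with_logits(logits, targets)
    pcl = pair_contrastive_loss(
        as_tensor(latents_a), as_tensor(latents_b), pair_labels, reduction=reduction
    )
    total = cls + float(alpha) * pcl
    return _maybe_float(total, (class_logits, latents_a, latents_b))
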