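"""The ACA loss family: component oracles, zero-loss identities, gradients."""

import numpy as np
import pytest
from sklearn.metrics import log_loss

from cliffaware import (
    ACALossConfig,
    CliffCutoffs,
    TripletSet,
    aca_loss,
    classification_total_loss,
    mae_loss,
    mine_conditional_triplets,
    mse_loss,
    pair_contrastive_loss,
    tsm_loss,
    tsm_loss_squared,
)
from cliffaware.nn import Tensor


def test_regression_losses_match_scalar_loops(rng):
    pred = rng.normal(6, 1, size=50)
    lab = rng.normal(6, 1, size=50)
    assert mae_loss(pred, lab) == pytest.approx(
        sum(abs(p - l) for p, l in zip(pred, lab)) / 50
    )
    assert mse_loss(pred, lab) == pytest.approx(
        sum((p - l) ** 2 for p, l in zip(pred, lab)) / 50
    )
    assert mae_loss(lab, lab) == 0.0
    assert mae_loss([6.0, 7.0], [7.0, 6.0]) == 1.0
    assert mse_loss([6.0, 7.0], [7.0, 6.0]) == 1.0
    with pytest.raises(ValueError):
        mae_loss([1.0], [1.0, 2.0])


def test_tsm_loss_zero_when_latents_equal_labels(rng):
    labels = rng.uniform(4, 10, size=20)
    ts = mine_conditional_triplets(labels, CliffCutoffs(1.0, 1.0))
    assert len(ts) > 0
    loss, m_prime = tsm_loss(labels[:, None], ts)
    assert loss == 0.0 and m_prime == 0
    loss_sq, m_prime_sq = tsm_loss_squared(labels[:, None], ts)
    assert loss_sq == 0.0 and m_prime_sq == 0


def test_tsm_loss_empty_triplets_is_zero():
    loss, m_prime = tsm_loss(np.zeros((4, 2)), TripletSet.empty())
    assert loss == 0.0 and m_prime == 0


def test_tsm_single_triplet_hand_value():
    ts = TripletSet([0], [1], [2], [1.8], [0.2], [2.0])
    latents = np.array([[0.0], [1.0], [-1.0]])  # d(A,P) = d(A,N) = 1
    loss, m_prime = tsm_loss(latents, ts)
    assert loss == pytest.approx(1.8) and m_prime == 1


def test_tsm_squared_hand_value():
    # labels (6, 6.2, 8): m^2 = 2^2 - 0.2^2 = 3.96 for anchor 0
    mined = mine_conditional_triplets([6.0, 6.2, 8.0], CliffCutoffs(0.5, 1.0))
    first = mined[0]
    assert (first.anchor, first.positive, first.negative) == (0, 1, 2)
    np.testing.assert_allclose(
        (mined.gap_an**2 - mined.gap_ap**2)[0], 3.96
    )
    ts = TripletSet([0], [1], [2], [1.8], [0.2], [2.0])
    # squared latent distances 1 and 2 -> bracket 1 - 2 + 3.96 = 2.96
    latents = np.array([[0.0], [1.0], [np.sqrt(2.0)]])
    loss, m_prime = tsm_loss_squared(latents, ts)
    assert loss == pytest.approx(2.96) and m_prime == 1


def test_tsm_matches_scalar_loop_oracle(rng):
    labels = rng.uniform(4, 10, size=12)
    latents = rng.normal(size=(12, 5))
    ts = mine_conditional_triplets(labels, CliffCutoffs(1.0, 1.0))
    total, m_prime = 0.0, 0
    for t in ts:
        d_ap = np.linalg.norm(latents[t.anchor] - latents[t.positive])
        d_an = np.linalg.norm(latents[t.anchor] - latents[t.negative])
        bracket = d_ap - d_an + t.margin
        if bracket > 0:
            total += bracket
            m_prime += 1
    loss, reported = tsm_loss(latents, ts)
    assert reported == m_prime
    assert loss == pytest.approx(total / m_prime)


def test_aca_loss_reduces_to_regression_at_alpha_zero(rng):
    labels = rng.uniform(4, 10, size=16)
    pred = labels + rng.normal(0, 0.5, size=16)
    latents = rng.normal(size=(16, 4))
    out = aca_loss(pred, labels, latents, ACALossConfig(alpha=0.0))
    assert out.total == mae_loss(pred, labels)  # bit-exact
    assert out.contrastive_term >= 0


def test_aca_loss_zero_at_perfect_fit_and_aligned_latents(rng):
    labels = rng.uniform(4, 10, size=16)
    out = aca_loss(labels, labels, labels[:, None], ACALossConfig(alpha=1.0))
    assert out.total == 0.0


def test_aca_loss_combines_component_oracles(rng):
    labels = np.array([5.0, 5.1, 7.2, 7.3, 5.05, 9.0, 4.9, 7.15])
    pred = labels + rng.normal(0, 0.3, size=8)
    latents = rng.normal(size=(8, 3))
    config = ACALossConfig(alpha=1.0, cl=0.5, cu=1.5)
    out = aca_loss(pred, labels, latents, config)
    ts = mine_conditional_triplets(labels, CliffCutoffs(0.5, 1.5))
    contrastive, m_prime = tsm_loss(latents, ts)
    assert out.m_conditional == len(ts)
    assert out.m_high_value == m_prime
    assert out.total == pytest.approx(mae_loss(pred, labels) + contrastive)
    # squared variant combines MSE with the squared triplet term
    out_sq = aca_loss(pred, labels, latents, ACALossConfig(alpha=1.0, squared=True))
    ts_sq = mine_conditional_triplets(labels, CliffCutoffs(1.0, 1.0))
    sq_term, _ = tsm_loss_squared(latents, ts_sq)
    assert out_sq.total == pytest.approx(mse_loss(pred, labels) + sq_term)


def test_tsm_gradient_matches_finite_differences(rng):
    for _ in range(20):
        labels = rng.uniform(4, 10, size=8)
        latents = rng.normal(size=(8, 3))
        ts = mine_conditional_triplets(labels, CliffCutoffs(1.0, 1.0))
        if len(ts) == 0:
            continue
        t = Tensor(latents, requires_grad=True)
        loss, m_prime = tsm_loss(t, ts)
        if m_prime == 0:
            continue
        # stay away from hinge kinks where the loss is not differentiable
        brackets = []
        for trip in ts:
            d_ap = np.linalg.norm(latents[trip.anchor] - latents[trip.positive])
            d_an = np.linalg.norm(latents[trip.anchor] - latents[trip.negative])
            brackets.append(d_ap - d_an + trip.margin)
        if np.min(np.abs(brackets)) < 1e-3:
            continue
        loss.backward()
        eps = 1e-6
        for idx in [(0, 0), (3, 1), (7, 2)]:
            hi = latents.copy()
            hi[idx] += eps
            lo = latents.copy()
            lo[idx] -= eps
            num = (tsm_loss(hi, ts)[0] - tsm_loss(lo, ts)[0]) / (2 * eps)
            assert t.grad[idx] == pytest.approx(num, abs=1e-4)
        return
    pytest.fail("no differentiable instance found")


def test_pair_contrastive_endpoints_and_hand_value():
    cliff = np.array([1.0])
    non_cliff = np.array([0.0])
    a = np.array([[1.0, 0.0]])
    # cliff pair at sim = -1 contributes 0
    assert pair_contrastive_loss(a, -a, cliff) == pytest.approx(0.0)
    # non-cliff pair at sim = +1 contributes 0
    assert pair_contrastive_loss(a, a, non_cliff) == pytest.approx(0.0)
    # cliff pair at sim = 0 contributes 1
    b = np.array([[0.0, 1.0]])
    assert pair_contrastive_loss(a, b, cliff) == pytest.approx(1.0)


def test_pair_contrastive_bounds_and_errors(rng):
    a = rng.normal(size=(30, 4))
    b = rng.normal(size=(30, 4))
    y = (rng.random(30) < 0.5).astype(float)
    total = pair_contrastive_loss(a, b, y)
    per_pair = [
        pair_contrastive_loss(a[i : i + 1], b[i : i + 1], y[i : i + 1])
        for i in range(30)
    ]
    assert all(0.0 <= v <= 2.0 for v in per_pair)
    assert total == pytest.approx(sum(per_pair))
    assert pair_contrastive_loss(a, b, y, reduction="mean") == pytest.approx(
        total / 30
    )
    with pytest.raises(ValueError):
        pair_contrastive_loss(np.zeros((1, 3)), a[:1], y[:1])
    with pytest.raises(ValueError):
        pair_contrastive_loss(a, b, y * 0.5)


def test_classification_total_loss_components(rng):
    logits = rng.normal(size=20)
    labels = (rng.random(20) < 0.5).astype(float)
    a = rng.normal(size=(20, 4))
    b = rng.normal(size=(20, 4))
    bce = log_loss(labels, 1 / (1 + np.exp(-logits)), labels=[0, 1])
    # alpha = 0: classification loss alone
    assert classification_total_loss(logits, labels, a, b, labels, 0.0) == pytest.approx(bce)
    expected = bce + 0.3 * pair_contrastive_loss(a, b, labels)
    assert classification_total_loss(logits, labels, a, b, labels, 0.3) == pytest.approx(expected)


def test_classification_loss_near_zero_when_separated():
    logits = np.array([20.0, -20.0])
    labels = np.array([1.0, 0.0])
    a = np.array([[1.0, 0.0], [0.0, 1.0]])
    b = np.array([[-1.0, 0.0], [0.0, 1.0]])  # cliff at sim -1, non-cliff at sim 1
    assert classification_total_loss(logits, labels, a, b, labels, 1.0) < 1e-6


def test_loss_config_validation():
    with pytest.raises(ValueError):
        ACALossConfig(alpha=-0.1)
    with pytest.raises(ValueError):
        ACALossConfig(cl=2.0, cu=1.0)
    with pytest.raises(ValueError):
        ACALossConfig(p=0.5)
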