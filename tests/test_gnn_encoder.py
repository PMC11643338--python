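"""Encoder construction, invariances, pooling, and pair classification."""

import numpy as np
import pytest

from cliffaware import (
    EncoderConfig,
    GraphBatch,
    MoleculeRecord,
    build_encoder,
    build_pair_classifier,
    featurize_batch,
    forward,
    global_max_pool,
)

SMALL = dict(conv_channels=(8, 16), head_widths=(8,))


@pytest.mark.parametrize("backbone", ["gcn", "gat", "gin", "pna"])
def test_all_backbones_forward_shapes(backbone, small_batch):
    enc = build_encoder(EncoderConfig(backbone=backbone, **SMALL), seed=3)
    pred, latents = forward(enc, small_batch)
    assert pred.shape == (small_batch.n_graphs,)
    assert latents.shape == (small_batch.n_graphs, 16)
    assert np.isfinite(pred).all() and np.isfinite(latents).all()


def test_latent_dim_follows_last_conv_channel():
    assert EncoderConfig(conv_channels=(8, 16)).latent_dim == 16
    assert EncoderConfig().latent_dim == 512  # default channel plan


def test_default_architecture_settings():
    cfg = EncoderConfig()
    assert cfg.backbone == "pna"
    assert cfg.conv_channels == (64, 128, 256, 512)
    assert cfg.head_widths == (256, 128, 32)
    assert cfg.batch_norm and cfg.dropout == 0.0


@pytest.mark.parametrize("backbone", ["gcn", "gat", "gin", "pna"])
def test_seeded_build_is_reproducible(backbone, small_batch):
    cfg = EncoderConfig(backbone=backbone, **SMALL)
    enc1 = build_encoder(cfg, seed=7)
    enc2 = build_encoder(cfg, seed=7)
    for a, b in zip(enc1.state_arrays(), enc2.state_arrays()):
        np.testing.assert_array_equal(a, b)
    p1, l1 = forward(enc1, small_batch)
    p2, l2 = forward(enc2, small_batch)
    np.testing.assert_array_equal(p1, p2)
    np.testing.assert_array_equal(l1, l2)


def test_gin_exposes_trainable_epsilon():
    enc = build_encoder(EncoderConfig(backbone="gin", **SMALL))
    scalars = [p for p in enc.parameters() if p.data.ndim == 0]
    assert len(scalars) == len(SMALL["conv_channels"])


def _permute_batch_nodes(batch: GraphBatch, perm: np.ndarray) -> GraphBatch:
    inverse = np.empty_like(perm)
    inverse[perm] = np.arange(len(perm))
    return GraphBatch(
        node_features=batch.node_features[perm],
        edge_index=inverse[batch.edge_index],
        edge_features=batch.edge_features,
        node_graph=batch.node_graph[perm],
        y=batch.y,
        n_graphs=batch.n_graphs,
    )


@pytest.mark.parametrize("backbone", ["gcn", "gat", "gin", "pna"])
def test_atom_permutation_invariance(backbone, rng):
    batch = featurize_batch([MoleculeRecord("CC(=O)Nc1ccccc1O", 6.0)])
    enc = build_encoder(EncoderConfig(backbone=backbone, **SMALL), seed=0)
    pred, lat = forward(enc, batch)
    perm = rng.permutation(batch.node_features.shape[0])
    pred_p, lat_p = forward(enc, _permute_batch_nodes(batch, perm))
    np.testing.assert_allclose(pred, pred_p, atol=1e-10)
    np.testing.assert_allclose(lat, lat_p, atol=1e-10)


def test_molecule_permutation_permutes_outputs(small_records):
    enc = build_encoder(EncoderConfig(backbone="gcn", **SMALL), seed=0)
    batch = featurize_batch(small_records)
    pred, lat = forward(enc, batch)
    reordered = featurize_batch(small_records[::-1])
    pred_r, lat_r = forward(enc, reordered)
    np.testing.assert_allclose(pred_r, pred[::-1], atol=1e-12)
    np.testing.assert_allclose(lat_r, lat[::-1], atol=1e-12)


def test_duplicated_molecule_gets_identical_prediction(small_records):
    enc = build_encoder(EncoderConfig(backbone="pna", **SMALL), seed=0)
    doubled = small_records + [small_records[0]]
    pred, _ = forward(enc, featurize_batch(doubled))
    assert pred[0] == pytest.approx(pred[-1], abs=1e-12)


def test_unknown_backbone_rejected():
    with pytest.raises(ValueError):
        EncoderConfig(backbone="transformer")


def test_global_max_pool_values():
    feats = np.array([[1.0, 5.0], [3.0, 2.0], [7.0, -1.0]])
    out = global_max_pool(feats, np.array([0, 0, 1]))
    np.testing.assert_array_equal(out, [[3.0, 5.0], [7.0, -1.0]])
    single = global_max_pool(feats[:1], np.array([0]))
    np.testing.assert_array_equal(single, feats[:1])
    with pytest.raises(ValueError):
        global_max_pool(feats, np.array([0, 0, 2]))  # molecule 1 has no nodes


def test_global_max_pool_node_permutation_invariant(rng):
    feats = rng.normal(size=(10, 4))
    membership = np.array([0] * 4 + [1] * 6)
    out = global_max_pool(feats, membership)
    perm = np.concatenate([rng.permutation(4), 4 + rng.permutation(6)])
    np.testing.assert_array_equal(
        out, global_max_pool(feats[perm], membership)
    )


def test_latents_are_pooled_conv_outputs(small_batch):
    """The latent fed to the triplet loss is the GMP readout, not a head
    activation: its width equals the last conv channel, and pooling the
    conv stack directly reproduces it."""
    enc = build_encoder(EncoderConfig(backbone="gcn", **SMALL), seed=0)
    _, lat = forward(enc, small_batch)
    pooled = enc.encode(small_batch, training=False)
    np.testing.assert_array_equal(lat, pooled.data)
    assert lat.shape[1] == enc.config.conv_channels[-1]
    assert lat.shape[1] != enc.config.head_widths[-1]


def test_pair_classifier_shapes_and_sharing(small_records):
    clf = build_pair_classifier(
        EncoderConfig(backbone="gcn", task="pair_classification", **SMALL), seed=0
    )
    batch_a = featurize_batch(small_records[:3])
    batch_b = featurize_batch(small_records[3:])
    logits, lat_a, lat_b = clf(batch_a, batch_b)
    assert logits.data.shape == (3,)
    assert lat_a.data.shape == (3, 16) and lat_b.data.shape == (3, 16)
    # shared trunk: swapping the inputs swaps the latents
    _, lat_b2, lat_a2 = clf(batch_b, batch_a)
    np.testing.assert_array_equal(lat_a.data, lat_a2.data)
    np.testing.assert_array_equal(lat_b.data, lat_b2.data)
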