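"""Molecule table reading and graph featurization."""

import json

import numpy as np
import pytest

from cliffaware import (
    MoleculeRecord,
    feature_descriptor,
    featurize,
    featurize_batch,
    read_molecule_table,
    write_feature_descriptor,
)
from cliffaware.mol_graph_io import ATOM_FEATURE_DIM, BOND_FEATURE_DIM

ATOM_NAMES = feature_descriptor()["atom_features"]


def test_feature_dimensions_are_39_and_10():
    assert ATOM_FEATURE_DIM == 39
    assert BOND_FEATURE_DIM == 10
    g = featurize("CCO")
    assert g.node_features.shape == (3, 39)
    assert g.edge_features.shape == (4, 10)


@pytest.mark.parametrize(
    "smiles,n_atoms,n_edges",
    [("C", 1, 0), ("CCO", 3, 4), ("C1CC1", 3, 6), ("c1ccccc1", 6, 12)],
)
def test_atom_and_edge_counts(smiles, n_atoms, n_edges):
    g = featurize(smiles)
    assert g.n_atoms == n_atoms
    assert g.n_edges == n_edges
    # edge indices address valid atoms; each bond appears in both directions
    assert g.edge_index.max(initial=-1) < n_atoms
    fwd = {(int(i), int(j)) for i, j in g.edge_index.T}
    assert fwd == {(j, i) for i, j in fwd}


def test_both_directions_share_bond_features():
    g = featurize("C=CC#N")
    for e in range(0, g.n_edges, 2):
        np.testing.assert_array_equal(g.edge_features[e], g.edge_features[e + 1])


def test_ring_membership_flag():
    ring_col = ATOM_NAMES.index("in_ring")
    assert featurize("C1CC1").node_features[:, ring_col].all()
    assert not featurize("CCO").node_features[:, ring_col].any()


def test_featurization_is_deterministic_across_dialects():
    a = featurize("CCO")
    b = featurize("OCC")  # same molecule, different SMILES dialect
    np.testing.assert_array_equal(a.node_features, b.node_features)
    np.testing.assert_array_equal(a.edge_features, b.edge_features)
    np.testing.assert_array_equal(a.edge_index, b.edge_index)


def test_unknown_element_maps_to_other_slot_keeping_39_columns():
    g = featurize("[Zn]")
    other_col = ATOM_NAMES.index("element_other")
    assert g.node_features.shape == (1, 39)
    assert g.node_features[0, other_col] == 1.0


def test_largest_fragment_is_kept():
    g = featurize("CCO.[Na+].[Cl-]")  # salt stripped to the organic fragment
    assert g.n_atoms == 3


def test_unparseable_smiles_error_names_the_string():
    with pytest.raises(ValueError, match="not_a_smiles"):
        featurize("not_a_smiles")


def test_batch_membership_and_slicing_roundtrip(small_records, small_batch):
    batch = small_batch
    assert batch.n_graphs == len(small_records)
    assert batch.node_graph.shape[0] == batch.node_features.shape[0]
    np.testing.assert_array_equal(
        batch.y, [r.y for r in small_records]
    )
    for i, rec in enumerate(small_records):
        single = featurize(rec.smiles)
        np.testing.assert_array_equal(
            batch.node_features[batch.node_graph == i], single.node_features
        )


def test_batch_membership_example():
    batch = featurize_batch(
        [MoleculeRecord("C", 5.0), MoleculeRecord("CCO", 6.0)]
    )
    np.testing.assert_array_equal(batch.node_graph, [0, 1, 1, 1])
    assert batch.node_features.shape[0] == 4


def test_featurize_batch_errors():
    with pytest.raises(ValueError):
        featurize_batch([])
    with pytest.raises(ValueError, match=r"\[1\]"):
        featurize_batch(
            [MoleculeRecord("C", 5.0), MoleculeRecord("xx$yy", 6.0)]
        )


def test_read_molecule_table(tmp_path):
    path = tmp_path / "mols.csv"
    path.write_text("smiles,y\nCCO,6.0\nc1ccccc1,7.5\n")
    records = read_molecule_table(path)
    assert [r.smiles for r in records] == ["CCO", "c1ccccc1"]
    assert [r.y for r in records] == [6.0, 7.5]


def test_read_molecule_table_skips_bad_smiles(tmp_path):
    path = tmp_path / "mols.csv"
    path.write_text("smiles,y\nCCO,6.0\nnot_a_smiles,5.0\n")
    with pytest.warns(UserWarning, match="skipped 1"):
        records, skipped = read_molecule_table(path, return_skipped=True)
    assert len(records) == 1 and skipped == 1


def test_read_molecule_table_hard_errors(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text("smiles,y\n")
    with pytest.raises(ValueError, match="no data rows"):
        read_molecule_table(empty)
    bad_col = tmp_path / "cols.csv"
    bad_col.write_text("structure,y\nCCO,6.0\n")
    with pytest.raises(ValueError, match="smiles"):
        read_molecule_table(bad_col)
    all_bad = tmp_path / "bad.csv"
    all_bad.write_text("smiles,y\nzzz,6.0\n")
    with pytest.raises(ValueError, match="unparseable"), pytest.warns(UserWarning):
        read_molecule_table(all_bad)
    with pytest.raises(FileNotFoundError):
        read_molecule_table(tmp_path / "missing.csv")


def test_feature_descriptor_roundtrip(tmp_path):
    desc = feature_descriptor()
    assert len(desc["atom_features"]) == 39
    assert len(desc["bond_features"]) == 10
    out = tmp_path / "features.json"
    write_feature_descriptor(out)
    assert json.loads(out.read_text()) == desc
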