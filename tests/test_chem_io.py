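"""Featurization, dose transforms, scaffold splits and table loading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmal.chem_io import (
    FEATURE_DIM,
    EndpointDataset,
    SmilesParseError,
    TaskSpec,
    featurize_atom,
    load_endpoint_table,
    murcko_scaffold,
    scaffold_split,
    smiles_to_graph,
    transform_dose,
)
from pmal.synthetic import generate_molecules

BLOCKS = [(0, 44), (44, 61), (61, 78), (78, 95)]  # element, degree, implicit H, valence


class TestFeaturizeAtom:
    def test_vector_layout(self):
        v = featurize_atom("C", 2, 1, 4, aromatic=True)
        assert v.shape == (FEATURE_DIM,)
        for lo, hi in BLOCKS:
            assert v[lo:hi].sum() == 1.0
        assert v[95] == 1.0

    def test_aromatic_benzene_carbon_has_five_unit_entries(self):
        v = featurize_atom("C", 2, 1, 4, aromatic=True)
        assert np.count_nonzero(v) == 5
        assert set(np.unique(v)) == {0.0, 1.0}

    def test_nonaromatic_carbon_flag_zero(self):
        v = featurize_atom("C", 0, 4, 4, aromatic=False)
        assert v[95] == 0.0

    def test_unknown_element_maps_to_other_slot(self):
        v = featurize_atom("Xx", 1, 0, 1, aromatic=False)
        assert v[43] == 1.0

    def test_counts_above_sixteen_clamp(self):
        v = featurize_atom("C", 20, 0, 20, aromatic=False)
        assert v[44 + 16] == 1.0 and v[78 + 16] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            featurize_atom("C", -1, 0, 4, aromatic=False)


class TestSmilesToGraph:
    @pytest.mark.parametrize(
        "smiles,n_atoms,n_edges",
        [("c1ccccc1", 6, 6), ("C", 1, 0), ("CC", 2, 1), ("CCO", 3, 2)],
    )
    def test_topology(self, smiles, n_atoms, n_edges):
        g = smiles_to_graph(smiles)
        assert g.n_atoms == n_atoms and len(g.edges) == n_edges
        g.validate()

    def test_ethane_not_aromatic(self):
        g = smiles_to_graph("CC")
        assert np.all(g.node_features[:, 95] == 0.0)

    def test_parse_error_names_the_string(self):
        with pytest.raises(SmilesParseError, match="not_a_smiles"):
            smiles_to_graph("not_a_smiles")

    def test_canonicalization_makes_graph_order_independent(self):
        a = smiles_to_graph("OCC")
        b = smiles_to_graph("CCO")
        assert a.smiles == b.smiles
        assert np.array_equal(a.node_features, b.node_features)
        assert a.edges == b.edges

    def test_feature_dim_on_generated_pool(self):
        for s in generate_molecules(50, seed=7):
            g = smiles_to_graph(s)
            assert g.node_features.shape == (g.n_atoms, FEATURE_DIM)
            # every row is 4 one-hot blocks + flag
            for lo, hi in BLOCKS:
                assert np.all(g.node_features[:, lo:hi].sum(axis=1) == 1.0)


class TestTransformDose:
    @pytest.mark.parametrize("dose,expected", [(1.0, 0.0), (0.001, 3.0)])
    def test_reference_points(self, dose, expected):
        assert transform_dose(dose) == pytest.approx(expected)

    @given(st.floats(min_value=1e-9, max_value=1e3))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, dose):
        assert transform_dose(transform_dose(dose), "inverse") == pytest.approx(
            dose, rel=1e-9)

    @given(st.floats(min_value=1e-6, max_value=1e3),
           st.floats(min_value=1.0 + 1e-6, max_value=10.0))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing(self, dose, factor):
        assert transform_dose(dose * factor) < transform_dose(dose)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            transform_dose(0.0)


def _dataset_from_smiles(smiles_list):
    graphs = [smiles_to_graph(s) for s in smiles_list]
    n = len(graphs)
    labels = np.zeros((n, 1))
    return EndpointDataset(
        molecule_ids=[g.smiles for g in graphs], graphs=graphs,
        labels=labels, label_mask=np.ones((n, 1), bool),
        tasks=[TaskSpec(0, "t")],
    )


class TestScaffoldSplit:
    CORES = ["c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
             "C1CCCCC1", "C1CCCC1", "c1ccc2ccccc2c1", "C1CCNCC1", "C1CCOC1"]

    def test_ten_equal_groups_split_80_10_10(self):
        # 10 scaffold groups of 10 members (alkyl chains never change the core)
        smiles = [f"{'C' * k}{core}" for core in self.CORES for k in range(1, 11)]
        ds = _dataset_from_smiles(smiles)
        train, val, test = scaffold_split(ds, (8, 1, 1), seed=0)
        assert (len(train), len(val), len(test)) == (80, 10, 10)

    def test_single_scaffold_is_atomic(self):
        ds = _dataset_from_smiles([f"{'C' * k}c1ccccc1" for k in range(1, 7)])
        with pytest.warns(UserWarning, match="scaffold group"):
            train, val, test = scaffold_split(ds, seed=1)
        assert len(train) == 6 and len(val) == 0 and len(test) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_partition_and_scaffold_disjointness(self, seed):
        ds = _dataset_from_smiles(generate_molecules(120, seed=seed))
        parts = scaffold_split(ds, seed=seed)
        joined = np.concatenate(parts)
        assert sorted(joined) == list(range(ds.n_molecules))
        scaffolds = [
            {murcko_scaffold(ds.graphs[i].smiles) for i in part} for part in parts
        ]
        assert not (scaffolds[0] & scaffolds[1])
        assert not (scaffolds[0] & scaffolds[2])
        assert not (scaffolds[1] & scaffolds[2])


class TestLoadEndpointTable:
    def test_missing_cell_sets_mask(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("smiles,a,b\nCC,1.0,2.0\nCCO,,3.0\nc1ccccc1,4.0,5.0\n")
        ds = load_endpoint_table(p)
        assert ds.n_molecules == 3 and ds.n_tasks == 2
        assert (~ds.label_mask).sum() == 1
        assert not ds.label_mask[1, 0]

    def test_unparseable_rows_dropped(self, tmp_path, caplog):
        p = tmp_path / "d.csv"
        p.write_text("smiles,a\nCC,1.0\nxxxx,2.0\n")
        ds = load_endpoint_table(p)
        assert ds.n_molecules == 1

    def test_all_bad_smiles_warns(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("smiles,a\nxxxx,1.0\nyyyy,2.0\n")
        with pytest.warns(UserWarning, match="no parseable"):
            ds = load_endpoint_table(p)
        assert ds.n_molecules == 0

    def test_missing_smiles_column_errors(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("mol,a\nCC,1.0\n")
        with pytest.raises(ValueError, match="smiles"):
            load_endpoint_table(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("")
        with pytest.raises(Exception):
            load_endpoint_table(p)
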