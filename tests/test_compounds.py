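"""Compound parsing, descriptor definitions and conformer determinism."""

import itertools

import numpy as np
import networkx as nx
import pytest
from rdkit import Chem

from triadnet.compounds import (Compound, DescriptorRegistry, default_registry,
                                elemental_composition, embed_conformer, encode_compound,
                                encode_compounds, parse_structures, ring_descriptors)

from conftest import make_compound

MOLECULES = {
    "methane": "C",
    "water": "O",
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "cyclohexane": "C1CCCCC1",
    "pyridine": "c1ccncc1",
    "furan": "c1ccoc1",
    "spiro": "C1CCC2(CC1)CCCC2",
    "glycine": "NCC(=O)O",
}


class TestParsing:
    def test_smiles_file_order_and_count(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("C methane\nCCO ethanol\nc1ccccc1 benzene\n")
        out = parse_structures(p, "smiles")
        assert [c.id for c in out] == ["methane", "ethanol", "benzene"]
        assert out[0].mol.GetNumAtoms() == 1  # heavy atoms only

    def test_sdf_count_preservation(self, tmp_path):
        p = tmp_path / "in.sdf"
        w = Chem.SDWriter(str(p))
        for name in ("CCO", "c1ccccc1"):
            m = Chem.MolFromSmiles(name)
            m.SetProp("_Name", name)
            w.write(m)
        w.close()
        out = parse_structures(p, "sdf")
        assert [c.id for c in out] == ["CCO", "c1ccccc1"]

    def test_malformed_smiles_names_line(self, tmp_path):
        p = tmp_path / "bad.smi"
        p.write_text("C1CC unclosed\n")
        with pytest.raises(ValueError, match="line 1"):
            parse_structures(p, "smiles")

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.smi"
        p.write_text("")
        with pytest.raises(ValueError):
            parse_structures(p, "smiles")


class TestElementalComposition:
    @pytest.mark.parametrize("smiles, element, expected", [
        ("C", "C", 1 / 5),        # methane: 1 C of 5 atoms
        ("O", "O", 1 / 3),        # water
        ("CCO", "H", 6 / 9),      # ethanol: 6 H of 9 atoms
        ("CCO", "O", 1 / 9),
    ])
    def test_known_fractions(self, smiles, element, expected):
        assert elemental_composition(make_compound(smiles), element) == pytest.approx(expected)

    def test_fractions_partition_unity(self):
        # C + H + all heteroatoms must cover every atom exactly once
        for smiles in MOLECULES.values():
            c = make_compound(smiles)
            total = sum(elemental_composition(c, el)
                        for el in ("C", "H", "O", "N", "P", "S"))
            assert 0 <= total <= 1 + 1e-12


def _ring_oracle(mol):
    """Independent ring analysis from a minimum cycle basis (networkx)."""
    g = nx.Graph()
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    basis = nx.minimum_cycle_basis(g)
    edge_sets = []
    for cyc in basis:
        cyc_set = set(cyc)
        edges = frozenset(frozenset((u, v)) for u, v in g.edges()
                          if u in cyc_set and v in cyc_set)
        edge_sets.append(edges)
    n = len(basis)
    fused = sum(1 for i in range(n)
                if any(i != j and edge_sets[i] & edge_sets[j] for j in range(n)))
    sizes = sorted(len(c) for c in basis)
    return {"count": n, "sizes": sizes, "fused": fused}


class TestRingDescriptors:
    def test_benzene(self):
        d = ring_descriptors(make_compound("c1ccccc1"))
        assert d["RingCount"] == 1
        assert d["SmallestRingSize"] == 6
        assert d["CarboAromaticRingCount"] == 1
        assert d["FusedRingCount"] == 0

    def test_acyclic_all_zero(self):
        d = ring_descriptors(make_compound("C"))
        assert all(v == 0 for v in d.values())

    def test_naphthalene_fusion(self):
        d = ring_descriptors(make_compound("c1ccc2ccccc2c1"))
        assert d["FusedRingCount"] == 2
        assert d["RingSystemCount"] == 1
        assert d["SmallestRingSystemSize"] == 10

    def test_spiro_not_fused(self):
        # spiro rings share an atom but no bond
        d = ring_descriptors(make_compound("C1CCC2(CC1)CCCC2"))
        assert d["RingCount"] == 2 and d["FusedRingCount"] == 0

    @pytest.mark.parametrize("smiles", list(MOLECULES.values()))
    def test_against_cycle_basis_oracle(self, smiles):
        c = make_compound(smiles)
        d = ring_descriptors(c)
        o = _ring_oracle(c.mol)
        assert d["RingCount"] == o["count"]
        assert d["FusedRingCount"] == o["fused"]
        if o["count"]:
            assert d["SmallestRingSize"] == o["sizes"][0]
            assert d["LargestRingSize"] == o["sizes"][-1]

    def test_carbo_plus_hetero_partition(self):
        for smiles in MOLECULES.values():
            d = ring_descriptors(make_compound(smiles))
            assert d["CarboRingCount"] + d["HeteroRingCount"] == d["RingCount"]
            assert d["AromaticRingCount"] + d["AliphaticRingCount"] == d["RingCount"]


class TestConformer:
    def test_deterministic_for_fixed_seed(self):
        a = make_compound("CCOc1ccccc1", embed=True, seed=42)
        b = make_compound("CCOc1ccccc1", embed=True, seed=42)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_single_atom_at_origin(self):
        c = make_compound("[He]")
        embed_conformer(c, 0)
        np.testing.assert_array_equal(c.coords, np.zeros((1, 3)))

    def test_centroid_at_origin_and_axis_order(self):
        c = make_compound("C#CC#CC#C", embed=True, seed=1)  # elongated molecule
        np.testing.assert_allclose(c.coords.mean(axis=0), 0, atol=1e-9)
        spans = c.coords.max(axis=0) - c.coords.min(axis=0)
        assert spans[0] >= spans[1] >= spans[2]


class TestEncoding:
    def test_vector_length_is_registry_length(self, registry):
        c = make_compound("C", embed=True)
        vec = encode_compound(c, registry)
        assert len(vec.values) == 79
        assert np.all(np.isfinite(vec.values))

    def test_empty_registry_gives_empty_vector(self):
        c = make_compound("C", embed=True)
        vec = encode_compound(c, DescriptorRegistry([]))
        assert len(vec.values) == 0

    def test_registry_contract(self, registry):
        assert len(registry) == 79
        required = [
            "CComposition", "HComposition", "OComposition", "NComposition",
            "PComposition", "LogP", "Polarizability", "VanDerWaalsSurfaceArea",
            "WaterAccessibleSurfaceArea(Negative)", "MinZ", "RingCount",
            "SmallestRingSize", "SmallestRingSystemSize", "RotatableBondCount",
            "StereoDoubleBondCount", "FusedRingCount", "FusedAliphaticRingCount",
            "CarboRingCount", "CarboAliphaticRingCount", "CarboAromaticRingCount",
            "HeteroAliphaticRingCount",
        ]
        for name in required:
            assert name in registry.names
        assert set(registry.categories.values()) == {
            "elemental analysis", "geometry", "chemistry"}

    def test_encode_is_pure_in_structure_and_seed(self, registry):
        t1 = encode_compounds([make_compound(s, cid=f"m{i}")
                               for i, s in enumerate(MOLECULES.values())],
                              registry, seed=5)
        t2 = encode_compounds([make_compound(s, cid=f"m{i}")
                               for i, s in enumerate(MOLECULES.values())],
                              registry, seed=5)
        np.testing.assert_array_equal(t1.to_numpy(), t2.to_numpy())

    def test_count_descriptors_nonnegative_integers(self, registry):
        count_names = [n for n in registry.names if n.endswith("Count")]
        table = encode_compounds([make_compound(s, cid=f"m{i}")
                                  for i, s in enumerate(MOLECULES.values())],
                                 registry, seed=0)
        counts = table[count_names].to_numpy()
        assert np.all(counts >= 0)
        np.testing.assert_array_equal(counts, np.round(counts))
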