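"""Subgraph isomorphism, MCS mapping and symmetry orbits against
independent brute-force oracles."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from autosom import graph_map
from autosom.chem_prep import standardize
from autosom.fixtures import SCAFFOLDS
from oracles import (
    automorphism_orbits,
    exhaustive_subgraph_exists,
    max_common_subgraph_atoms,
)
from util import first_match


def mol(smiles: str) -> Chem.Mol:
    return standardize(Chem.MolFromSmiles(smiles))


@pytest.mark.parametrize(
    "small, large, expected",
    [
        ("c1ccccc1", "Oc1ccccc1", True),   # ring unchanged by hydroxylation
        ("Oc1ccccc1", "O=C1C=CC=CC1=O", False),  # aromatic ring lost
        ("CCO", "CCO", True),
    ],
)
def test_is_subgraph_matches_exhaustive_enumeration(small, large, expected):
    ms, ml = mol(small), mol(large)
    found, embeddings = graph_map.is_subgraph(ms, ml, bond_order_sensitive=True)
    assert found is expected
    assert exhaustive_subgraph_exists(ms, ml, bond_order_sensitive=True) is expected
    if expected:
        assert embeddings
        # every embedding is a partial isomorphism: mapped bonds agree
        gs, gl = graph_map.to_graph(ms), graph_map.to_graph(ml)
        for emb in embeddings:
            for u, v in gs.edges:
                assert gl.has_edge(emb[u], emb[v])
                assert gs.edges[u, v]["order"] == gl.edges[emb[u], emb[v]]["order"]


def test_identity_embedding_on_identical_molecule():
    m = mol("CCO")
    found, embeddings = graph_map.is_subgraph(m, m)
    assert found
    assert {i: i for i in range(m.GetNumAtoms())} in embeddings


@pytest.mark.parametrize(
    "sub, met, expected_atoms",
    [
        ("Nc1ccccc1", "Nc1ccccc1O", 7),     # aniline fully mapped, OH unmapped
        ("COC(=O)c1ccccc1", "OC(=O)c1ccccc1", 9),  # methyl C unmapped
        ("CCO", "CCO", 3),
    ],
)
def test_mcs_mapping_size_equals_bruteforce(sub, met, expected_atoms):
    ms, mm = mol(sub), mol(met)
    mapping = graph_map.mcs_mapping(ms, mm, bond_order_sensitive=True)
    assert mapping is not None
    assert len(mapping) == expected_atoms
    assert max_common_subgraph_atoms(ms, mm, bond_order_sensitive=True) == expected_atoms
    if sub == met:
        assert mapping.complete


def test_mcs_mapping_is_injective_and_element_preserving():
    ms, mm = mol("Nc1ccccc1"), mol("Nc1ccccc1O")
    mapping = graph_map.mcs_mapping(ms, mm)
    values = list(mapping.pairs.values())
    assert len(values) == len(set(values))
    for s, m in mapping.pairs.items():
        assert ms.GetAtomWithIdx(s).GetSymbol() == mm.GetAtomWithIdx(m).GetSymbol()


def test_aniline_ortho_carbons_share_an_orbit():
    m = mol("Nc1ccccc1")
    ipso = first_match(m, "[NX3]c")[1]
    orthos = {
        nb.GetIdx()
        for nb in m.GetAtomWithIdx(ipso).GetNeighbors()
        if nb.GetIsAromatic()
    }
    expanded = graph_map.symmetry_expand(m, {min(orthos)})
    assert expanded == orthos


def test_singleton_orbit_and_empty_set():
    m = mol("NC(=O)CCl")  # no symmetry
    for idx in range(m.GetNumAtoms()):
        assert graph_map.symmetry_expand(m, {idx}) == {idx}
    assert graph_map.symmetry_expand(m, set()) == frozenset()


@pytest.mark.parametrize("smiles", SCAFFOLDS)
def test_orbits_equal_bruteforce_automorphism_orbits(smiles):
    m = mol(smiles)
    assert set(graph_map.symmetry_orbits(m)) == automorphism_orbits(m)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(data=st.data())
def test_symmetry_expand_idempotent_and_monotone(data):
    smiles = data.draw(st.sampled_from(SCAFFOLDS))
    m = mol(smiles)
    soms = data.draw(
        st.sets(st.integers(min_value=0, max_value=m.GetNumAtoms() - 1), max_size=4)
    )
    once = graph_map.symmetry_expand(m, soms)
    assert soms <= set(once) or not soms
    assert graph_map.symmetry_expand(m, once) == once
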