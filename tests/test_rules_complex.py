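"""Complex handler: oxidative dehalogenation, full-isomorphism and MCS-based
SOMs, ring-hydrolysis corrections, handler ordering."""

import pytest
from rdkit import Chem

from autosom import chem_prep, pipeline
from autosom.records import (
    HETEROCYCLE_HYDROLYSIS,
    ISOMORPHISM_MAPPING,
    LACTONE_HYDROLYSIS,
    MCS_MAPPING,
    OXACYCLOPROPANE_HYDROLYSIS,
    OXIDATIVE_DEHALOGENATION,
    UNKNOWN,
    ReactionRecord,
    RuleConfig,
)
from autosom.rules_complex import (
    annotate_by_full_isomorphism,
    annotate_by_mcs_diff,
    annotate_oxidative_dehalogenation,
    handle_complex,
)
from util import first_match, pair_of


@pytest.mark.parametrize(
    "sub, met",
    [
        ("Clc1ccccc1", "Oc1ccccc1"),
        ("Cc1ccc(Cl)cc1", "Cc1ccc(O)cc1"),
        ("CCBr", "CCO"),
    ],
)
def test_oxidative_dehalogenation_som_is_halogenated_carbon(sub, met):
    pair = pair_of(sub, met)
    annotation = annotate_oxidative_dehalogenation(pair)
    assert annotation is not None
    assert annotation.rule == OXIDATIVE_DEHALOGENATION
    carbon = first_match(pair.substrate, "[#6][Cl,Br]")[0]
    assert annotation.som_indices == {carbon}


def test_epoxide_forming_dehalogenation_labels_both_ring_carbons():
    pair = pair_of("ClC=Cc1ccccc1", "c1ccccc1C1CO1")
    annotation = annotate_oxidative_dehalogenation(pair)
    assert annotation is not None
    alkene = set(first_match(pair.substrate, "[CX3]=[CX3]"))
    assert annotation.som_indices == alkene


def test_dehalogenation_requires_constant_carbon_count():
    pair = pair_of("CN1CCN(c2ccccc2)CC1", "C1CN(c2ccccc2)CCN1")
    assert annotate_oxidative_dehalogenation(pair) is None


def test_full_isomorphism_dehydrogenation_soms():
    # imidazoline -> imidazole: the two sp3 ring carbons lose one H each
    pair = pair_of("C1CN=C(c2ccccc2)N1", "c1ccc(-c2ncc[nH]2)cc1")
    annotation = annotate_by_full_isomorphism(pair)
    assert annotation is not None
    assert annotation.rule == ISOMORPHISM_MAPPING
    sp3 = set(first_match(pair.substrate, "[CX4H2][CX4H2]"))
    assert annotation.som_indices == sp3


def test_full_isomorphism_hydrogenation_of_alkene():
    pair = pair_of("CC=C", "CCC")
    annotation = annotate_by_full_isomorphism(pair)
    assert annotation is not None
    alkene = set(first_match(pair.substrate, "[CX3]=[CX3]"))
    assert annotation.som_indices == alkene


def test_full_isomorphism_invariant_under_atom_relabeling():
    sub_smiles, met_smiles = "CCc1ccccc1", "C=Cc1ccccc1"
    pair = pair_of(sub_smiles, met_smiles)
    base = annotate_by_full_isomorphism(pair)
    mol = pair.substrate
    order = list(range(mol.GetNumAtoms() - 1, -1, -1))  # reverse indices
    renumbered = Chem.RenumberAtoms(mol, order)
    permuted_pair = pair_of(Chem.MolToSmiles(renumbered), met_smiles)
    # recompute expectation structurally on the permuted substrate
    expected = set(first_match(permuted_pair.substrate, "[CX4;!H0][CX4;!H0]"))
    permuted = annotate_by_full_isomorphism(permuted_pair)
    assert set(first_match(pair.substrate, "[CX4;!H0][CX4;!H0]")) == base.som_indices
    assert permuted.som_indices == expected


def test_mcs_diff_covers_both_quinone_carbons():
    pair = pair_of("Oc1ccccc1", "O=C1C=CC=CC1=O")
    annotation = annotate_by_mcs_diff(pair)
    assert annotation is not None
    assert annotation.rule == MCS_MAPPING
    c_oh = first_match(pair.substrate, "c[OX2H]")[0]
    orthos = {
        nb.GetIdx()
        for nb in pair.substrate.GetAtomWithIdx(c_oh).GetNeighbors()
        if nb.GetIsAromatic()
    }
    assert {c_oh} | orthos <= annotation.som_indices


def test_mcs_diff_none_when_no_common_substructure():
    pair = pair_of("CCCC", "N#N")
    assert annotate_by_mcs_diff(pair) is None


def test_oxacyclopropane_correction_labels_both_ring_carbons():
    pair = pair_of("c1ccccc1C1CO1", "OCC(O)c1ccccc1")
    annotation = handle_complex(pair, RuleConfig())
    assert annotation.rule == OXACYCLOPROPANE_HYDROLYSIS
    ring = first_match(pair.substrate, "[#6]1[#8][#6]1")
    carbons = {i for i in ring if pair.substrate.GetAtomWithIdx(i).GetSymbol() == "C"}
    assert annotation.som_indices == carbons


def test_lactone_correction_som_is_carbonyl_carbon():
    pair = pair_of("O=C1CCCO1", "O=C(O)CCCO")
    annotation = handle_complex(pair, RuleConfig())
    assert annotation.rule == LACTONE_HYDROLYSIS
    carbonyl = first_match(pair.substrate, "[C;R](=O)[O;R]")[0]
    assert annotation.som_indices == {carbonyl}


def test_ether_ring_opening_labels_flanking_carbons():
    pair = pair_of("c1ccccc1C1CCCO1", "OCCCC(O)c1ccccc1")
    annotation = handle_complex(pair, RuleConfig())
    assert annotation.rule == HETEROCYCLE_HYDROLYSIS
    ring_o = first_match(pair.substrate, "[OX2;R]")[0]
    flanking = {
        nb.GetIdx()
        for nb in pair.substrate.GetAtomWithIdx(ring_o).GetNeighbors()
        if nb.GetSymbol() == "C"
    }
    assert annotation.som_indices == flanking


def test_non_ring_reaction_unaffected_by_ring_corrections():
    pair = pair_of("C=CC(=O)c1ccccc1", "O=C(c1ccccc1)C1CO1")
    annotation = handle_complex(pair, RuleConfig())
    assert annotation.rule == MCS_MAPPING
    alkene = set(first_match(pair.substrate, "[CX3H2]=[CX3H1]"))
    assert annotation.som_indices == alkene


def test_unmatchable_pair_is_unknown():
    pair, annotation = pipeline.annotate_record(ReactionRecord("CCCC", "N#N", 1, 2))
    assert annotation.rule == UNKNOWN
    assert annotation.som_indices == frozenset()
    assert annotation.status == "unknown"
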