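"""Addition handler: glutathione detection, general addition, carnitine
correction, and the ordering between them."""

import pytest

from autosom.graph_map import symmetry_expand
from autosom.records import (
    CARNITINE_CONJUGATION,
    GENERAL_ADDITION,
    GLUTATHIONE_CONJUGATION,
    RuleConfig,
)
from autosom.rules_addition import (
    annotate_general_addition,
    annotate_glutathione,
    carnitine_correction,
    handle_addition,
)
from util import first_match, pair_of

GSH_TAIL = "CC(NC(=O)CCC(N)C(=O)O)C(=O)NCC(=O)O"  # S-substituted glutathione


def test_glutathione_som_is_carbon_bonded_to_sulfur():
    # acrolein + GSH: the beta-carbon carries the new thioether
    pair = pair_of("C=CC=O", "O=CCCS" + GSH_TAIL)
    annotation = annotate_glutathione(pair)
    assert annotation is not None
    assert annotation.rule == GLUTATHIONE_CONJUGATION
    beta = first_match(pair.substrate, "[CH2]=[CH]")[0]
    assert annotation.som_indices == {beta}


def test_glutathione_ring_opened_epoxide():
    # styrene oxide conjugate: SOM is the ring-opened carbon bearing sulfur
    pair = pair_of("c1ccccc1C1CO1", "OC(c1ccccc1)CS" + GSH_TAIL)
    annotation = annotate_glutathione(pair)
    assert annotation is not None
    ring = first_match(pair.substrate, "[#6]1[#8][#6]1")
    carbons = [i for i in ring if pair.substrate.GetAtomWithIdx(i).GetSymbol() == "C"]
    # the terminal (CH2) ring carbon is the one that picked up the sulfur
    terminal = next(
        c for c in carbons if pair.substrate.GetAtomWithIdx(c).GetTotalNumHs() == 2
    )
    assert annotation.som_indices == {terminal}


def test_no_glutathione_without_tripeptide():
    pair = pair_of("Nc1ccccc1", "Nc1ccccc1O")
    assert annotate_glutathione(pair) is None


def test_general_addition_ortho_hydroxylation():
    pair = pair_of("Nc1ccccc1", "Nc1ccccc1O")
    annotation = annotate_general_addition(pair)
    assert annotation is not None
    assert annotation.rule == GENERAL_ADDITION
    ipso = first_match(pair.substrate, "[NX3]c")[1]
    orthos = {
        nb.GetIdx()
        for nb in pair.substrate.GetAtomWithIdx(ipso).GetNeighbors()
        if nb.GetIsAromatic()
    }
    assert len(annotation.som_indices) == 1
    assert annotation.som_indices <= orthos
    assert symmetry_expand(pair.substrate, annotation.som_indices) == orthos


def test_acyl_glucuronidation_som_is_sp3_oxygen():
    pair = pair_of(
        "OC(=O)c1ccccc1", "O=C(OC1OC(C(=O)O)C(O)C(O)C1O)c1ccccc1"
    )
    annotation = annotate_general_addition(pair)
    assert annotation is not None
    hydroxyl_o = first_match(pair.substrate, "[CX3](=O)[OX2H]")[2]
    assert annotation.som_indices == {hydroxyl_o}


def test_bond_order_change_defeats_general_addition():
    # phenol -> 1,2-benzoquinone has no bond-order-sensitive embedding
    pair = pair_of("Oc1ccccc1", "O=C1C=CC=CC1=O")
    assert annotate_general_addition(pair) is None


def test_gating_on_heavy_atom_count():
    pair = pair_of("CCO", "CC")  # metabolite lighter
    assert annotate_general_addition(pair) is None


@pytest.mark.parametrize(
    "sub, met",
    [
        ("CCCCCC(=O)O", "CCCCCC(=O)OC(CC(=O)[O-])C[N+](C)(C)C"),
        ("CC(=O)O", "CC(=O)OC(CC(=O)[O-])C[N+](C)(C)C"),
    ],
)
def test_carnitine_correction_moves_som_to_carboxyl_carbon(sub, met):
    pair = pair_of(sub, met)
    raw = annotate_general_addition(pair)
    assert raw is not None
    corrected = carnitine_correction(pair, raw)
    assert corrected.rule == CARNITINE_CONJUGATION
    carboxyl_c = first_match(pair.substrate, "[CX3](=O)[OX2H]")[0]
    assert corrected.som_indices == {carboxyl_c}


def test_carnitine_correction_leaves_glucuronide_unchanged():
    pair = pair_of(
        "OC(=O)c1ccccc1", "O=C(OC1OC(C(=O)O)C(O)C(O)C1O)c1ccccc1"
    )
    raw = annotate_general_addition(pair)
    assert carnitine_correction(pair, raw) is raw


def test_glutathione_checked_before_general_addition():
    # the conjugate contains the (saturated) substrate graph too, but the
    # glutathione rule must claim it first
    pair = pair_of("CCC=O", "O=CCCS" + GSH_TAIL)
    annotation = handle_addition(pair, RuleConfig())
    assert annotation.rule == GLUTATHIONE_CONJUGATION


def test_som_indices_generated_on_addition_fixtures(annotated_corpus):
    """On fixtures built by atom addition, SOMs lie on the attachment atoms
    recorded at generation time (up to symmetry)."""
    for fx, pair, annotation, _ in annotated_corpus:
        if fx.family != "addition":
            continue
        assert annotation.som_indices
        assert annotation.som_indices <= set(range(pair.substrate.GetNumAtoms()))
        expected = symmetry_expand(pair.substrate, fx.truth_soms)
        assert annotation.som_indices == expected
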