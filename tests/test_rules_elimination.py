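"""Elimination handler: type-1/type-2 dispatch and the ester corrections."""

import pytest

from autosom.records import (
    ESTER_HYDROLYSIS,
    GENERAL_ELIMINATION,
    INORGANIC_ESTER_HYDROLYSIS,
    RuleConfig,
)
from autosom.rules_elimination import (
    annotate_general_elimination,
    ester_corrections,
    handle_elimination,
)
from util import first_match, pair_of


def test_type1_n_demethylation_som_is_removed_methyl():
    pair = pair_of("CN1CCN(c2ccccc2)CC1", "C1CN(c2ccccc2)CCN1")
    annotation = annotate_general_elimination(pair)
    assert annotation is not None
    methyl = first_match(pair.substrate, "[CH3][NX3]")[0]
    assert annotation.som_indices == {methyl}


def test_type2_reductive_dehalogenation_som_is_ipso_carbon():
    pair = pair_of("Clc1ccccc1", "c1ccccc1")
    annotation = annotate_general_elimination(pair)
    assert annotation is not None
    ipso = first_match(pair.substrate, "c[Cl]")[0]
    assert annotation.som_indices == {ipso}


def test_type2_heteroatom_reduction_som_is_nitrogen():
    # nitro -> nitroso: the lost oxygen marks the retained nitrogen
    pair = pair_of("O=[N+]([O-])c1ccccc1", "O=Nc1ccccc1")
    annotation = annotate_general_elimination(pair)
    assert annotation is not None
    nitrogen = first_match(pair.substrate, "[N]")[0]
    assert annotation.som_indices == {nitrogen}


def test_gating_on_heavy_atom_count():
    pair = pair_of("CC", "CCO")  # metabolite heavier
    assert annotate_general_elimination(pair) is None


def test_ester_hydrolysis_correction_moves_som_to_carbonyl_carbon():
    pair = pair_of("COC(=O)c1ccccc1", "OC(=O)c1ccccc1")
    raw = annotate_general_elimination(pair)
    methyl = first_match(pair.substrate, "[CH3][OX2]")[0]
    assert raw.som_indices == {methyl}
    corrected = ester_corrections(pair, raw, RuleConfig())
    carbonyl = first_match(pair.substrate, "[CX3](=O)[OX2]")[0]
    assert corrected.rule == ESTER_HYDROLYSIS
    assert corrected.som_indices == {carbonyl}


def test_thiophosphate_hydrolysis_som_is_phosphorus():
    pair = pair_of("CCOP(=S)(O)OCC", "CCOP(=S)(O)O")
    annotation = handle_elimination(pair, RuleConfig())
    assert annotation.rule == INORGANIC_ESTER_HYDROLYSIS
    phosphorus = first_match(pair.substrate, "[PX4]")[0]
    assert annotation.som_indices == {phosphorus}


def test_sulfonate_hydrolysis_som_is_sulfur():
    pair = pair_of("Cc1ccc(S(=O)(=O)OC)cc1", "Cc1ccc(S(=O)(=O)O)cc1")
    annotation = handle_elimination(pair, RuleConfig())
    assert annotation.rule == INORGANIC_ESTER_HYDROLYSIS
    sulfur = first_match(pair.substrate, "[SX4](=O)(=O)")[0]
    assert annotation.som_indices == {sulfur}


def test_correction_leaves_dealkylation_unchanged():
    pair = pair_of("COc1ccccc1", "Oc1ccccc1")
    raw = annotate_general_elimination(pair)
    corrected = ester_corrections(pair, raw, RuleConfig())
    assert corrected.rule == GENERAL_ELIMINATION
    assert corrected.som_indices == raw.som_indices


def test_corrections_disabled_by_config():
    config = RuleConfig(enabled_rules=frozenset({GENERAL_ELIMINATION}))
    pair = pair_of("COC(=O)c1ccccc1", "OC(=O)c1ccccc1")
    annotation = handle_elimination(pair, config)
    assert annotation.rule == GENERAL_ELIMINATION
    methyl = first_match(pair.substrate, "[CH3][OX2]")[0]
    assert annotation.som_indices == {methyl}


def test_dealkylation_fixtures_recover_alpha_carbon(annotated_corpus):
    from autosom.graph_map import symmetry_expand

    for fx, pair, annotation, _ in annotated_corpus:
        if fx.template not in ("n_dealkylation", "o_dealkylation"):
            continue
        assert annotation.rule == GENERAL_ELIMINATION
        expected = symmetry_expand(pair.substrate, fx.truth_soms)
        assert annotation.som_indices == expected
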