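"""Addition handler: reactions where the metabolite gains heavy atoms and
strictly contains the substrate graph.

Order of checks mirrors the addition workflow: glutathione conjugation is
detected first (the Michael-type attack saturates a double bond, which
defeats bond-order-sensitive matching), then general addition via an
induced, bond-order- and charge-sensitive embedding of the substrate into
the metabolite, finally a carnitine-ester correction that relocates the SOM
from the ester oxygen to the carboxyl carbon (in carnitine conjugation the
carnitine hydroxyl is the nucleophile, not the substrate oxygen).
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
from rdkit import Chem

from . import graph_map
from .graph_map import NO_DEADLINE, Deadline
from .records import (
    CARNITINE_CONJUGATION,
    GENERAL_ADDITION,
    GLUTATHIONE_CONJUGATION,
    RuleConfig,
    SomAnnotation,
    StandardizedPair,
)

#: Glutathione tripeptide (gamma-Glu-Cys-Gly) used as a substructure query;
#: matches the conjugated moiety since SMILES queries leave hydrogen counts
#: and substitution open.
_GSH_QUERY = Chem.MolFromSmiles("NC(CCC(=O)NC(CS)C(=O)NCC(=O)O)C(=O)O")

#: Carnitine ester: trimethylammonium-CH2-CH(O-acyl)-CH2-carboxylate.
_CARNITINE_ESTER = Chem.MolFromSmarts(
    "[CH3][N+]([CH3])([CH3])[CH2][CH]([CH2][CX3](=O)[OX1-,OX2H])[OX2][CX3]=O"
)
# indices within the SMARTS above
_CARN_ESTER_O = 10
_CARN_ACYL_C = 11


def annotate_glutathione(
    pair: StandardizedPair, deadline: Deadline = NO_DEADLINE
) -> Optional[SomAnnotation]:
    """SOM of a glutathione conjugation: the substrate atom bonded to the
    glutathione cysteine sulfur in the conjugate.

    The tripeptide is located in the metabolite by substructure match; its
    atoms are deleted and the remainder is embedded back into the substrate
    (bond orders relaxed, monomorphism: the substrate may hold a bond the
    conjugation opened, e.g. an epoxide).  The image of the sulfur-bearing
    attachment atom is the SOM.
    """
    met, sub = pair.metabolite, pair.substrate
    matches = met.GetSubstructMatches(_GSH_QUERY, uniquify=True, maxMatches=8)
    if not matches:
        return None
    g_met = graph_map.to_graph(met)
    g_sub = graph_map.to_graph(sub)
    best = None  # (tie-break key, SOM, embedding met->sub)
    for match in matches:
        deadline.check()
        match_set = set(match)
        sulfur = next(
            (i for i in match if met.GetAtomWithIdx(i).GetSymbol() == "S"), None
        )
        if sulfur is None:
            continue
        attach = [n for n in g_met.neighbors(sulfur) if n not in match_set]
        if len(attach) != 1:
            continue
        remainder_nodes = [n for n in g_met.nodes if n not in match_set]
        remainder = g_met.subgraph(remainder_nodes)
        if remainder.number_of_nodes() == 0 or not nx.is_connected(remainder):
            continue
        found, embeddings = graph_map.is_subgraph(
            remainder,
            g_sub,
            bond_order_sensitive=False,
            match_charge=False,
            deadline=deadline,
            monomorphism=True,
        )
        for emb in embeddings:  # emb: metabolite remainder atom -> substrate atom
            if attach[0] not in emb:
                continue
            som = emb[attach[0]]
            key = (som, tuple(sorted(emb.items())))
            if best is None or key < best[0]:
                best = (key, som, emb)
    if best is None:
        return None
    _, som, emb = best
    return SomAnnotation(
        som_indices=frozenset({som}),
        rule=GLUTATHIONE_CONJUGATION,
        mapping={v: k for k, v in emb.items()},
    )


def annotate_general_addition(
    pair: StandardizedPair, deadline: Deadline = NO_DEADLINE
) -> Optional[SomAnnotation]:
    """SOMs of a general addition: substrate atoms whose image in the
    metabolite acquired a neighbor outside the embedded substrate."""
    sub, met = pair.substrate, pair.metabolite
    if met.GetNumAtoms() <= sub.GetNumAtoms():
        return None
    found, embeddings = graph_map.is_subgraph(
        sub, met, bond_order_sensitive=True, match_charge=True, deadline=deadline
    )
    if not found:
        return None
    g_met = graph_map.to_graph(met)

    def soms_of(emb: dict[int, int]) -> set[int]:
        image = set(emb.values())
        return {
            s
            for s, m in emb.items()
            if any(n not in image for n in g_met.neighbors(m))
        }

    picked = graph_map.pick_minimal(embeddings, soms_of)
    if picked is None:
        return None
    emb, soms = picked
    return SomAnnotation(som_indices=soms, rule=GENERAL_ADDITION, mapping=dict(emb))


def carnitine_correction(
    pair: StandardizedPair, annotation: SomAnnotation
) -> SomAnnotation:
    """Relocate the SOM of a carnitine conjugation from the ester sp3 oxygen
    to the carboxyl carbon; other annotations pass through unchanged."""
    if annotation.rule != GENERAL_ADDITION or not annotation.mapping:
        return annotation
    met = pair.metabolite
    matches = met.GetSubstructMatches(_CARNITINE_ESTER, maxMatches=8)
    if not matches:
        return annotation
    mapping = annotation.mapping
    inverse = {v: k for k, v in mapping.items()}
    for match in matches:
        ester_o_met = match[_CARN_ESTER_O]
        acyl_c_met = match[_CARN_ACYL_C]
        for som in sorted(annotation.som_indices):
            if mapping.get(som) == ester_o_met and acyl_c_met in inverse:
                return SomAnnotation(
                    som_indices=frozenset({inverse[acyl_c_met]}),
                    rule=CARNITINE_CONJUGATION,
                    mapping=mapping,
                )
    return annotation


def handle_addition(
    pair: StandardizedPair,
    config: RuleConfig,
    deadline: Deadline = NO_DEADLINE,
) -> Optional[SomAnnotation]:
    """Full addition workflow under the configured rule set."""
    deadline.check()
    if config.enabled(GLUTATHIONE_CONJUGATION):
        annotation = annotate_glutathione(pair, deadline)
        if annotation is not None:
            return annotation
    if config.enabled(GENERAL_ADDITION):
        annotation = annotate_general_addition(pair, deadline)
        if annotation is not None:
            if config.enabled(CARNITINE_CONJUGATION):
                annotation = carnitine_correction(pair, annotation)
            return annotation
    return None
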