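"""Elimination handler: reactions where the substrate loses heavy atoms and
the metabolite graph is contained in the substrate graph.

Two SOM patterns are distinguished at each boundary bond between a mapped
and an unmapped substrate atom:

* type 1 (dealkylation, deacylation): the unmapped boundary atom is carbon
  -> that carbon is the SOM;
* type 2 (reductive dehalogenation, reduction at heteroatoms): the unmapped
  boundary atom is a heteroatom -> the mapped neighbor is the SOM.

Hydrolyses of (thio)esters and of inorganic-acid esters (phosphates,
thiophosphates, sulfamates, sulfonamides, sulfonates) then relocate the raw
SOM onto the carbonyl carbon or onto the phosphorus/sulfur center.
"""

from __future__ import annotations

from typing import Optional

from rdkit import Chem

from . import graph_map
from .graph_map import NO_DEADLINE, Deadline
from .records import (
    ESTER_HYDROLYSIS,
    GENERAL_ELIMINATION,
    INORGANIC_ESTER_HYDROLYSIS,
    RuleConfig,
    SomAnnotation,
    StandardizedPair,
)

_HALOGENS = {"F", "Cl", "Br", "I"}


def _boundary_soms(sub: Chem.Mol, mapped_sub: set[int]) -> set[int]:
    """Apply the type-1/type-2 dispatch over every boundary bond."""
    soms: set[int] = set()
    for atom in sub.GetAtoms():
        idx = atom.GetIdx()
        if idx not in mapped_sub:
            continue
        for nb in atom.GetNeighbors():
            n = nb.GetIdx()
            if n in mapped_sub:
                continue
            if nb.GetSymbol() == "C":
                soms.add(n)  # type 1: the removed carbon
            else:
                soms.add(idx)  # type 2: the retained mapped neighbor
    return soms


def annotate_general_elimination(
    pair: StandardizedPair, deadline: Deadline = NO_DEADLINE
) -> Optional[SomAnnotation]:
    """General elimination via an induced embedding of the metabolite into
    the substrate (elements only: reductions may change charge and bond
    order on the reacting center)."""
    sub, met = pair.substrate, pair.metabolite
    if met.GetNumAtoms() >= sub.GetNumAtoms():
        return None
    found, embeddings = graph_map.is_subgraph(
        met, sub, bond_order_sensitive=False, match_charge=False, deadline=deadline
    )
    if not found:
        return None

    def soms_of(emb: dict[int, int]) -> set[int]:
        return _boundary_soms(sub, set(emb.values()))

    picked = graph_map.pick_minimal(embeddings, soms_of)
    if picked is None:
        return None
    emb, soms = picked  # emb: metabolite atom -> substrate atom
    return SomAnnotation(
        som_indices=soms,
        rule=GENERAL_ELIMINATION,
        mapping={v: k for k, v in emb.items()},
    )


def _is_carbonyl_carbon(mol: Chem.Mol, idx: int) -> bool:
    atom = mol.GetAtomWithIdx(idx)
    if atom.GetSymbol() != "C":
        return False
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetSymbol() in ("O", "S") and bond.GetBondTypeAsDouble() == 2.0:
            return True
    return False


def _acid_center(mol: Chem.Mol, linker_idx: int, exclude: int) -> tuple[Optional[int], Optional[str]]:
    """Classify the acid side of an ester linkage.

    ``linker_idx`` is the single-bonded O/S/N bridging atom; ``exclude`` the
    alkyl atom being removed.  Returns (center atom index, rule label) for a
    carboxylic (thio)ester or an inorganic P/S acid ester, else (None, None).
    """
    linker = mol.GetAtomWithIdx(linker_idx)
    for nb in linker.GetNeighbors():
        c = nb.GetIdx()
        if c == exclude:
            continue
        symbol = nb.GetSymbol()
        if symbol == "C" and _is_carbonyl_carbon(mol, c):
            return c, ESTER_HYDROLYSIS
        if symbol == "P":
            return c, INORGANIC_ESTER_HYDROLYSIS
        if symbol == "S":
            has_oxo = any(
                b.GetOtherAtom(nb).GetSymbol() == "O"
                and b.GetBondTypeAsDouble() == 2.0
                for b in nb.GetBonds()
            )
            if has_oxo:
                return c, INORGANIC_ESTER_HYDROLYSIS
    return None, None


def ester_corrections(
    pair: StandardizedPair, annotation: SomAnnotation, config: RuleConfig
) -> SomAnnotation:
    """Relocate type-1 SOMs that sit on the alkyl side of an ester linkage.

    A raw SOM that is an alkyl carbon attached through a single-bonded O/S/N
    to a carbonyl carbon becomes the carbonyl carbon ((thio)ester
    hydrolysis); attached to a P or oxo-S center it becomes that center
    (inorganic acid ester hydrolysis).  SOMs never move outside the
    functional group containing the raw SOM.
    """
    if annotation.rule != GENERAL_ELIMINATION or not annotation.mapping:
        return annotation
    sub = pair.substrate
    mapped = set(annotation.mapping)
    new_soms: set[int] = set()
    label = None
    for som in sorted(annotation.som_indices):
        replaced = False
        atom = sub.GetAtomWithIdx(som)
        is_alkyl_c = (
            som not in mapped
            and atom.GetSymbol() == "C"
            and not _is_carbonyl_carbon(sub, som)
        )
        if is_alkyl_c:
            for bond in atom.GetBonds():
                linker = bond.GetOtherAtom(atom)
                if (
                    linker.GetIdx() in mapped
                    and linker.GetSymbol() in ("O", "S", "N")
                    and bond.GetBondTypeAsDouble() == 1.0
                ):
                    center, rule = _acid_center(sub, linker.GetIdx(), som)
                    if center is not None and config.enabled(rule):
                        new_soms.add(center)
                        label = rule if label is None else label
                        replaced = True
                        break
        if not replaced:
            new_soms.add(som)
    if label is None:
        return annotation
    return SomAnnotation(
        som_indices=frozenset(new_soms), rule=label, mapping=annotation.mapping
    )


def handle_elimination(
    pair: StandardizedPair,
    config: RuleConfig,
    deadline: Deadline = NO_DEADLINE,
) -> Optional[SomAnnotation]:
    """Full elimination workflow under the configured rule set."""
    deadline.check()
    if not config.enabled(GENERAL_ELIMINATION):
        return None
    annotation = annotate_general_elimination(pair, deadline)
    if annotation is None:
        return None
    return ester_corrections(pair, annotation, config)
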