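"""Complex handler: transformations that are neither pure additions nor pure
eliminations (redox reactions, ring openings, halogen/oxygen exchanges).

Checks run in a fixed order: oxidative dehalogenation first (same carbon
count, halogen lost, oxygen gained), then a complete subgraph-isomorphism
mapping (SOMs where hydrogen count or formal charge changed), then an MCS
mapping with relaxed bond orders (SOMs wherever the topology changed).
Ring-hydrolysis corrections (oxacyclopropane, lactone, other heterocycles)
reshape the MCS-based SOM set afterwards.
"""

from __future__ import annotations

from typing import Optional

from rdkit import Chem

from . import graph_map
from .graph_map import NO_DEADLINE, AtomMapping, Deadline
from .records import (
    HETEROCYCLE_HYDROLYSIS,
    ISOMORPHISM_MAPPING,
    LACTONE_HYDROLYSIS,
    MCS_MAPPING,
    OXACYCLOPROPANE_HYDROLYSIS,
    OXIDATIVE_DEHALOGENATION,
    RuleConfig,
    SomAnnotation,
    StandardizedPair,
)

_HALOGENS = {"F", "Cl", "Br", "I"}
_EPOXIDE = Chem.MolFromSmarts("[#6]1[#8][#6]1")
_RING_ESTER = Chem.MolFromSmarts("[C;R](=O)[O;R]")


def _count(mol: Chem.Mol, symbols: set[str]) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetSymbol() in symbols)


def annotate_oxidative_dehalogenation(
    pair: StandardizedPair, deadline: Deadline = NO_DEADLINE
) -> Optional[SomAnnotation]:
    """Oxidative dehalogenation: carbon count retained, a halogen lost, an
    oxygen gained.  The general variant puts the SOM on the formerly
    halogenated carbon; if a new epoxide ring appears in the metabolite,
    both ring carbons are the SOMs."""
    sub, met = pair.substrate, pair.metabolite
    if _count(sub, {"C"}) != _count(met, {"C"}):
        return None
    if _count(sub, _HALOGENS) <= _count(met, _HALOGENS):
        return None
    if _count(sub, {"O"}) >= _count(met, {"O"}):
        return None
    candidates = graph_map.mcs_mappings(sub, met, bond_order_sensitive=False,
                                        deadline=deadline)
    if not candidates:
        return None

    epoxide_new = bool(met.GetSubstructMatches(_EPOXIDE)) and not bool(
        sub.GetSubstructMatches(_EPOXIDE)
    )

    def soms_of(mapping: AtomMapping) -> set[int]:
        pairs = mapping.pairs
        if epoxide_new:
            inverse = mapping.inverse()
            soms = set()
            for match in met.GetSubstructMatches(_EPOXIDE):
                ring_carbons = [
                    i for i in match if met.GetAtomWithIdx(i).GetSymbol() == "C"
                ]
                if all(c in inverse for c in ring_carbons):
                    soms.update(inverse[c] for c in ring_carbons)
            return soms
        soms = set()
        for atom in sub.GetAtoms():
            if atom.GetSymbol() not in _HALOGENS or atom.GetIdx() in pairs:
                continue
            for nb in atom.GetNeighbors():
                if nb.GetSymbol() == "C" and nb.GetIdx() in pairs:
                    soms.add(nb.GetIdx())
        return soms

    picked = graph_map.pick_minimal(candidates, soms_of)
    if picked is None:
        return None
    mapping, soms = picked
    return SomAnnotation(
        som_indices=soms, rule=OXIDATIVE_DEHALOGENATION, mapping=dict(mapping.pairs)
    )


def annotate_by_full_isomorphism(
    pair: StandardizedPair, deadline: Deadline = NO_DEADLINE
) -> Optional[SomAnnotation]:
    """Complete atom mapping (elements + connectivity, bond orders ignored);
    SOMs are the atoms whose hydrogen count or formal charge changed."""
    sub, met = pair.substrate, pair.metabolite
    mappings = graph_map.full_isomorphisms(sub, met, deadline)
    if not mappings:
        return None

    def soms_of(mapping: dict[int, int]) -> set[int]:
        soms = set()
        for s, m in mapping.items():
            sa, ma = sub.GetAtomWithIdx(s), met.GetAtomWithIdx(m)
            if (
                sa.GetTotalNumHs() != ma.GetTotalNumHs()
                or sa.GetFormalCharge() != ma.GetFormalCharge()
            ):
                soms.add(s)
        return soms

    picked = graph_map.pick_minimal(mappings, soms_of)
    if picked is None:
        return None
    mapping, soms = picked
    return SomAnnotation(som_indices=soms, rule=ISOMORPHISM_MAPPING, mapping=dict(mapping))


def annotate_by_mcs_diff(
    pair: StandardizedPair, deadline: Deadline = NO_DEADLINE
) -> Optional[SomAnnotation]:
    """MCS mapping with relaxed bond orders; every substrate atom that
    underwent a topological change is a SOM: mapped atoms whose neighbor set
    or incident bond orders changed, plus unmapped substrate atoms adjacent
    to mapped ones."""
    sub, met = pair.substrate, pair.metabolite
    candidates = graph_map.mcs_mappings(sub, met, bond_order_sensitive=False,
                                        deadline=deadline)
    if not candidates:
        return None
    g_sub = graph_map.to_graph(sub)
    g_met = graph_map.to_graph(met)

    def soms_of(mapping: AtomMapping) -> set[int]:
        pairs = mapping.pairs
        mapped_sub = set(pairs)
        mapped_met = set(pairs.values())
        soms: set[int] = set()
        for s, m in pairs.items():
            sub_nbs = set(g_sub.neighbors(s))
            met_nbs = set(g_met.neighbors(m))
            if any(n not in mapped_sub for n in sub_nbs):
                soms.add(s)  # loses a neighbor outside the MCS
                continue
            if any(n not in mapped_met for n in met_nbs):
                soms.add(s)  # gains a neighbor outside the MCS
                continue
            if {pairs[n] for n in sub_nbs} != met_nbs:
                soms.add(s)  # rewired within the MCS
                continue
            for n in sub_nbs:
                if g_sub.edges[s, n]["order"] != g_met.edges[m, pairs[n]]["order"]:
                    soms.add(s)  # incident bond order changed
                    break
        for s in g_sub.nodes:
            if s not in mapped_sub and any(n in mapped_sub for n in g_sub.neighbors(s)):
                soms.add(s)
        return soms

    picked = graph_map.pick_minimal(candidates, soms_of)
    if picked is None:
        return None
    mapping, soms = picked
    return SomAnnotation(som_indices=soms, rule=MCS_MAPPING, mapping=dict(mapping.pairs))


def _broken_ring_bonds(
    sub: Chem.Mol, met: Chem.Mol, mapping: dict[int, int]
) -> list[tuple[int, int]]:
    """Substrate ring bonds whose image is absent from the metabolite."""
    broken = []
    for bond in sub.GetBonds():
        if not bond.IsInRing():
            continue
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if u in mapping and v in mapping:
            if met.GetBondBetweenAtoms(mapping[u], mapping[v]) is None:
                broken.append((u, v))
        elif (u in mapping) != (v in mapping):
            broken.append((u, v))
    return broken


def ring_hydrolysis_corrections(
    pair: StandardizedPair, annotation: SomAnnotation, config: RuleConfig
) -> SomAnnotation:
    """Reshape MCS-based SOMs for hydrolytic ring openings.

    Oxacyclopropane hydrolysis -> both former ring carbons; lactone
    hydrolysis -> the carbonyl carbon; other heterocyclic C-heteroatom ring
    cleavages -> the carbon side of the cleaved bond.  Applies only when the
    raw SOM set touches the ring in question and the metabolite gained
    oxygen (hydrolytic water addition).
    """
    if annotation.rule != MCS_MAPPING or not annotation.mapping:
        return annotation
    sub, met = pair.substrate, pair.metabolite
    if _count(met, {"O"}) <= _count(sub, {"O"}):
        return annotation
    mapping = annotation.mapping
    broken = _broken_ring_bonds(sub, met, mapping)
    if not broken:
        return annotation
    raw = set(annotation.som_indices)

    # oxacyclopropane: a 3-membered O-ring of the substrate opened
    if config.enabled(OXACYCLOPROPANE_HYDROLYSIS):
        for match in sub.GetSubstructMatches(_EPOXIDE):
            ring_carbons = {i for i in match if sub.GetAtomWithIdx(i).GetSymbol() == "C"}
            opened = any(set(b) <= set(match) for b in broken)
            if opened and raw & set(match):
                return SomAnnotation(
                    som_indices=frozenset(ring_carbons),
                    rule=OXACYCLOPROPANE_HYDROLYSIS,
                    mapping=mapping,
                )

    # lactone: a cyclic ester ring opened anywhere along the ring (the MCS is
    # free to break either C-O bond of the ester; both mean hydrolysis)
    if config.enabled(LACTONE_HYDROLYSIS):
        rings = sub.GetRingInfo().AtomRings()
        for match in sub.GetSubstructMatches(_RING_ESTER):
            carbonyl_c, _, ring_o = match
            ester_rings = [
                set(r) for r in rings if carbonyl_c in r and ring_o in r
            ]
            opened = any(
                set(b) <= ring for b in broken for ring in ester_rings
            )
            if opened and raw & (set().union(*ester_rings) if ester_rings else set()):
                return SomAnnotation(
                    som_indices=frozenset({carbonyl_c}),
                    rule=LACTONE_HYDROLYSIS,
                    mapping=mapping,
                )

    # other heterocycles: a ring C-heteroatom bond cleaved.  As with
    # oxacyclopropanes, the hydrolysis product cannot reveal which of the
    # heteroatom's two ring C-X bonds broke (either opening yields the same
    # open-chain diol/amino-alcohol), so every ring carbon flanking the
    # cleaved heteroatom is a SOM.
    if config.enabled(HETEROCYCLE_HYDROLYSIS):
        carbons = set()
        for u, v in broken:
            su, sv = sub.GetAtomWithIdx(u).GetSymbol(), sub.GetAtomWithIdx(v).GetSymbol()
            if su in ("O", "N", "S") and sv == "C":
                u, v, su, sv = v, u, sv, su
            if su == "C" and sv in ("O", "N", "S") and {u, v} & raw:
                hetero = sub.GetAtomWithIdx(v)
                for nb in hetero.GetNeighbors():
                    bond = sub.GetBondBetweenAtoms(v, nb.GetIdx())
                    if nb.GetSymbol() == "C" and bond.IsInRing():
                        carbons.add(nb.GetIdx())
                carbons.add(u)
        if carbons:
            return SomAnnotation(
                som_indices=frozenset(carbons),
                rule=HETEROCYCLE_HYDROLYSIS,
                mapping=mapping,
            )

    return annotation


def handle_complex(
    pair: StandardizedPair,
    config: RuleConfig,
    deadline: Deadline = NO_DEADLINE,
) -> Optional[SomAnnotation]:
    """Full complex workflow under the configured rule set."""
    deadline.check()
    if config.enabled(OXIDATIVE_DEHALOGENATION):
        annotation = annotate_oxidative_dehalogenation(pair, deadline)
        if annotation is not None:
            return annotation
    if config.enabled(ISOMORPHISM_MAPPING):
        annotation = annotate_by_full_isomorphism(pair, deadline)
        if annotation is not None:
            return annotation
    if config.enabled(MCS_MAPPING):
        annotation = annotate_by_mcs_diff(pair, deadline)
        if annotation is not None:
            return ring_hydrolysis_corrections(pair, annotation, config)
    return None
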