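"""Graph-matching primitives shared by all annotation handlers.

Molecules are treated as colored heavy-atom graphs: nodes carry element,
formal charge, total hydrogen count and aromaticity; edges carry the bond
order (aromatic bonds count as 1.5 so a kekulized and an aromatic drawing of
the same ring compare equal).  On top of that representation this module
provides

* induced-subgraph isomorphism tests with deterministic embedding
  enumeration (:func:`is_subgraph`),
* maximum-common-substructure atom-to-atom mappings via RDKit's FMCS with a
  deterministic tie-break (:func:`mcs_mappings` / :func:`pick_mapping`),
* topological-symmetry orbits and orbit expansion of SOM sets
  (:func:`symmetry_orbits` / :func:`symmetry_expand`).

All matching is on heavy atoms; hydrogens are implicit node attributes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import networkx as nx
from networkx.algorithms import isomorphism as nx_iso
from rdkit import Chem
from rdkit.Chem import rdFMCS

#: Cap on enumerated embeddings/matches per query; symmetric drug-sized
#: molecules stay far below this.
MAX_EMBEDDINGS = 64


class AnnotationTimeout(Exception):
    """Raised when an annotation attempt exceeds its deadline."""


class Deadline:
    """Cooperative deadline passed through the matching loops."""

    def __init__(self, seconds: Optional[float]):
        self.expires_at = None if seconds is None else time.monotonic() + seconds

    def check(self) -> None:
        if self.expires_at is not None and time.monotonic() > self.expires_at:
            raise AnnotationTimeout

    def remaining(self, minimum: float = 1.0) -> float:
        if self.expires_at is None:
            return 3600.0
        return max(minimum, self.expires_at - time.monotonic())


NO_DEADLINE = Deadline(None)


def to_graph(mol: Chem.Mol) -> nx.Graph:
    """Colored heavy-atom graph of an RDKit molecule."""
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            element=atom.GetSymbol(),
            charge=atom.GetFormalCharge(),
            hydrogens=atom.GetTotalNumHs(),
            aromatic=atom.GetIsAromatic(),
        )
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=bond.GetBondTypeAsDouble(),
        )
    return g


def _node_match(match_charge: bool) -> Callable:
    if match_charge:
        return lambda a, b: a["element"] == b["element"] and a["charge"] == b["charge"]
    return lambda a, b: a["element"] == b["element"]


def _edge_match(bond_order_sensitive: bool) -> Optional[Callable]:
    if bond_order_sensitive:
        return lambda a, b: a["order"] == b["order"]
    return None


@dataclass
class AtomMapping:
    """Partial injective substrate-atom -> metabolite-atom map."""

    pairs: dict[int, int]
    bond_order_sensitive: bool = False
    complete: bool = False

    def inverse(self) -> dict[int, int]:
        return {v: k for k, v in self.pairs.items()}

    def __len__(self) -> int:
        return len(self.pairs)


def _sorted_embeddings(raw: Iterable[dict[int, int]]) -> list[dict[int, int]]:
    return sorted(raw, key=lambda m: tuple(sorted(m.items())))


def is_subgraph(
    small: Chem.Mol | nx.Graph,
    large: Chem.Mol | nx.Graph,
    bond_order_sensitive: bool = True,
    match_charge: bool = True,
    deadline: Deadline = NO_DEADLINE,
    monomorphism: bool = False,
) -> tuple[bool, list[dict[int, int]]]:
    """Test whether ``small`` embeds in ``large`` as an induced subgraph.

    Returns ``(found, embeddings)`` where each embedding maps small-atom
    indices to large-atom indices; embeddings are enumerated
    deterministically and capped at :data:`MAX_EMBEDDINGS`.  With
    ``monomorphism=True`` extra bonds of ``large`` among matched atoms are
    tolerated (used for the glutathione remainder step).
    """
    g_small = small if isinstance(small, nx.Graph) else to_graph(small)
    g_large = large if isinstance(large, nx.Graph) else to_graph(large)
    if g_small.number_of_nodes() > g_large.number_of_nodes():
        return False, []
    matcher = nx_iso.GraphMatcher(
        g_large,
        g_small,
        node_match=_node_match(match_charge),
        edge_match=_edge_match(bond_order_sensitive),
    )
    it = (
        matcher.subgraph_monomorphisms_iter()
        if monomorphism
        else matcher.subgraph_isomorphisms_iter()
    )
    embeddings: list[dict[int, int]] = []
    seen = set()
    for large_to_small in it:
        deadline.check()
        emb = {s: l for l, s in large_to_small.items()}
        key = tuple(sorted(emb.items()))
        if key not in seen:
            seen.add(key)
            embeddings.append(emb)
        if len(embeddings) >= MAX_EMBEDDINGS:
            break
    return bool(embeddings), _sorted_embeddings(embeddings)


def full_isomorphisms(
    sub: Chem.Mol,
    met: Chem.Mol,
    deadline: Deadline = NO_DEADLINE,
) -> list[dict[int, int]]:
    """Complete atom mappings (element + connectivity, bond orders ignored)."""
    g_sub, g_met = to_graph(sub), to_graph(met)
    if g_sub.number_of_nodes() != g_met.number_of_nodes():
        return []
    matcher = nx_iso.GraphMatcher(g_sub, g_met, node_match=_node_match(False))
    mappings = []
    for m in matcher.isomorphisms_iter():
        deadline.check()
        mappings.append(dict(m))
        if len(mappings) >= MAX_EMBEDDINGS:
            break
    return _sorted_embeddings(mappings)


def mcs_mappings(
    sub: Chem.Mol,
    met: Chem.Mol,
    bond_order_sensitive: bool = False,
    deadline: Deadline = NO_DEADLINE,
) -> list[AtomMapping]:
    """Candidate atom-to-atom mappings restricted to the MCS.

    The MCS is found with RDKit's FMCS (elements compared, bond order per
    flag, single connected fragment) and mapped back onto both molecules;
    every combination of substrate/metabolite placements of the MCS query
    yields one candidate mapping.
    """
    deadline.check()
    params = rdFMCS.MCSParameters()
    params.MaximizeBonds = False  # maximize mapped atoms
    params.AtomTyper = rdFMCS.AtomCompare.CompareElements
    params.BondTyper = (
        rdFMCS.BondCompare.CompareOrderExact
        if bond_order_sensitive
        else rdFMCS.BondCompare.CompareAny
    )
    params.Timeout = max(1, int(deadline.remaining()))
    result = rdFMCS.FindMCS([sub, met], params)
    if result.numAtoms == 0 or result.queryMol is None:
        return []
    query = result.queryMol
    sub_matches = sub.GetSubstructMatches(query, uniquify=False, maxMatches=MAX_EMBEDDINGS)
    met_matches = met.GetSubstructMatches(query, uniquify=False, maxMatches=MAX_EMBEDDINGS)
    mappings: list[AtomMapping] = []
    seen = set()
    complete = result.numAtoms == sub.GetNumAtoms() == met.GetNumAtoms()
    for sm in sub_matches:
        for mm in met_matches:
            deadline.check()
            pairs = dict(zip(sm, mm))
            key = tuple(sorted(pairs.items()))
            if key in seen:
                continue
            seen.add(key)
            mappings.append(
                AtomMapping(pairs=pairs, bond_order_sensitive=bond_order_sensitive,
                            complete=complete)
            )
            if len(mappings) >= MAX_EMBEDDINGS:
                return sorted(mappings, key=lambda m: tuple(sorted(m.pairs.items())))
    return sorted(mappings, key=lambda m: tuple(sorted(m.pairs.items())))


def mcs_mapping(
    sub: Chem.Mol,
    met: Chem.Mol,
    bond_order_sensitive: bool = False,
    deadline: Deadline = NO_DEADLINE,
) -> Optional[AtomMapping]:
    """Single deterministic MCS mapping (lexicographically first candidate)."""
    candidates = mcs_mappings(sub, met, bond_order_sensitive, deadline)
    return candidates[0] if candidates else None


def pick_minimal(
    candidates: list,
    som_fn: Callable,
) -> Optional[tuple[object, frozenset[int]]]:
    """Deterministic tie-break shared by all handlers.

    Among candidate embeddings/mappings, prefer the one producing the fewest
    SOMs; remaining ties go to the lexicographically smallest sorted SOM
    index set, then to the smallest mapping itself.  Candidates yielding no
    SOMs are skipped.  Returns ``(candidate, soms)`` or ``None``.
    """
    best = None
    for cand in candidates:
        soms = frozenset(som_fn(cand))
        if not soms:
            continue
        pairs = cand.pairs if isinstance(cand, AtomMapping) else cand
        key = (len(soms), tuple(sorted(soms)), tuple(sorted(pairs.items())))
        if best is None or key < best[0]:
            best = (key, cand, soms)
    if best is None:
        return None
    return best[1], best[2]


def symmetry_orbits(mol: Chem.Mol) -> list[frozenset[int]]:
    """Orbits of the molecular graph's automorphism group.

    Computed from RDKit's canonical ranking with tie-breaking disabled,
    which assigns identical ranks exactly to topologically equivalent atoms
    (element, charge, hydrogen count and bond orders all respected).
    """
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    by_rank: dict[int, set[int]] = {}
    for idx, rank in enumerate(ranks):
        by_rank.setdefault(rank, set()).add(idx)
    return [frozenset(v) for _, v in sorted(by_rank.items())]


def symmetry_expand(mol: Chem.Mol, soms: Iterable[int]) -> frozenset[int]:
    """Union of the symmetry orbits intersecting ``soms``.

    Idempotent and monotone; annotating one ortho position of a symmetric
    aromatic therefore annotates both.
    """
    som_set = set(soms)
    if not som_set:
        return frozenset()
    expanded: set[int] = set()
    for orbit in symmetry_orbits(mol):
        if orbit & som_set:
            expanded |= orbit
    return frozenset(expanded)
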