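"""Independent brute-force oracles, deliberately separate from the package's
matching code paths: exhaustive embedding enumeration, a McGregor-style
maximum-common-connected-subgraph search, and automorphism-orbit
computation by explicit isomorphism enumeration."""

from __future__ import annotations

from itertools import permutations

import networkx as nx
from rdkit import Chem


def mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            element=atom.GetSymbol(),
            charge=atom.GetFormalCharge(),
        )
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=bond.GetBondTypeAsDouble(),
        )
    return g


def exhaustive_subgraph_exists(
    small: Chem.Mol, large: Chem.Mol, bond_order_sensitive: bool = True
) -> bool:
    """Induced-subgraph test by brute force over all injections (tiny inputs
    only: enumerates permutations of the large molecule's atoms)."""
    gs, gl = mol_graph(small), mol_graph(large)
    ns, nl = gs.number_of_nodes(), gl.number_of_nodes()
    if ns > nl:
        return False
    small_nodes = list(gs.nodes)
    for image in permutations(gl.nodes, ns):
        mapping = dict(zip(small_nodes, image))
        ok = True
        for u in small_nodes:
            if gs.nodes[u]["element"] != gl.nodes[mapping[u]]["element"] or \
               gs.nodes[u]["charge"] != gl.nodes[mapping[u]]["charge"]:
                ok = False
                break
        if not ok:
            continue
        for u, v in ((a, b) for a in small_nodes for b in small_nodes if a < b):
            has_s = gs.has_edge(u, v)
            has_l = gl.has_edge(mapping[u], mapping[v])
            if has_s != has_l:
                ok = False
                break
            if has_s and bond_order_sensitive and \
               gs.edges[u, v]["order"] != gl.edges[mapping[u], mapping[v]]["order"]:
                ok = False
                break
        if ok:
            return True
    return False


def max_common_subgraph_atoms(
    a: Chem.Mol, b: Chem.Mol, bond_order_sensitive: bool = False
) -> int:
    """Atom count of the largest connected common subgraph (elements match;
    bond orders per flag), found by McGregor-style backtracking.  Connectivity
    is over the common edges."""
    ga, gb = mol_graph(a), mol_graph(b)
    best = 0

    def compatible(u: int, v: int) -> bool:
        return ga.nodes[u]["element"] == gb.nodes[v]["element"]

    def common_edge(u, x, v, y) -> bool:
        if not (ga.has_edge(u, x) and gb.has_edge(v, y)):
            return False
        if bond_order_sensitive and ga.edges[u, x]["order"] != gb.edges[v, y]["order"]:
            return False
        return True

    def extend(mapping: dict[int, int], used_b: set[int]) -> None:
        nonlocal best
        best = max(best, len(mapping))
        if len(mapping) + min(
            ga.number_of_nodes() - len(mapping), gb.number_of_nodes() - len(used_b)
        ) <= best:
            return
        candidates = []
        for u in ga.nodes:
            if u in mapping:
                continue
            for v in gb.nodes:
                if v in used_b or not compatible(u, v):
                    continue
                links = [x for x in mapping if common_edge(u, x, v, mapping[x])]
                if mapping and not links:
                    continue
                candidates.append((u, v))
        if not candidates:
            return
        # branch on the smallest substrate atom first for determinism
        seen_pairs = set()
        for u, v in sorted(candidates):
            if (u, v) in seen_pairs:
                continue
            seen_pairs.add((u, v))
            mapping[u] = v
            extend(mapping, used_b | {v})
            del mapping[u]

    extend({}, set())
    return best


def automorphism_orbits(mol: Chem.Mol) -> set[frozenset[int]]:
    """Orbits of the colored-graph automorphism group, by enumerating every
    isomorphism of the molecular graph with itself."""
    g = mol_graph(mol)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g,
        g,
        node_match=lambda x, y: x["element"] == y["element"]
        and x["charge"] == y["charge"],
        edge_match=lambda x, y: x["order"] == y["order"],
    )
    parent = {n: n for n in g.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for mapping in matcher.isomorphisms_iter():
        for u, v in mapping.items():
            union(u, v)
    orbits: dict[int, set[int]] = {}
    for n in g.nodes:
        orbits.setdefault(find(n), set()).add(n)
    return {frozenset(v) for v in orbits.values()}
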