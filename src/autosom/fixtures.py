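"""Synthetic substrate-metabolite pairs with generated ground truth.

Each fixture is produced by forward-applying a biotransformation template
(hydroxylation, conjugation, dealkylation, hydrolysis, ...) to a drug-like
scaffold.  The template records its anchor atoms while editing the
molecular graph, so the true SOM set is generated, never hand-annotated,
and always refers to 0-based atom indices on the standardized substrate.

The template inventory spans the full rule vocabulary: additions
(hydroxylations, glucuronidation, sulfation, glutathione and carnitine
conjugation), eliminations (N-/O-dealkylation, (thio)ester and
inorganic-acid-ester hydrolysis, reductive dehalogenation) and complex
transformations (oxidative dehalogenation, dehydrogenation, epoxidation,
lactone/epoxide/ether ring hydrolysis).
"""

from __future__ import annotations

import logging
import random
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import pandas as pd
from rdkit import Chem

from . import chem_prep
from .records import (
    CARNITINE_CONJUGATION,
    ESTER_HYDROLYSIS,
    GENERAL_ADDITION,
    GENERAL_ELIMINATION,
    GLUTATHIONE_CONJUGATION,
    HETEROCYCLE_HYDROLYSIS,
    INORGANIC_ESTER_HYDROLYSIS,
    ISOMORPHISM_MAPPING,
    LACTONE_HYDROLYSIS,
    MCS_MAPPING,
    OXACYCLOPROPANE_HYDROLYSIS,
    OXIDATIVE_DEHALOGENATION,
    Fixture,
    ReactionRecord,
)

logger = logging.getLogger("autosom")

#: Drug-like scaffold panel; includes symmetric molecules (para-substituted
#: aromatics, cyclohexane) to exercise symmetry-orbit expansion.
SCAFFOLDS: tuple[str, ...] = (
    "Cc1ccccc1",                       # toluene
    "Cc1ccc(C)cc1",                    # p-xylene
    "Nc1ccccc1",                       # aniline
    "Oc1ccccc1",                       # phenol
    "OC(=O)c1ccccc1",                  # benzoic acid
    "CCCCCC(=O)O",                     # hexanoic acid
    "CCOC(=O)c1ccccc1",                # ethyl benzoate
    "CSC(=O)c1ccccc1",                 # S-methyl thiobenzoate
    "CCOP(=O)(OCC)OCC",                # triethyl phosphate
    "CCOP(=S)(OCC)OCC",                # triethyl thiophosphate
    "Cc1ccc(S(=O)(=O)OC)cc1",          # methyl tosylate
    "CN1CCN(c2ccccc2)CC1",             # 1-methyl-4-phenylpiperazine
    "COc1ccccc1",                      # anisole
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",    # naproxen
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",      # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",              # paracetamol
    "CCN(CC)CC(=O)Nc1c(C)cccc1C",      # lidocaine
    "Clc1ccccc1",                      # chlorobenzene
    "Clc1ccc(C)cc1",                   # 4-chlorotoluene
    "CCBr",                            # bromoethane
    "ClC=Cc1ccccc1",                   # beta-chlorostyrene
    "C=Cc1ccccc1",                     # styrene
    "C=CC(=O)c1ccccc1",                # phenyl vinyl ketone
    "C=CC(=O)OC",                      # methyl acrylate
    "CCc1ccccc1",                      # ethylbenzene
    "C1CCCCC1",                        # cyclohexane
    "O=C1CCCO1",                       # gamma-butyrolactone
    "CC1CCC(=O)O1",                    # gamma-valerolactone
    "c1ccccc1C1CO1",                   # styrene oxide
    "c1ccccc1C1CCCO1",                 # 2-phenyltetrahydrofuran
)

_GLUCURONYL = "C1OC(C(=O)O)C(O)C(O)C1O"       # attach at atom 0 (anomeric C)
_SULFO = "S(=O)(=O)O"                          # attach at atom 0 (S)
_GSH = "NC(CCC(=O)NC(CS)C(=O)NCC(=O)O)C(=O)O"  # attach at the cysteine S
_CARNITINYL = "C[N+](C)(C)CC(CC(=O)[O-])"      # attach at atom 5 (the CH)


# --- graph-edit helpers -----------------------------------------------------

def _finish(editable: Chem.RWMol) -> Optional[Chem.Mol]:
    mol = editable.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _add_hydroxyl(mol: Chem.Mol, atom: int) -> Optional[Chem.Mol]:
    ed = Chem.RWMol(mol)
    o = ed.AddAtom(Chem.Atom(8))
    ed.AddBond(atom, o, Chem.BondType.SINGLE)
    return _finish(ed)


def _attach_fragment(
    mol: Chem.Mol, site: int, fragment_smiles: str, attach_idx: int
) -> Optional[Chem.Mol]:
    frag = Chem.MolFromSmiles(fragment_smiles)
    ed = Chem.RWMol(Chem.CombineMols(mol, frag))
    ed.AddBond(site, mol.GetNumAtoms() + attach_idx, Chem.BondType.SINGLE)
    return _finish(ed)


def _component_after_cut(ed: Chem.RWMol, start: int) -> set[int]:
    """Atoms reachable from ``start`` in the edited graph (BFS)."""
    adjacency: dict[int, list[int]] = {}
    for bond in ed.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency.setdefault(u, []).append(v)
        adjacency.setdefault(v, []).append(u)
    seen = {start}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for nb in adjacency.get(node, ()):
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    return seen


def _remove_side(mol: Chem.Mol, keep: int, cut: int) -> Optional[Chem.Mol]:
    """Cut the keep-cut bond and delete the component containing ``cut``."""
    ed = Chem.RWMol(mol)
    if ed.GetBondBetweenAtoms(keep, cut) is None:
        return None
    ed.RemoveBond(keep, cut)
    component = _component_after_cut(ed, cut)
    if keep in component:
        return None  # the bond was in a ring
    for idx in sorted(component, reverse=True):
        ed.RemoveAtom(idx)
    return _finish(ed)


def _open_ring(mol: Chem.Mol, carbon: int, hetero: int) -> Optional[Chem.Mol]:
    """Break a ring C-heteroatom bond and hydroxylate the carbon side."""
    ed = Chem.RWMol(mol)
    if ed.GetBondBetweenAtoms(carbon, hetero) is None:
        return None
    ed.RemoveBond(carbon, hetero)
    o = ed.AddAtom(Chem.Atom(8))
    ed.AddBond(carbon, o, Chem.BondType.SINGLE)
    return _finish(ed)


# --- template definitions ---------------------------------------------------

BuildResult = Optional[tuple[Chem.Mol, set[int]]]


@dataclass(frozen=True)
class Template:
    """A forward biotransformation with anchor-atom bookkeeping."""

    name: str
    label: str  # rule label the pipeline is expected to apply
    pattern: str
    builder: Callable[[Chem.Mol, tuple[int, ...]], BuildResult]
    site_filter: Optional[Callable[[Chem.Mol, tuple[int, ...]], bool]] = None

    def sites(self, mol: Chem.Mol) -> list[tuple[int, ...]]:
        query = Chem.MolFromSmarts(self.pattern)
        matches = mol.GetSubstructMatches(query, uniquify=True, maxMatches=64)
        if self.site_filter is None:
            return list(matches)
        return [m for m in matches if self.site_filter(mol, m)]


def _non_ring_bond(mol: Chem.Mol, u: int, v: int) -> bool:
    bond = mol.GetBondBetweenAtoms(u, v)
    return bond is not None and not bond.IsInRing()


def _ring_bond_min_size(mol: Chem.Mol, u: int, v: int) -> int:
    bond = mol.GetBondBetweenAtoms(u, v)
    if bond is None or not bond.IsInRing():
        return 0
    return mol.GetRingInfo().MinBondRingSize(bond.GetIdx())


def _b_aromatic_hydroxylation(mol, site) -> BuildResult:
    met = _add_hydroxyl(mol, site[0])
    return None if met is None else (met, {site[0]})


def _b_aliphatic_hydroxylation(mol, site) -> BuildResult:
    met = _add_hydroxyl(mol, site[0])
    return None if met is None else (met, {site[0]})


def _b_glucuronidation(mol, site) -> BuildResult:
    met = _attach_fragment(mol, site[0], _GLUCURONYL, 0)
    return None if met is None else (met, {site[0]})


def _b_sulfation(mol, site) -> BuildResult:
    met = _attach_fragment(mol, site[0], _SULFO, 0)
    return None if met is None else (met, {site[0]})


def _b_glutathione(mol, site) -> BuildResult:
    beta, alpha = site[0], site[1]
    frag = Chem.MolFromSmiles(_GSH)
    sulfur = next(a.GetIdx() for a in frag.GetAtoms() if a.GetSymbol() == "S")
    ed = Chem.RWMol(Chem.CombineMols(mol, frag))
    ed.GetBondBetweenAtoms(beta, alpha).SetBondType(Chem.BondType.SINGLE)
    ed.AddBond(beta, mol.GetNumAtoms() + sulfur, Chem.BondType.SINGLE)
    met = _finish(ed)
    return None if met is None else (met, {beta})


def _b_carnitine(mol, site) -> BuildResult:
    acyl_c, _, hydroxyl_o = site
    met = _attach_fragment(mol, hydroxyl_o, _CARNITINYL, 5)
    return None if met is None else (met, {acyl_c})


def _b_dealkylation(mol, site) -> BuildResult:
    hetero, alpha = site
    met = _remove_side(mol, hetero, alpha)
    return None if met is None else (met, {alpha})


def _b_ester_hydrolysis(mol, site) -> BuildResult:
    acyl_c, _, ester_o, alkyl_c = site
    met = _remove_side(mol, ester_o, alkyl_c)
    return None if met is None else (met, {acyl_c})


def _b_thioester_hydrolysis(mol, site) -> BuildResult:
    acyl_c, _, sulfur, _alkyl = site
    met = _remove_side(mol, sulfur, acyl_c)
    return None if met is None else (met, {acyl_c})


def _b_inorganic_ester(mol, site) -> BuildResult:
    center, ester_o, alkyl_c = site[0], site[-2], site[-1]
    met = _remove_side(mol, ester_o, alkyl_c)
    return None if met is None else (met, {center})


def _b_reductive_dehalogenation(mol, site) -> BuildResult:
    carbon, halogen = site
    ed = Chem.RWMol(mol)
    ed.RemoveAtom(halogen)
    met = _finish(ed)
    return None if met is None else (met, {carbon})


def _b_oxidative_dehalogenation(mol, site) -> BuildResult:
    carbon, halogen = site
    ed = Chem.RWMol(mol)
    ed.ReplaceAtom(halogen, Chem.Atom(8))
    met = _finish(ed)
    return None if met is None else (met, {carbon})


def _b_oxidative_dehalogenation_epoxide(mol, site) -> BuildResult:
    halogen, c1, c2 = site
    ed = Chem.RWMol(mol)
    ed.GetBondBetweenAtoms(c1, c2).SetBondType(Chem.BondType.SINGLE)
    o = ed.AddAtom(Chem.Atom(8))
    ed.AddBond(c1, o, Chem.BondType.SINGLE)
    ed.AddBond(c2, o, Chem.BondType.SINGLE)
    ed.RemoveAtom(halogen)
    met = _finish(ed)
    return None if met is None else (met, {c1, c2})


def _b_dehydrogenation(mol, site) -> BuildResult:
    c1, c2 = site
    ed = Chem.RWMol(mol)
    ed.GetBondBetweenAtoms(c1, c2).SetBondType(Chem.BondType.DOUBLE)
    met = _finish(ed)
    return None if met is None else (met, {c1, c2})


def _b_epoxidation(mol, site) -> BuildResult:
    c1, c2 = site
    ed = Chem.RWMol(mol)
    ed.GetBondBetweenAtoms(c1, c2).SetBondType(Chem.BondType.SINGLE)
    o = ed.AddAtom(Chem.Atom(8))
    ed.AddBond(c1, o, Chem.BondType.SINGLE)
    ed.AddBond(c2, o, Chem.BondType.SINGLE)
    met = _finish(ed)
    return None if met is None else (met, {c1, c2})


def _b_lactone_hydrolysis(mol, site) -> BuildResult:
    carbonyl_c, _, ring_o = site
    met = _open_ring(mol, carbonyl_c, ring_o)
    return None if met is None else (met, {carbonyl_c})


def _b_epoxide_hydrolysis(mol, site) -> BuildResult:
    c1, ring_o, c2 = site
    met = _open_ring(mol, c1, ring_o)
    return None if met is None else (met, {c1, c2})


def _b_ether_ring_hydrolysis(mol, site) -> BuildResult:
    carbon, ring_o = site
    met = _open_ring(mol, carbon, ring_o)
    if met is None:
        return None
    # the open-chain product is the same whichever C-O ring bond broke, so
    # both carbons flanking the ring oxygen are true SOMs
    truth = {carbon}
    for nb in mol.GetAtomWithIdx(ring_o).GetNeighbors():
        bond = mol.GetBondBetweenAtoms(ring_o, nb.GetIdx())
        if nb.GetSymbol() == "C" and bond.IsInRing():
            truth.add(nb.GetIdx())
    return met, truth


TEMPLATES: tuple[Template, ...] = (
    Template("aromatic_hydroxylation", GENERAL_ADDITION, "[cH]",
             _b_aromatic_hydroxylation),
    Template("aliphatic_hydroxylation", GENERAL_ADDITION,
             "[CX4;H2,H3;!$([CX4][O,N,S,P])]", _b_aliphatic_hydroxylation),
    Template("glucuronidation", GENERAL_ADDITION,
             "[OX2H;$([OX2H]c),$([OX2H][CX3]=O)]", _b_glucuronidation),
    Template("sulfation", GENERAL_ADDITION, "[OX2H;$([OX2H]c)]", _b_sulfation),
    Template("glutathione_conjugation", GLUTATHIONE_CONJUGATION,
             "[CH2]=[CH][CX3]=[OX1]", _b_glutathione),
    Template("carnitine_conjugation", CARNITINE_CONJUGATION,
             "[CX3](=O)[OX2H]", _b_carnitine),
    Template("n_dealkylation", GENERAL_ELIMINATION, "[NX3][CX4;H2,H3]",
             _b_dealkylation,
             site_filter=lambda m, s: _non_ring_bond(m, s[0], s[1])),
    Template("o_dealkylation", GENERAL_ELIMINATION,
             "[OX2;!$([OX2]C=O)&$([OX2]c)][CX4;H3]", _b_dealkylation,
             site_filter=lambda m, s: _non_ring_bond(m, s[0], s[1])),
    Template("ester_hydrolysis", ESTER_HYDROLYSIS,
             "[CX3;!R](=O)[OX2;!R][CX4]", _b_ester_hydrolysis),
    Template("thioester_hydrolysis", GENERAL_ELIMINATION,
             "[CX3;!R](=O)[SX2;!R][CX4]", _b_thioester_hydrolysis),
    Template("phosphate_ester_hydrolysis", INORGANIC_ESTER_HYDROLYSIS,
             "[PX4][OX2][CX4;H2,H3]", _b_inorganic_ester,
             site_filter=lambda m, s: _non_ring_bond(m, s[-2], s[-1])),
    Template("sulfonate_ester_hydrolysis", INORGANIC_ESTER_HYDROLYSIS,
             "[SX4](=O)(=O)[OX2][CX4;H2,H3]", _b_inorganic_ester,
             site_filter=lambda m, s: _non_ring_bond(m, s[-2], s[-1])),
    Template("reductive_dehalogenation", GENERAL_ELIMINATION, "[#6][Cl,Br]",
             _b_reductive_dehalogenation),
    Template("oxidative_dehalogenation", OXIDATIVE_DEHALOGENATION,
             "[#6][Cl,Br]", _b_oxidative_dehalogenation),
    Template("oxidative_dehalogenation_epoxide", OXIDATIVE_DEHALOGENATION,
             "[Cl,Br][CX3]=[CX3]", _b_oxidative_dehalogenation_epoxide),
    Template("dehydrogenation", ISOMORPHISM_MAPPING,
             "[CX4;!H0;!$([CX4][O,N,S])][CX4;!H0;!$([CX4][O,N,S])]",
             _b_dehydrogenation),
    Template("epoxidation", MCS_MAPPING, "[CX3;!$([CX3][Cl,Br])]=[CX3]",
             _b_epoxidation),
    Template("lactone_hydrolysis", LACTONE_HYDROLYSIS, "[C;R](=O)[O;R]",
             _b_lactone_hydrolysis),
    Template("epoxide_hydrolysis", OXACYCLOPROPANE_HYDROLYSIS,
             "[#6]1[#8][#6]1", _b_epoxide_hydrolysis),
    Template("ether_ring_hydrolysis", HETEROCYCLE_HYDROLYSIS,
             "[CX4;R;!$([C]=O)][OX2;R;!$([O]C=O)]", _b_ether_ring_hydrolysis,
             site_filter=lambda m, s: _ring_bond_min_size(m, s[0], s[1]) >= 4),
)


# --- substrate preparation --------------------------------------------------

def _same_indexing(a: Chem.Mol, b: Chem.Mol) -> bool:
    if a.GetNumAtoms() != b.GetNumAtoms() or a.GetNumBonds() != b.GetNumBonds():
        return False
    for x, y in zip(a.GetAtoms(), b.GetAtoms()):
        if (
            x.GetSymbol() != y.GetSymbol()
            or x.GetFormalCharge() != y.GetFormalCharge()
            or x.GetTotalNumHs() != y.GetTotalNumHs()
        ):
            return False
    bonds_a = {
        tuple(sorted((bd.GetBeginAtomIdx(), bd.GetEndAtomIdx())))
        + (bd.GetBondTypeAsDouble(),)
        for bd in a.GetBonds()
    }
    bonds_b = {
        tuple(sorted((bd.GetBeginAtomIdx(), bd.GetEndAtomIdx())))
        + (bd.GetBondTypeAsDouble(),)
        for bd in b.GetBonds()
    }
    return bonds_a == bonds_b


def _prepare_substrate(smiles: str) -> Optional[tuple[str, Chem.Mol]]:
    """Standardize a scaffold and verify its atom indexing is stable under a
    parse -> standardize round trip, so generated SOM indices remain valid
    for any consumer that re-parses the emitted SMILES."""
    raw = Chem.MolFromSmiles(smiles)
    if raw is None:
        return None
    std = chem_prep.standardize(raw)
    if std is None:
        return None
    canonical = Chem.MolToSmiles(std)
    work = Chem.MolFromSmiles(canonical)
    if work is None:
        return None
    std2 = chem_prep.standardize(Chem.Mol(work))
    if std2 is None or not _same_indexing(work, std2):
        return None
    return canonical, work


# --- generation -------------------------------------------------------------

def _build_fixture(
    template: Template, canonical: str, work: Chem.Mol, site: tuple[int, ...],
    seed: int,
) -> Optional[Fixture]:
    built = template.builder(work, site)
    if built is None:
        return None
    met, truth = built
    if not truth:
        return None
    met_smiles = Chem.MolToSmiles(met)
    probe = ReactionRecord(canonical, met_smiles, 0, 1)
    pair = chem_prep.validate(probe)
    if not pair.accepted:
        return None
    return Fixture(
        substrate_smiles=canonical,
        metabolite_smiles=met_smiles,
        truth_soms=frozenset(truth),
        transformation=template.label,
        seed=seed,
        template=template.name,
    )


def enumerate_applications() -> dict[str, list[tuple[str, Chem.Mol, tuple[int, ...]]]]:
    """All (scaffold, site) applications per template, deterministic order."""
    prepared = []
    for smiles in SCAFFOLDS:
        item = _prepare_substrate(smiles)
        if item is None:
            logger.info("scaffold skipped (unstable standardization): %s", smiles)
            continue
        prepared.append(item)
    applications: dict[str, list] = {t.name: [] for t in TEMPLATES}
    for template in TEMPLATES:
        for canonical, work in prepared:
            for site in template.sites(work):
                applications[template.name].append((canonical, work, site))
    return applications


def generate(seed: int, n: int) -> list[Fixture]:
    """Generate ``n`` fixtures, deterministic for a fixed seed.

    Templates are sampled round-robin so every transformation family is
    exercised roughly equally; scaffold/site choices within a template are
    drawn from a seeded RNG.  Inapplicable or chemically invalid
    applications are skipped and logged.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = random.Random(seed)
    applications = enumerate_applications()
    template_by_name = {t.name: t for t in TEMPLATES}
    order = [t.name for t in TEMPLATES if applications[t.name]]
    if not order:
        raise RuntimeError("no applicable template/scaffold combinations")
    fixtures: list[Fixture] = []
    stalled = 0
    while len(fixtures) < n:
        progressed = False
        for name in order:
            if len(fixtures) >= n:
                break
            apps = applications[name]
            canonical, work, site = apps[rng.randrange(len(apps))]
            fixture = _build_fixture(template_by_name[name], canonical, work, site, seed)
            if fixture is None:
                logger.info("template %s skipped on %s", name, canonical)
                continue
            fixtures.append(fixture)
            progressed = True
        stalled = 0 if progressed else stalled + 1
        if stalled > 10:
            raise RuntimeError("fixture generation stalled; no template applies")
    return fixtures


# --- CSV emission (same dialect the pipeline consumes) ----------------------

def write_pairs_csv(fixtures: list[Fixture], path) -> None:
    frame = pd.DataFrame(
        {
            "substrate_smiles": [f.substrate_smiles for f in fixtures],
            "substrate_id": [1000 + i for i in range(len(fixtures))],
            "metabolite_smiles": [f.metabolite_smiles for f in fixtures],
            "metabolite_id": [500000 + i for i in range(len(fixtures))],
        }
    )
    frame.to_csv(path, index=False)


def write_truth_csv(fixtures: list[Fixture], path) -> None:
    frame = pd.DataFrame(
        {
            "substrate_id": [1000 + i for i in range(len(fixtures))],
            "metabolite_id": [500000 + i for i in range(len(fixtures))],
            "substrate_smiles": [f.substrate_smiles for f in fixtures],
            "som_indices": [
                " ".join(str(i) for i in sorted(f.truth_soms)) for f in fixtures
            ],
            "transformation": [f.transformation for f in fixtures],
            "family": [f.family for f in fixtures],
            "template": [f.template for f in fixtures],
        }
    )
    frame.to_csv(path, index=False)
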