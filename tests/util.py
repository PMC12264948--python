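"""Small helpers shared across test modules."""

from __future__ import annotations

from rdkit import Chem

from autosom import chem_prep
from autosom.records import ReactionRecord


def record(sub: str, met: str, i: int = 0) -> ReactionRecord:
    return ReactionRecord(sub, met, 10 + i, 900 + i)


def pair_of(sub: str, met: str, i: int = 0):
    pair = chem_prep.validate(record(sub, met, i))
    assert pair.accepted, f"test pair unexpectedly rejected: {pair.rejection_reason}"
    return pair


def first_match(mol: Chem.Mol, smarts: str) -> tuple[int, ...]:
    query = Chem.MolFromSmarts(smarts)
    matches = mol.GetSubstructMatches(query)
    assert matches, f"pattern {smarts} not found in {Chem.MolToSmiles(mol)}"
    return matches[0]


def all_match_atoms(mol: Chem.Mol, smarts: str, position: int = 0) -> set[int]:
    query = Chem.MolFromSmarts(smarts)
    return {m[position] for m in mol.GetSubstructMatches(query)}
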