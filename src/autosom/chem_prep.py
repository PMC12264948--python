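"""Input validation and molecule standardization.

Substrate-metabolite pairs arrive as SMILES strings; before any graph
matching both sides are brought onto a common footing: counterions and
solvents stripped to a single organic parent, functional groups normalized,
charges neutralized where chemically valid, and one canonical tautomer
chosen.  Pairs that cannot be parsed, contain unsupported elements, or are
structurally identical (same InChI key) are rejected as data, not raised as
exceptions, so a batch run never aborts on a bad row.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .records import (
    DISALLOWED_ELEMENT,
    IDENTICAL_PAIR,
    KEY_FAILURE,
    UNPARSEABLE,
    ReactionRecord,
    StandardizedPair,
)

logger = logging.getLogger("autosom")

RDLogger.DisableLog("rdApp.*")

#: Elements accepted on either side of a reaction.  Anything else marks the
#: pair as outside the validated chemical space.
ALLOWED_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si", "Se"}
)

_uncharger = rdMolStandardize.Uncharger()
_tautomer_params = rdMolStandardize.CleanupParameters()
_tautomer_params.maxTautomers = 500
_tautomer_params.maxTransforms = 500
_tautomerizer = rdMolStandardize.TautomerEnumerator(_tautomer_params)


def _inchi_key(mol: Chem.Mol) -> Optional[str]:
    try:
        key = Chem.MolToInchiKey(mol)
    except Exception:  # pragma: no cover - RDKit raises rarely here
        return None
    return key or None


def _largest_organic_parent(mol: Chem.Mol) -> Chem.Mol:
    """Keep a single parent component.

    Preference: organic (carbon-containing) fragments first, then heavy-atom
    count, then lexicographically smallest InChI key for a stable tie-break.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol

    ranked = sorted(
        frags,
        key=lambda f: (
            not any(a.GetSymbol() == "C" for a in f.GetAtoms()),
            -f.GetNumHeavyAtoms(),
            _inchi_key(f) or "",
        ),
    )
    return ranked[0]


def standardize(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Standardize a parsed molecule; ``None`` on failure.

    Steps, in order: largest-organic-parent selection, functional-group
    normalization, neutralization, stereo stripping, canonical tautomer,
    implicit hydrogens.  Neutralization runs before tautomer
    canonicalization because protonation state can change tautomer ranking.
    The whole procedure is idempotent up to InChI-key equality.
    """
    try:
        mol = _largest_organic_parent(mol)
        mol = rdMolStandardize.Cleanup(mol)
        mol = rdMolStandardize.Normalize(mol)
        mol = _uncharger.uncharge(mol)
        Chem.RemoveStereochemistry(mol)
        mol = _tautomerizer.Canonicalize(mol)
        mol = Chem.RemoveHs(mol)
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _has_disallowed_element(mol: Chem.Mol) -> bool:
    return any(a.GetSymbol() not in ALLOWED_ELEMENTS for a in mol.GetAtoms())


def validate(record: ReactionRecord) -> StandardizedPair:
    """Validate and standardize one input row.

    Returns an accepted :class:`StandardizedPair` or one tagged with exactly
    one rejection reason (``unparseable``, ``key_failure``,
    ``identical_pair``, ``disallowed_element``).
    """

    def reject(reason: str) -> StandardizedPair:
        logger.info(
            "rejected pair (%s, %s): %s",
            record.substrate_id,
            record.metabolite_id,
            reason,
        )
        return StandardizedPair(record=record, rejection_reason=reason)

    sub_raw = Chem.MolFromSmiles(record.substrate_smiles)
    met_raw = Chem.MolFromSmiles(record.metabolite_smiles)
    if sub_raw is None or met_raw is None:
        return reject(UNPARSEABLE)

    sub_key_raw = _inchi_key(sub_raw)
    met_key_raw = _inchi_key(met_raw)
    if sub_key_raw is None or met_key_raw is None:
        return reject(KEY_FAILURE)
    if sub_key_raw == met_key_raw:
        return reject(IDENTICAL_PAIR)

    if _has_disallowed_element(sub_raw) or _has_disallowed_element(met_raw):
        return reject(DISALLOWED_ELEMENT)

    sub = standardize(sub_raw)
    met = standardize(met_raw)
    if sub is None or met is None:
        return reject(UNPARSEABLE)

    sub_key = _inchi_key(sub)
    met_key = _inchi_key(met)
    if sub_key is None or met_key is None:
        return reject(KEY_FAILURE)
    if sub_key == met_key:
        # e.g. the two sides are tautomers or a salt of the same parent
        return reject(IDENTICAL_PAIR)

    return StandardizedPair(
        record=record,
        substrate=sub,
        metabolite=met,
        substrate_key=sub_key,
        metabolite_key=met_key,
    )


def read_records(csv_path) -> list[ReactionRecord]:
    """Read the input CSV (columns substrate_smiles, substrate_id,
    metabolite_smiles, metabolite_id) into records."""
    frame = pd.read_csv(csv_path)
    required = {"substrate_smiles", "substrate_id", "metabolite_smiles", "metabolite_id"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"input CSV missing columns: {sorted(missing)}")
    return [
        ReactionRecord(
            substrate_smiles=str(row.substrate_smiles),
            metabolite_smiles=str(row.metabolite_smiles),
            substrate_id=int(row.substrate_id),
            metabolite_id=int(row.metabolite_id),
        )
        for row in frame.itertuples(index=False)
    ]


def validate_all(records: Iterable[ReactionRecord]) -> list[StandardizedPair]:
    return [validate(r) for r in records]
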