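"""Scoring of predicted against ground-truth SOM sets.

Three mutually exclusive match categories (plus "none"):

* ``full``     - predicted set equals the truth set exactly;
* ``partial``  - non-empty overlap but a false positive or false negative;
* ``neighbor`` - no overlap, yet some true SOM is bonded to a predicted atom;
* ``none``     - anything else (including an empty prediction).

Truth sets are expanded over the substrate's symmetry orbits before
comparison, so annotations that differ only in which of two topologically
equivalent atoms they name compare equal.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem

from .graph_map import symmetry_expand

FULL = "full"
PARTIAL = "partial"
NEIGHBOR = "neighbor"
NONE = "none"

CATEGORIES = (FULL, PARTIAL, NEIGHBOR, NONE)


def match_category(
    predicted: Iterable[int], truth: Iterable[int], substrate: Chem.Mol
) -> str:
    """Categorize one prediction; ``truth`` must be non-empty."""
    predicted = frozenset(predicted)
    truth = frozenset(truth)
    if not truth:
        raise ValueError("truth SOM set must be non-empty")
    if predicted == truth:
        return FULL
    if predicted & truth:
        return PARTIAL
    for t in truth:
        atom = substrate.GetAtomWithIdx(int(t))
        if any(nb.GetIdx() in predicted for nb in atom.GetNeighbors()):
            return NEIGHBOR
    return NONE


def score(
    predicted: Iterable[int],
    truth: Iterable[int],
    substrate: Chem.Mol,
    expand_truth: bool = True,
) -> str:
    """Orbit-expand the truth set, then categorize."""
    truth = frozenset(truth)
    if expand_truth:
        truth = symmetry_expand(substrate, truth)
    return match_category(predicted, truth, substrate)


def aggregate(results: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Per-rule match-rate table from ``(rule label, category)`` pairs.

    One row per rule plus an "All" row; percentages are relative to the
    number of reactions in that row's category.
    """
    if not results:
        raise ValueError("no results to aggregate")
    frame = pd.DataFrame(results, columns=["rule", "category"])
    rows = []
    groups = [("All", frame)] + [
        (rule, g) for rule, g in frame.groupby("rule", sort=True)
    ]
    for name, group in groups:
        n = len(group)
        counts = group["category"].value_counts()
        rows.append(
            {
                "rule": name,
                "n_reactions": n,
                "full_pct": 100.0 * counts.get(FULL, 0) / n,
                "partial_pct": 100.0 * counts.get(PARTIAL, 0) / n,
                "neighbor_pct": 100.0 * counts.get(NEIGHBOR, 0) / n,
            }
        )
    return pd.DataFrame(rows)


def _parse_soms(text) -> frozenset[int]:
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return frozenset()
    text = str(text).strip()
    if not text:
        return frozenset()
    return frozenset(int(t) for t in text.split())


def score_tables(
    predictions: pd.DataFrame,
    truth: pd.DataFrame,
    expand_truth: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a results table against a truth table.

    Both tables are keyed by (substrate_id, metabolite_id) with a
    space-separated ``som_indices`` column; the truth table additionally
    carries ``substrate_smiles`` so adjacency and symmetry can be computed.
    Returns the merged per-reaction table (with a ``category`` column) and
    the aggregate per-rule table.
    """
    from . import chem_prep  # local import to avoid a cycle

    merged = predictions.merge(
        truth,
        on=["substrate_id", "metabolite_id"],
        suffixes=("_pred", "_true"),
        how="inner",
    )
    categories = []
    for row in merged.itertuples(index=False):
        mol = Chem.MolFromSmiles(row.substrate_smiles)
        mol = chem_prep.standardize(mol) if mol is not None else None
        if mol is None:
            categories.append(NONE)
            continue
        categories.append(
            score(
                _parse_soms(row.som_indices_pred),
                _parse_soms(row.som_indices_true),
                mol,
                expand_truth=expand_truth,
            )
        )
    merged = merged.copy()
    merged["category"] = categories
    rule_col = "rule" if "rule" in merged.columns else "rule_pred"
    table = aggregate(list(zip(merged[rule_col], merged["category"])))
    return merged, table
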