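"""Orchestration: routing, timeout enforcement, symmetry post-processing,
batch execution and output writing.

Routing is by heavy-atom count: metabolite heavier -> addition handler,
lighter -> elimination handler, equal -> complex handler directly.  A
handler that finds nothing forwards the pair to the complex handler.  Any
SOM set found is expanded over the substrate's topological-symmetry orbits
immediately before output.  Every annotation attempt is bounded by a
cooperative deadline (default 20 s); on expiry the reaction is returned
with the "timeout" status and no SOMs.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem

from . import chem_prep, graph_map
from .graph_map import AnnotationTimeout, Deadline
from .records import (
    ANNOTATION_RULES,
    DEFAULT_RULE_ORDER,
    INVALID,
    TIMEOUT,
    UNKNOWN,
    ReactionRecord,
    RuleConfig,
    SomAnnotation,
    StandardizedPair,
)
from .rules_addition import handle_addition
from .rules_complex import handle_complex
from .rules_elimination import handle_elimination

logger = logging.getLogger("autosom")

RESULT_COLUMNS = ["substrate_id", "metabolite_id", "som_indices", "rule", "status", "elapsed_s"]


def annotate(pair: StandardizedPair, config: Optional[RuleConfig] = None) -> SomAnnotation:
    """Annotate one accepted pair; timing excludes standardization."""
    if not pair.accepted:
        return SomAnnotation(rule=INVALID)
    config = config or RuleConfig()
    start = time.monotonic()
    deadline = Deadline(config.timeout_seconds)
    annotation: Optional[SomAnnotation] = None
    try:
        deadline.check()
        n_sub = pair.substrate.GetNumAtoms()
        n_met = pair.metabolite.GetNumAtoms()
        if n_met > n_sub:
            annotation = handle_addition(pair, config, deadline)
        elif n_met < n_sub:
            annotation = handle_elimination(pair, config, deadline)
        if annotation is None:
            annotation = handle_complex(pair, config, deadline)
    except AnnotationTimeout:
        elapsed = time.monotonic() - start
        logger.info(
            "timeout for pair (%s, %s) after %.2fs",
            pair.record.substrate_id,
            pair.record.metabolite_id,
            elapsed,
        )
        return SomAnnotation(rule=TIMEOUT, elapsed_s=elapsed)
    elapsed = time.monotonic() - start
    if annotation is None or not annotation.som_indices:
        return SomAnnotation(rule=UNKNOWN, elapsed_s=elapsed)
    expanded = graph_map.symmetry_expand(pair.substrate, annotation.som_indices)
    return SomAnnotation(
        som_indices=expanded,
        rule=annotation.rule,
        elapsed_s=elapsed,
        mapping=annotation.mapping,
    )


def annotate_record(record: ReactionRecord, config: Optional[RuleConfig] = None
                    ) -> tuple[StandardizedPair, SomAnnotation]:
    """Validate + annotate a single raw record."""
    pair = chem_prep.validate(record)
    return pair, annotate(pair, config)


def _result_row(pair: StandardizedPair, annotation: SomAnnotation) -> dict:
    return {
        "substrate_id": pair.record.substrate_id,
        "metabolite_id": pair.record.metabolite_id,
        "som_indices": " ".join(str(i) for i in sorted(annotation.som_indices)),
        "rule": annotation.rule,
        "status": annotation.status,
        "elapsed_s": round(annotation.elapsed_s, 4),
    }


def _write_sdf(path: Path, entries: Iterable[tuple[Chem.Mol, dict]]) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for mol, props in entries:
        mol = Chem.Mol(mol)
        for key, value in props.items():
            mol.SetProp(key, str(value))
        writer.write(mol)
    writer.close()


def run_batch(
    input_csv,
    config: Optional[RuleConfig] = None,
    out_dir=None,
) -> pd.DataFrame:
    """Annotate every row of the input CSV.

    Returns the results table and, when ``out_dir`` is given, writes
    ``results.csv`` plus three V2000 SD files: annotated substrates,
    metabolites, and a consolidated file in which each unique substrate
    (by InChI key) appears once with the union of its SOMs.
    """
    config = config or RuleConfig()
    records = chem_prep.read_records(input_csv)
    rows = []
    substrate_entries: list[tuple[Chem.Mol, dict]] = []
    metabolite_entries: list[tuple[Chem.Mol, dict]] = []
    consolidated: dict[str, dict] = {}
    for record in records:
        pair = chem_prep.validate(record)
        annotation = annotate(pair, config)
        rows.append(_result_row(pair, annotation))
        if not pair.accepted:
            continue
        som_str = " ".join(str(i) for i in sorted(annotation.som_indices))
        substrate_entries.append(
            (pair.substrate, {"SOMS": som_str, "RULE": annotation.rule,
                              "ID": record.substrate_id})
        )
        metabolite_entries.append(
            (pair.metabolite, {"RULE": annotation.rule, "ID": record.metabolite_id})
        )
        entry = consolidated.setdefault(
            pair.substrate_key,
            {"mol": pair.substrate, "soms": set(), "rules": set(),
             "id": record.substrate_id},
        )
        entry["soms"] |= annotation.som_indices
        if annotation.rule in ANNOTATION_RULES:
            entry["rules"].add(annotation.rule)

    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "results.csv", index=False)
        _write_sdf(out / "substrates.sdf", substrate_entries)
        _write_sdf(out / "metabolites.sdf", metabolite_entries)
        _write_sdf(
            out / "substrates_consolidated.sdf",
            (
                (
                    entry["mol"],
                    {
                        "SOMS": " ".join(str(i) for i in sorted(entry["soms"])),
                        "RULE": "; ".join(sorted(entry["rules"])),
                        "INCHIKEY": key,
                        "ID": entry["id"],
                    },
                )
                for key, entry in sorted(consolidated.items())
            ),
        )
    return frame


def ablation_run(
    pairs: Sequence[StandardizedPair],
    rule_order: Sequence[str] = DEFAULT_RULE_ORDER,
    timeout_seconds: float = 20.0,
) -> pd.DataFrame:
    """Annotate the same pairs under growing rule-set prefixes.

    For k = 0..N the first k rules of ``rule_order`` are enabled; the table
    reports the annotated-reaction count (coverage) and the per-pair rules.
    Coverage is monotone non-decreasing in k.
    """
    rows = []
    for k in range(len(rule_order) + 1):
        enabled = frozenset(rule_order[:k])
        config = RuleConfig(timeout_seconds=timeout_seconds, enabled_rules=enabled)
        annotations = [annotate(p, config) for p in pairs]
        annotated = sum(1 for a in annotations if a.status == "annotated")
        rows.append(
            {
                "n_rules": k,
                "enabled_rules": ", ".join(rule_order[:k]),
                "n_pairs": len(pairs),
                "n_annotated": annotated,
                "coverage": annotated / len(pairs) if pairs else 0.0,
                "annotations": annotations,
            }
        )
    return pd.DataFrame(rows)
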