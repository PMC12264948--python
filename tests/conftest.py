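"""Shared corpus fixtures.

The synthetic corpus (200 pairs, fixed seed) is generated once per session
and annotated once; most invariant and recovery tests read from it.
"""

from __future__ import annotations

import pytest

from autosom import chem_prep, evaluation, fixtures, pipeline
from autosom.records import ReactionRecord

CORPUS_SEED = 1
CORPUS_N = 200


@pytest.fixture(scope="session")
def corpus():
    return fixtures.generate(CORPUS_SEED, CORPUS_N)


@pytest.fixture(scope="session")
def annotated_corpus(corpus):
    """List of (fixture, standardized pair, annotation, match category)."""
    out = []
    for i, fx in enumerate(corpus):
        record = ReactionRecord(
            fx.substrate_smiles, fx.metabolite_smiles, 1000 + i, 500000 + i
        )
        pair = chem_prep.validate(record)
        annotation = pipeline.annotate(pair)
        category = evaluation.score(
            annotation.som_indices, fx.truth_soms, pair.substrate
        )
        out.append((fx, pair, annotation, category))
    return out


@pytest.fixture(scope="session")
def standardized_pairs(annotated_corpus):
    return [pair for _, pair, _, _ in annotated_corpus]
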