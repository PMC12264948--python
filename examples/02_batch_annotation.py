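"""Batch-annotate a CSV of reactions and write the standard outputs.

Builds a small input file, runs the pipeline, and prints the per-reaction
results table.  Next to results.csv the run writes three SD files: the
annotated substrates (SOMS/RULE properties), the metabolites, and a
consolidated file with one entry per unique substrate carrying the union of
its SOMs.
"""

import tempfile
from pathlib import Path

import pandas as pd

from autosom import run_batch

rows = [
    ("COC(=O)c1ccccc1", 1, "OC(=O)c1ccccc1", 101),        # ester hydrolysis
    ("CN1CCN(c2ccccc2)CC1", 2, "C1CN(c2ccccc2)CCN1", 102),  # N-demethylation
    ("Clc1ccccc1", 3, "Oc1ccccc1", 103),                   # oxidative dehalogenation
    ("Cc1ccccc1", 4, "Cc1ccccc1O", 104),                   # aromatic hydroxylation
    ("Cc1ccccc1", 5, "OCc1ccccc1", 105),                   # benzylic hydroxylation
]

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    pd.DataFrame(
        rows,
        columns=["substrate_smiles", "substrate_id",
                 "metabolite_smiles", "metabolite_id"],
    ).to_csv(tmp / "pairs.csv", index=False)

    results = run_batch(tmp / "pairs.csv", out_dir=tmp / "out")
    print(results.to_string(index=False))
    print()
    print("outputs:", sorted(p.name for p in (tmp / "out").iterdir()))
    print()
    print("Reactions 4 and 5 share the toluene substrate: the consolidated")
    print("SD file contains it once, with the ring and benzylic SOMs merged.")
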