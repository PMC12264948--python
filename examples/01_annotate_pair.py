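"""Annotate a single substrate-metabolite pair.

Aniline is ortho-hydroxylated to 2-aminophenol.  The annotator embeds the
substrate in the metabolite, marks the ring carbon that gained the hydroxyl
neighbor, and then expands over the substrate's symmetry orbits -- the two
ortho carbons are topologically equivalent, so both are reported.
"""

from autosom import annotate_record
from autosom.records import ReactionRecord

record = ReactionRecord(
    substrate_smiles="Nc1ccccc1",
    metabolite_smiles="Nc1ccccc1O",
    substrate_id=1,
    metabolite_id=2,
)
pair, annotation = annotate_record(record)

print(f"substrate : {record.substrate_smiles}")
print(f"metabolite: {record.metabolite_smiles}")
print(f"rule      : {annotation.rule}")
print(f"SOMs      : {sorted(annotation.som_indices)}")
print(f"elapsed   : {annotation.elapsed_s * 1000:.1f} ms")
print()
print("The SOM indices are 0-based atom positions on the standardized")
print("substrate; both ortho ring carbons appear because they are")
print("symmetry-equivalent sites of the same hydroxylation.")
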