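# autosom

Rule-based annotation of **sites of metabolism (SOMs)** from unbalanced
substrate–metabolite pairs.

Metabolic databases and the medicinal-chemistry literature are full of
substrate → metabolite observations, but most of them do not say *which
substrate atom* the metabolizing enzyme attacked. That atom — the site of
metabolism — is exactly the label SOM-prediction models need for training.
`autosom` closes that gap: given only the two SMILES strings of an
(unbalanced, not stoichiometry-normalized) reaction, it derives the SOM
atom set on the substrate by graph reasoning, without any machine-learned
component.

## Method

Each pair is standardized (salt stripping to the largest organic parent,
normalization, neutralization, one canonical tautomer) and routed by the
heavy-atom balance of the reaction:

- **Addition** (metabolite heavier, substrate ⊂ metabolite): the substrate
  is embedded in the metabolite by induced subgraph isomorphism with bond
  orders and charges matched; SOMs are the substrate atoms whose image
  gained a neighbor. Glutathione conjugates are recognized first by a
  tripeptide substructure (the Michael addition saturates a C=C bond, which
  defeats bond-order-sensitive matching); a carnitine-ester correction moves
  the SOM from the ester oxygen to the carboxyl carbon.
- **Elimination** (substrate heavier, metabolite ⊂ substrate): at each
  boundary bond between mapped and unmapped substrate atoms, a removed
  *carbon* is itself the SOM (type 1, dealkylations) while a removed
  *heteroatom* marks its retained neighbor (type 2, reductions).
  Hydrolyses of (thio)esters and of P/S-centered acid esters relocate the
  SOM to the carbonyl carbon or to the phosphorus/sulfur atom.
- **Complex** (everything else, including equal atom counts): oxidative
  dehalogenation (carbon count retained, halogen → oxygen exchange), then a
  complete atom mapping ignoring bond orders (SOMs where hydrogen counts or
  formal charges changed), then a maximum-common-substructure (MCS)
  difference map (SOMs wherever topology changed), followed by corrections
  for oxacyclopropane, lactone and other heterocyclic ring hydrolyses.

Found SOM sets are expanded over the substrate's topological-symmetry
orbits (both ortho carbons of aniline, both methyls of *p*-xylene), every
annotation carries exactly one rule label and its runtime, and a
per-reaction timeout (default 20 s) bounds the combinatorial matching.
Predictions are scored against reference annotations as **full** (exact set
equality), **partial** (overlap with errors) or **neighbor** (adjacent atom
only) matches.

Because curated metabolic databases cannot be redistributed, the package
ships a synthetic-fixture generator: 20 biotransformation templates applied
to a 30-molecule drug-like scaffold panel, with ground-truth SOMs recorded
during graph editing rather than hand-annotated.

## Worked example

```python
from autosom import annotate_record
from autosom.records import ReactionRecord

pair, annotation = annotate_record(
    ReactionRecord("Nc1ccccc1", "Nc1ccccc1O", 1, 2)
)
print(annotation.rule, sorted(annotation.som_indices))
```

prints

```
general addition [2, 6]
```

— the ortho-hydroxylation of aniline is recognized as a general addition,
and both ortho ring carbons (atoms 2 and 6 of the standardized substrate)
are annotated because they are symmetry-equivalent attack sites. The
scripts in `examples/` walk through single-pair annotation, batch runs with
SDF output, corpus evaluation and rule ablation; `autosom annotate|evaluate|fixtures`
exposes the same functionality on the command line.

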