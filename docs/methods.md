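# Methods

## Problem and scope

Given an unbalanced substrate–metabolite pair (two SMILES strings, no
stoichiometry, no atom mapping), the package derives the set of substrate
atoms at which the metabolic transformation was initiated — the sites of
metabolism (SOMs). The method is purely rule-based graph reasoning;
nothing is learned from data, so every annotation is deterministic and
explainable by the single rule label it carries.

## Standardization

Both sides of a pair are brought onto a common footing before any
matching, using RDKit's `rdMolStandardize`:

1. largest-organic-parent selection (counterion/solvent stripping);
   ties are broken by heavy-atom count, then lexicographically by InChI
   key, so the choice is reproducible;
2. cleanup and functional-group normalization;
3. neutralization where chemically valid (permanent charges such as
   quaternary ammonium and the balancing carboxylate of a zwitterion are
   kept);
4. stereochemistry stripping — stereo handling is out of scope, and all
   matching is constitutional;
5. canonical-tautomer selection, run *after* neutralization because
   protonation state can change tautomer ranking;
6. implicit hydrogens only.

The procedure is idempotent (checked by test). Pairs are rejected as data,
never as exceptions, with exactly one reason each: `unparseable`,
`key_failure` (no InChI key), `identical_pair` (same InChI key before or
after standardization — this also catches tautomer pairs and, since stereo
is stripped late, routes chiral inversions to `unknown` rather than
rejecting them), or `disallowed_element` (outside H, C, N, O, S, P, F, Cl,
Br, I, B, Si, Se).

## Graph model and matching regimes

Molecules are colored heavy-atom graphs: nodes carry element, formal
charge, total hydrogen count and aromaticity; edges carry the bond order,
with aromatic bonds compared as order 1.5 so kekulized and aromatic
drawings of one ring agree. Three matching primitives are used:

- **Induced subgraph isomorphism** (NetworkX VF2) with configurable
  node/edge strictness. The addition handler matches elements, charges
  *and* bond orders — the cheapest, most specific regime. The elimination
  handler matches elements only: the reductions it must recognize (nitro →
  nitroso, sulfoxide → sulfide) change charge and bond order on the
  reacting center. The glutathione remainder step uses subgraph
  *monomorphism*, because the substrate may retain a bond (an epoxide C–O)
  that conjugation opened.
- **Maximum common substructure** (RDKit FMCS), elements compared, bond
  orders per regime, single connected fragment, atom count maximized. A
  disconnected MCS would scatter spurious SOMs on small pairs, hence the
  connectivity requirement.
- **Symmetry orbits** from RDKit's canonical ranking with tie-breaking
  disabled, which groups exactly the topologically equivalent atoms.
  Tests cross-check these orbits against brute-force automorphism
  enumeration, and the MCS size against a McGregor-style exhaustive
  search, on all small corpus pairs.

**Tie-break policy.** Wherever several embeddings or MCS placements exist
(symmetric substrates), the handler evaluates the SOM set each candidate
would produce and keeps the one with the fewest SOMs, then the
lexicographically smallest sorted index set, then the smallest mapping.
This makes every annotation deterministic; the symmetry expansion applied
at the end makes the choice among equivalent atoms immaterial.

## Routing and handlers

Heavier metabolite → addition handler; lighter → elimination handler;
equal heavy-atom counts → complex handler directly (the balance ratio
defines only the two strict branches). A handler that finds nothing
forwards the pair to the complex handler; if that also fails, the reaction
is returned with empty SOMs and status `unknown`.

Within the complex handler the order is: oxidative dehalogenation →
complete-mapping hydrogen/charge diff → MCS topology diff → ring-hydrolysis
corrections. "Topological change" in the MCS diff includes incident
bond-order changes, not only neighbor-set changes — redox reactions such as
phenol → benzoquinone alter bond orders at atoms whose neighbor sets are
unchanged. Hydrogen-count changes alone are deliberately *not* MCS-diff
SOM criteria, to avoid labeling spectator hydroxyls.

Two ring corrections reflect an identity limit of the data: when a
symmetric ring opens hydrolytically, the product cannot reveal which C–X
bond broke. For oxacyclopropanes both ring carbons are therefore labeled;
the same convention is extended to other heterocyclic ring openings (all
ring carbons flanking the cleaved heteroatom). Lactone hydrolysis labels
the carbonyl carbon, whichever ester C–O bond the MCS happened to break.

## Timeout

Subgraph and MCS matching are exponential in the worst case. Every
annotation attempt runs under a cooperative deadline (default 20 s,
configurable): the matching loops poll a monotonic clock and the FMCS call
receives the remaining budget as its own timeout. The contract is
observable termination within the limit plus a one-second grace;
timed-out reactions are reported with status `timeout` and no SOMs.
Reported per-reaction times exclude standardization.

## Outputs

Batch runs write a results CSV (`substrate_id, metabolite_id, som_indices,
rule, status, elapsed_s`; indices 0-based on the standardized substrate)
and three V2000 SD files: annotated substrates (`SOMS`/`RULE` properties),
metabolites, and a consolidated file keyed by substrate InChI key in which
each unique substrate appears once with the union of its SOMs across
reactions — union rather than per-reaction entries, so the consolidated
file is directly usable as a training-label table.

## Synthetic corpus

Real curated reaction databases cannot be shipped, so the test corpus is
generated: 20 transformation templates applied to a 30-molecule drug-like
scaffold panel embedded as source literals. Templates edit the molecular
graph forward (attach a glucuronyl or glutathionyl fragment, cut a
dealkylation bond, open a ring, exchange halogen for oxygen, ...) and
record their anchor atoms as ground truth during the edit. The generator
verifies that every emitted substrate's atom indexing is stable under a
parse → standardize round trip, so truth indices remain valid for any
consumer that re-reads the CSV. Sampling is round-robin over templates
with a seeded RNG, giving a deterministic corpus in which every rule label
is exercised (≥ 5 fixtures per label at n = 200; the default corpus is 200
pairs, sized to keep the full suite in seconds-to-minutes on one CPU).

What the generator does *not* emulate: multi-step transformations,
stereochemical outcomes, enzyme preferences or realistic metabolic
likelihoods, and metabolites whose connection to the substrate requires
knowledge beyond the two molecular graphs. Perfect recovery on this corpus
therefore shows the rule engine is internally consistent with its own
definitions on clean single-step chemistry; it does not bound accuracy on
curated experimental data, where drawing conventions, multistep records
and annotation subjectivity reduce agreement.

## Evaluation

Predictions are scored per reaction as full (set equality), partial
(non-empty overlap with a false positive or negative), neighbor (no
overlap, but a true SOM is bonded to a predicted atom; checked only when
the overlap is empty) or none; an empty prediction is always `none`, and
an empty truth set is an input error. Ground truth is expanded over the
substrate's symmetry orbits before comparison — annotations differing only
in the choice among equivalent atoms compare equal. Aggregation reports
percentages per rule label relative to that label's reaction count, plus
an overall row.

## Known limitations

- Reactions whose substrate embedding is defeated by drawing-level
  aromaticity differences fall through to the MCS diff, which may
  over-annotate (every changed ring bond marks its atoms).
- Multi-site simultaneous transformations are annotated per boundary bond
  independently; no attempt is made to detect multistep origin.
- Charge-change SOMs on the complete-mapping path are rare after
  neutralization but retained for the cases neutralization cannot touch.
- The per-reaction timeout makes batch throughput robust but means very
  large or highly symmetric molecules can return `timeout` rather than an
  annotation.
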