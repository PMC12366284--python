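# Methods

## Model

A mechanism is an ordered list of catalytic steps.  Each step carries
the labelled molecular graph of every species present in the active
site at the start of the step (atoms with atomic number and integer
formal charge; simple undirected bonds of order single, double, triple
or aromatic; the graph may be disconnected) plus at least one curly
arrow.  An arrow moves 1 or 2 electrons from a *source* — a lone
pair/radical on one atom, or an existing bond — to a *sink* — an atom,
an existing bond, or an *incipient* bond between two not-yet-bonded
atoms.  All arrows of a step are concerted by convention; anything
sequential belongs in the next step.

Assumptions and deliberate omissions: no 3D coordinates, no
stereochemistry (steps differing only in chirality compare equal), no
kinetics or energetics, no partial charges, no implicit hydrogens
(hydrogens that participate in the chemistry, or fall inside any
extraction shell of interest, must be explicit atoms).  Aromatic bonds
are a distinct order and are never kekulized, so env equality cannot
depend on an arbitrary kekulization choice.

## Reaction centres and arrow-environments

The *reaction centres* of an arrow are the atoms its tail or tip
touches; a tail or tip interacting with a bond (existing or incipient)
touches both atoms of that bond.  Any valid arrow therefore has 1–4
centres.  Centres are annotated with two digits: the electron count
(1 or 2) and the role — 1 tail, 2 tip, 3 both (deduplicated when tail
and tip meet the same atom).

An arrow-env is the induced subgraph of the state on all atoms within
`shell_depth` bonds of any centre (multi-source BFS per connected
component).  Induced means every state bond between two included atoms
is kept, including bonds between two outermost-shell atoms; this keeps
each env fragment connected to at least one centre.  Definitions:

| name               | shell_depth | outer-shell equivalence |
|--------------------|-------------|-------------------------|
| `one_away`         | 1           | none                    |
| `two_away`         | 2           | none                    |
| `ezmechanism_like` | 2           | {C, H}                  |

The equivalence applies only at *exactly* the outermost shell:
centre and inner-shell C/H atoms are never merged, and centres are
never equivalence-class atoms (they are at distance 0).  Custom
definitions (any depth ≥ 1, any equivalence element set) are ordinary
`ArrowEnvDefinition` values.

Because a one-away env is a deterministic function of the two-away env
(shell distances within the env agree with the state), and the
EzMechanism-like env is a pure relabelling of the two-away env, equal
two-away keys imply equal one-away keys and equal EzMechanism-like
keys.  The test suite asserts these coarsening implications on random
corpora.

## Canonicalization

Env equality is label-preserving graph isomorphism over the label
tuple (element set, formal charge, arrow digits) on atoms and bond
order on edges.  No off-the-shelf canonicalizer accepts this label
alphabet, so a small exact one is used: iterative neighbourhood-label
refinement (1-WL with vertex and edge labels), then exhaustive
individualization of the first non-discrete cell, keeping the
lexicographically smallest certificate.  Envs are tiny (usually well
under 30 atoms, automorphism groups of a handful of swaps), so the
worst case never bites in practice.  Correctness is tested against an
independent VF2 isomorphism search with the identical label predicate.

The canonical key is `<definition name>|<canonical SMARTS>`.  Keys of
different definitions never compare equal, and explicit comparison of
envs from different definitions is rejected — a score always uses one
definition for both sides.

## SMARTS dialect

Atoms are written `[#8]`, charges as `&-`/`&+`/`&-2`…, equivalence
classes as alternations in atomic-number-descending order (`[#6,#1]`),
arrow digits as atom maps `:ED`, bonds as explicit `-`, `=`, `#`, `:`;
fragments joined with `.`; rings closed with numeric labels.  Zero
charges are omitted.  The rendering walk is canonical: fragments are
sorted lexicographically; within a fragment the start atom prefers
unmapped atoms, then higher element symbol, then canonical rank, and
neighbours are visited in symbol-descending order with the last one
continuing the main chain.  ASCII hyphen-minus is always emitted;
typeset reproductions of such patterns sometimes use Unicode hyphens,
so comparisons against printed text should normalize the codepoint.
A restricted parser inverts the dialect (round trips preserve the
canonical key); it is not a general SMARTS matcher.

## Step graphs and similarity

Arrow B *follows* arrow A iff B's tail-touched atoms intersect A's
tip-touched atoms.  Nodes of a step graph are the distinct env keys,
edges the follows pairs over arrow instances (self-pairs of one
instance excluded; an edge between two instances sharing a key is kept
as a loop; instance multiplicity is recorded but ignored by scores —
set semantics throughout).  *Chains* are exactly the edges.

Unordered similarity is the Jaccard index of env-key sets; ordered
similarity averages the env Jaccard and the chain Jaccard.  Mechanism
level pools envs and chains across steps with no step alignment.  The
Jaccard of two empty sets is defined as 1, which is forced by
reflexivity: a mechanism must score 1 against itself even when no
arrow follows another.  Step-level ordered scores use the same formula
on a single step's sets and are provided as a convenience extension.
Display rounding is half-up to integer percent (5/12 → 42%); raw
fractions are kept everywhere in machine output.

## Fixtures

The glycosidase fixture pair encodes the classical retaining
double-displacement chemistry.  Step 1 (shared by both mechanisms):
the aspartate carboxylate attacks the anomeric carbon, the glycosidic
C–O bond swings onto the glutamate's acidic proton, and the glutamate
O–H bond collapses onto its oxygen.  Drawing the proton transfer this
way (rather than as a lone-pair attack of the leaving oxygen on the
proton) is what makes the three arrows a linear 2-edge chain: the
alternative drawing would also make the cleavage arrow follow the
proton-transfer arrow, creating a third edge.  Step 2 mirrors step 1
with the incoming nucleophile being water (alpha-amylase) or a sugar
hydroxyl (endo-xyloglucan transferase); the acceptor-glucan hydroxyl
was chosen as the attacking group, a choice the diagrams leave open.
Construction self-checks the two-away cardinalities — 6 and 6 envs
with intersection 4, 4 and 4 chains with intersection 2, identical
first steps — and fails loudly on drift, so the worked-example scores
(50% unordered, 42% ordered) are pinned by the fixtures themselves.
Fixtures ship both as constructors and as JSON package data; a test
asserts byte-for-byte agreement.

## Synthetic generator

`GeneratorConfig` defaults describe a plausible curated-corpus regime:
2–6 steps per mechanism, 3–9 arrows per step, active-site states of
14–26 atoms in 1–3 species, heavy atoms drawn from C/O/N/S/P
(weights 0.40/0.28/0.18/0.07/0.07) with ~35% explicit hydrogens as
leaves, formal charges on ~8% of heteroatoms, half of arrow sources
being bonds, sinks split between atoms, bonds and incipient bonds.
Species are random trees with occasional ring closures and double
bonds.  Everything derives from one `random.Random(seed)`, so equal
seeds give byte-identical JSON.

The generator emulates the *structural* statistics a mechanism corpus
exposes to this method — graph sizes, arrow connectivity, label
diversity — not chemical realism: no valence model, no thermodynamics,
no meaningful reaction chemistry.  Passing property tests on synthetic
corpora therefore demonstrates the algorithmic guarantees (canonical
keys, coarsening, symmetry, round trips), not that real curated
diagrams are encoded faithfully; the hand-built fixtures carry that
burden for one worked example.

`mutate_mechanism` applies seeded element swaps and charge edits on
non-centre atoms plus occasional arrow-sink rewires; edits are drawn
as a single sequence so larger edit counts extend smaller ones, which
makes the expected similarity to the original decay monotonically with
the edit count (asserted over 50 seeds per level).

## Numerical and interface choices

* Violations are collected, not raised, by `validate_mechanism`; I/O
  entry points raise a single error carrying the full list.
* An incipient sink over an already-bonded pair is flagged invalid —
  electron flow into an existing bond is the `bond` sink kind.
* JSON writing sorts atoms by id, bonds by pair and keys
  alphabetically; round trips are the identity on this canonical form.
* The MRV reader accepts a documented subset (element/charge atoms,
  order 1/2/3/A bonds, `MEFlow` arrows with atom/bond set points,
  `electronCount` defaulting to 2); everything else is ignored with a
  logged warning, and out-of-subset constructs raise named errors.
* EC agreement is at subsubclass level (first three numbers, all
  numeric; wildcards there mean "unannotated").  CATH agreement
  compares *sets* of catalytic-domain superfamilies: equal sets are
  "same", disjoint sets "different", and partial overlap is its own
  category, never folded into either.
* Test and acceptance problem sizes (corpora of 6–50 mechanisms, 200
  oracle pairs, 50 mutation seeds) were chosen so the whole suite
  completes in well under a minute while still exercising thousands of
  canonicalizations.

## Known limitations

* Alternative drawings of the same electron flow (e.g. around an
  aromatic ring) canonicalize to different envs; no resymbolization is
  attempted.
* Non-covalent interactions and 3D residue placement are outside the
  model.
* The SMARTS dialect is a serialization, not a query language; no
  substructure matching against arbitrary molecules.
* Corpus-wide census numbers depend on the external database release
  and are not reproduced here; the pipeline supports such a run via
  the CLI once mechanisms are exported to the JSON format.
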