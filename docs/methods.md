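# Methods

## Atom provenance and the retained-hydrogen rule

A route is the ancestor DAG of one terminal product within a document's
reaction network (molecules deduplicated by canonical SMILES, self-loops
dropped, cycles broken by discarding the latest record).  Provenance is
propagated from the target backwards: a reactant atom is *core* when its
map number corresponds to a core product atom; everything else —
unmapped reactant atoms and atoms feeding leaving positions — is
*leaving*.  Occurrences of one molecule in different records are aligned
through canonical atom ranks; for symmetric molecules any automorphism
is acceptable because the abstracted results coincide.

Hydrogens need care: a protecting group temporarily removes an H that a
later step reinstalls, so comparing an intermediate only against the
target would miss the loss.  Each core atom therefore carries a
*retained hydrogen count* `core_h = min(H_here, core_h_downstream)`,
the number of its hydrogens that survive every later step.  The excess
`H − core_h` counts as a leaving attachment.  Under this rule a
protection step (phenol → silyl ether, amine → carbamate) abstracts to
an identity and is removed, while the matching deprotection survives as
a cleavage-type higher-level step — the behavior expected from curated
higher-level routes.

## Markers

Each maximal connected leaving substructure contributes, per core
attachment bond, a marker classed by `classify_marker`:

| class | token | condition |
|---|---|---|
| 1 | HET | core atom is not carbon |
| 2 | C(+) | EN(leaving) − EN(C) > 0.1 |
| 3 | C(−) | EN(leaving) − EN(C) < −0.1 |
| 4 | C(0) | otherwise |

Pauling electronegativities; the ±0.1 band and the table are
configurable.  Hydrogen (EN 2.20) classifies as C(−) on carbon cores and
HET on heteroatom cores.  Markers are attachment-point pseudo-atoms
whose isotope encodes class and multiplicity (`class` for multiplicity
1, `10·m + class` otherwise); multiplicity accumulates attachment *bond
orders*, so a doubly bonded leaving oxygen (ketone-derived electrophile)
equals two singly bonded leaving alkoxides (acetal-derived) — the
acetal/ketone consolidation that makes C(+) electrophiles
interchangeable.  Core atoms that lost a neighbor or hydrogen have their
hydrogen count pinned explicitly; pins that agree with RDKit's implicit
value are normalized away so abstracted molecules and template outputs
serialize identically.  The C(0) class stands in for nonpolar couplings
(homolytic/cycloaddition-type chemistry) without further subdivision;
this is a deliberate simplification.

Stereocenters whose descriptor references a removed neighbor lose the
descriptor with a logged warning; core stereocenters are untouched.

## Templates

Extraction compares each mapped product atom with its reactant
counterpart (mapped-neighbor multiset, unmapped attachments, hydrogen
count, charge).  The changed atoms plus `radius` bonds of context (one
by default) form the product pattern; atoms multiply bonded to the core
are always completed (a carbonyl oxygen or alkyne partner is part of the
center's identity), and markers riding on selected atoms appear on both
sides.  Patterns are emitted in a SMARTS dialect with exact hydrogen
counts and charges; map numbers are renumbered from the fragment's
canonical output order so identical templates from different precedents
deduplicate by string.

Consolidation extracts, for every unique reactant–product pair, the
radius-1 template and its radius-0 generalization, applies the whole
pool to every product, and assigns each reaction the *most general
recovering* template — widest coverage over the training reactions,
ties broken by fewer pattern atoms, then lexicographic SMARTS.  The
round-trip property (assigned template regenerates the recorded
reactants) is enforced by tests at 100% on the synthetic corpus and is
the behavioral pin for the whole template layer.

## Relevance model

Products are featurized as 2048-bit radius-2 Morgan count fingerprints
with custom atom invariants (element, isotope, charge, degree, H count,
aromaticity, ring membership); the isotope term makes marker classes
distinct environments.  The classifier is a single-hidden-layer
feedforward network (512 ReLU units, softmax, Adam, early stopping on an
internal validation split for ≥500 training samples; both sizes
configurable).  Splits are 80/10/10 over unique pairs, seeded.

Pessimistic top-k: proposals are enumerated template-by-template in
descending score (ties by template id), each applicable template
contributing its distinct precursor sets; the recorded set counts as
found at the *last* position of its template's block.  The optimistic
variant uses the actual position.  Pessimistic ≤ optimistic holds by
construction, with equality whenever every block has size one.

## Planner

Monte Carlo tree search over a chemical/reaction bipartite graph with
graph-wide deduplication by canonical SMILES.  Selection walks from the
root by PUCT score `value + c · prior · √N_parent/(1 + N)` (c = 1.4,
prior = model probability, value = fraction of a node's expansions
resolved to buyables) until it reaches an unexpanded, nonterminal node;
expansion applies the top-`expansion_width` templates (default 25);
update backpropagates visit counts, rewards, and solved flags.  A
precursor equal to a path ancestor is pruned.  Every iteration expands
exactly one node, so given enough iterations the search enumerates the
reachable space within `max_depth` — route-finding completeness does not
depend on the value function, which only orders the exploration.

Termination: exact mode requires the canonical string in the catalog.
Substructure mode embeds the bare core graph in a candidate buyable
(pattern-fingerprint prescreen, then all embeddings including
automorphic ones) and accepts an embedding when every core atom's extra
attachments exactly account for its markers: each extra substituent's
attachment atom must satisfy the marker's electronegativity class, and
implicit hydrogens may stand in for HET markers on heteroatom cores
only.  Marker-free molecules always require an exact hit.  At most ten
matches are reported per terminal, smallest buyables first; feasibility
ranking of the matches is out of scope.

## Synthetic corpus

The generator emulates the statistical structure of a patent corpus:
each document is one multistep route to an assembled target.  Targets
are built from aryl/amine/alkyl fragment pools by scaffold joins
(sulfonamide, amide, ester, benzyl ether, N-benzylation, thioether,
alkynylation, vinylation, C–N aryl amination, biaryl coupling), each
family at most once per route; the recorded route is then derived by a
fixed decomposition priority over the assembled features, so a given
product always decomposes the same way and the recorded precursors are a
deterministic function of structure.  Detours are planted with
probability `p_tactical` (default 0.3): a triflation FGI in front of a
C–C coupling, an acid → acyl chloride FGI, or a silyl
protection/deprotection pair on a phenol; each adds exactly one tactical
step.  Leaving-group choices (Br/Cl, acid/acyl chloride) vary randomly
across documents so the concrete space contains the variant families the
abstraction is supposed to collapse.  Atom maps and ground truth
(leaving sets, retained hydrogens, tactical flags, route statistics,
distinct-strategy counts) are constructed together with the molecules
via persistent atom ids, not inferred afterwards.

The buyables builder returns either the true starting materials or an
adversarial stock in which every leaf is replaced by a functional-group
variant of the same abstracted form that never occurs in the recorded
corpus (Br→I, B(OH)₂→Bpin, acid→methyl ester, amine→Boc-amine,
phenol→triisopropylsilyl ether, ...).  Exact-match planning cannot
terminate in the adversarial stock; marker-aware substructure matching
can, which is the mechanism the higher-level planner relies on.

What the corpus does *not* emulate: reagent/condition diversity and
mapping noise (maps are exact by construction), failed or low-yield
reactions, stereochemistry, duplicate routes per document, and the
scale and long-tail template distribution of real patent corpora.
Passing tests therefore demonstrate correctness of the curation,
consolidation, evaluation, and search machinery under clean conditions,
not performance on real extraction noise.

A note on the model-recovery conditions: the pessimistic convention
charges the whole precursor block of a template, and a symmetric biaryl
retro-template necessarily proposes both polarity orientations of the
disconnection, so biaryl-terminated products cap pessimistic top-1 at
rank 2 regardless of model quality.  The model-recovery experiments
therefore run on the ten orientation-unambiguous families (the nine
other scaffold joins plus deprotection); biaryl coupling remains in the
default corpus and is exercised by the abstraction, consolidation, and
planner experiments.

## Sizes and numerical choices

Experiments are sized to run on one CPU in minutes: provenance recovery
on 110 single-route documents; model recovery on a 700-document
ten-family corpus (≈2,100 unique pairs, 80/10/10 split); planning on 40
documents with 12 query targets, expansion width 50, and iteration caps
of 400 (1,500 for exact mode, whose concrete space is wider).  All
randomness flows through explicit seeds: the corpus generator uses one
`random.Random` per document derived from the spec seed, dataset splits
use a seeded NumPy RNG, and network initialization uses scikit-learn's
`random_state`; reruns with one seed reproduce curation outputs
bit-for-bit and training metrics exactly on one machine.  Degenerate
inputs are handled explicitly: multi-product records keep the largest
product, spectator reagents (fully leaving reactants) are dropped with a
signal, routes whose provenance chain is broken are excluded and logged,
and template applications that fail sanitization are skipped.
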