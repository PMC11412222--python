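# Methods

## Model and procedure

The package implements constrained fossil placement by parsimony.  Inputs
are (a) a discrete morphological character matrix containing all extant taxa
plus one fossil, (b) an unrooted backbone tree over exactly the extant taxa,
and (c) a concavity constant `k`.  The extant relationships are treated as
known (in practice they come from molecular phylogenies) and are never
re-estimated; the only free parameter of the topology search is the
attachment branch of the fossil.  Every branch of the unrooted backbone is
enumerated (`2n−3` for a binary backbone with `n` tips; polytomies simply
have fewer branches), the fossil is grafted onto each in turn by bisecting
the branch with a new degree-3 node, and each augmented topology is scored.

### Scoring

Per character, the observed parsimony length `s` is computed by a
uniform-cost dynamic program over states: `cost[v][σ]` is the minimal number
of changes in the subtree at `v` given state `σ` at `v`, with a child
contributing `min(cost_child[σ], min_τ cost_child[τ] + 1)`.  This is the
exact generalization of the Fitch algorithm to multifurcations and to
set-valued tips, and is vectorized across characters with numpy (one
`(n_states × n_chars)` array per node, single postorder pass).  Scores are
defined on the unrooted topology; the rooted representation used internally
is arbitrary and root-invariance is property-tested.

The per-character minimum `m` (fewest changes on *any* topology) is the size
of a minimum hitting set of the observed state sets minus one: every tip
must be assignable a state from its set, grouping taxa by state costs one
change per additional state, and a polymorphic cell satisfied by an
already-needed state demands nothing.  The hitting set is found by
exhaustive subset search over the (small) observed alphabet.  Extra steps
`e = s − m` give the implied-weights penalty `f = e/(e+k)`; the tree score
is `Σ f`, minimized.  The functional form is the standard concave fit of
implied-weights parsimony; the alternative of ranking by raw length
(equal-weights, the `k → ∞` limit) is exposed as `score_kind="raw_length"`.

Cell-kind conventions: missing `?` and inapplicable `−` both enter the
dynamic program as full ambiguity, while remaining distinct in the data
model, in round-trips and in codability counts.  Scoring inapplicable cells
with a dedicated inapplicable-state algorithm is a known refinement that
this package deliberately omits; with `−` treated as missing, characters
containing inapplicable cells are scored slightly optimistically.
Characters with fewer than two observed taxa on the tree being scored carry
no signal and score `s = m = e = 0` rather than erroring, since
fossil-heavy matrices routinely contain them.

### Ranking and ties

The fits are floating-point, so ties are declared within a relative
tolerance (`1e-9` by default; relative to the larger magnitude, with an
absolute floor of the same size near zero).  Ranks are competition ranks —
all members of a tie share the rank of their best member — and the
`argmax_set` lists every branch tied for the optimum.  Order within equal
scores is fixed by a deterministic edge key (side size, then sorted labels),
so reruns produce byte-identical tables.  Branches are addressed throughout
by the bipartition of tip labels they induce, canonicalized to the side not
containing the lexicographically smallest label; bipartitions are stable
under re-rooting, pruning, and re-parsing, where internal node ids are not.
For a rooted binary input the two root-adjacent edges describe the same
unrooted branch and are collapsed onto one attachment point.

An optional clade restriction filters the ranking to branches lying within
(or subtending) a named set of tips, for reading the score map with
cross-clade attachments excluded.

## Synthetic data generator

The generator emulates the statistical structure of such a study, not any
particular organism:

* **Trees** — Yule (pure-birth) topologies with exponential branch
  durations, via dendropy's birth–death sampler at birth rate 1.
* **Characters** — independent symmetric Mk characters: uniform root state,
  substitution events along each branch with exponential waiting times
  (event count per branch is Poisson with mean `rate × length`), each event
  jumping uniformly to one of the other states.  Unordered states match the
  scoring model.
* **Fossilization** — each observed cell of the chosen taxon independently
  becomes `?` with probability `missing_fraction` and `−` with
  `inapplicable_fraction`; other rows are never touched.
* **Recovery experiments** — per replicate: simulate, choose a tip as the
  fossil, record its true attachment branch as the bipartition of extant
  taxa it induces, prune it to form the backbone, degrade its row, place,
  and test membership of the true branch in the argmax set (`recovered_tie`)
  or its unique optimality (`recovered_strict`).

Defaults are frozen at: 15 tips, 200 binary characters, `rate = 0.1`,
`missing_fraction = 0.5`, `k = 12`.  The rate is calibrated so the true
tree's ensemble consistency index lands near 0.6–0.7 with roughly three
quarters of characters variable, the homoplasy regime empirical
morphological matrices of comparable size occupy; the default missingness
mirrors a fossil codable for about half a matrix, as is typical of amber
material.  `k = 12` follows standard practice for implied-weights analyses
of morphological data.

What the generator does **not** emulate: rate heterogeneity and correlation
among characters, ascertainment ("only variable characters scored") bias,
ordered or hierarchically inapplicable characters, and non-random
missingness (real fossil gaps are anatomically clustered, not i.i.d.).
Passing recovery tests therefore demonstrate that the machinery is correct
and well-behaved under the model's assumptions, not that any particular
empirical placement is right.

## Measured behaviour

Under the default conditions with a *complete* fossil row, the true branch
is in the best-scoring set in roughly 85–90% of replicates (200-replicate
runs; see `scripts/acceptance.py` output).  The misses are genuine parsimony
behaviour, not numerical error: cross-checks against an independent
exhaustive implementation confirm the "wrong" branch scores strictly better
in those replicates, typically an adjacent branch separated from the truth
by a near-zero-length internode.  Recovery degrades gently to ~50% missing
data and the argmax set widens sharply by 90% missing — the quantitative
version of the qualitative caution above, that a largely incomplete fossil
spreads its signal over several neighbouring branches.

## Numerical and interface choices

* Scores are exact integer dynamic programs until the final division; the
  only floating-point is the fit itself.  TSV output prints fits at 10
  significant digits; tree annotations round to 2 decimals (figure-style);
  the TSV is the machine-readable artifact.
* NEXUS parsing (interleaved or flat, `{..}`/`(..)` polymorphism groups)
  goes through dendropy; a bare whitespace-delimited dialect is accepted as
  a fallback.  Malformations raise typed errors (dimension mismatch,
  duplicate taxon, unknown symbol).  Writing always emits flat NEXUS.
* Taxon labels are matched between matrix and tree after stripping
  surrounding quotes and mapping underscores to spaces, the usual
  NEXUS/Newick disagreement.
* Branch lengths in input trees are parsed and ignored: scoring is
  topology-only.
* Branch annotations are written either into the Newick label slot
  (internal branches; terminal branches use a `[&score=...]` comment, since
  their label slot is the taxon name) or uniformly as comment tags; both
  forms re-parse losslessly.
* All generators take explicit integer seeds and are reproducible
  bit-for-bit; experiment drivers derive per-replicate seeds from a single
  seed via numpy `SeedSequence`.
* Problem sizes in the shipped experiments (15 taxa × 200 characters × 200
  replicates) keep a full recovery sweep in the minutes range on one core
  while giving ~±3.5% Monte-Carlo standard error on recovery rates.

## Known limitations

* Single fossil per run; simultaneous placement of multiple fossils (which
  can interact) is out of scope.
* No specialized inapplicable-state scoring (see above).
* No character ordering, step matrices, or weights other than the implied
  concave fit.
* The placement enumeration rescopes the full dynamic program per branch
  (`O(edges × nodes × states × chars)`); an incremental two-pass scheme
  would be faster on large backbones but the exhaustive form is transparent
  and fast enough at the intended scale.
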