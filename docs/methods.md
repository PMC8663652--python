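# Methods

## Scope and model

morphoclad analyses rectangular taxa × characters matrices of discrete
morphological states (0–9, `?` unknown) under the maximum-parsimony
criterion. Trees are unrooted topologies without branch lengths; identity
is canonical (two trees are equal iff their bipartition sets are equal),
so child order and internal node numbering never matter. Rooting on an
outgroup is a view used for clade language, Newick output and character
mapping; for unordered and ordered characters the tree length is
rooting-invariant, and the test suite checks this.

Per-character optimization modes:

* **unordered** — Fitch optimization via post-order set
  intersection/union on bitmask state sets; a `?` tip contributes the full
  alphabet at no cost.
* **ordered** (Wagner/additive) — Farris interval method: each node
  carries a closed state interval, disjoint child intervals cost their gap
  in steps; `?` contributes the full 0–9 interval. This is the mode the
  bundled dataset uses throughout, matching its coding convention of
  successively derived states (0 → 1 → 2).
* **irreversible** — dynamic program over states with transitions
  permitted only from lower to higher, the ancestral state fixed by the
  root of the evaluation. A column that cannot be realized (a tip below
  the root state) scores the sentinel `INFEASIBLE` (`math.inf`) rather
  than raising.

Ensemble indices are Ci = Σm/Σs and Ri = (Σg−Σs)/(Σg−Σm) over all active
characters, uninformative ones included (an `informative-only` variant
would change the sums; the inclusive form is what the bundled analysis
reports). Display rounding is half-up to two decimals; full precision is
always retained alongside.

### Why the bundled dataset is all-ordered

The bundled matrix has four three-state characters (6, 7, 39, 40). With
all characters ordered, the matrix yields Σm = 45, Σg = 83, two MPTs at
length 59, Ci = 45/59 ≈ 0.76 and Ri = 24/38 ≈ 0.63, and the bootstrap
pattern reported for it. Treating the multistate characters as unordered
instead gives Σg = 80, Ri = 0.60 and nine MPTs — a measurably different
analysis. The ordered reading also matches the dataset's own coding
philosophy (oligomerization: states are successive losses/fusions), so
`load_bicorniphontodes()` marks every character ordered.

## Search

* **Exhaustive** — every unrooted binary topology, generated by
  sequential edge insertion ((2n−5)!! trees), is scored; feasible to 9
  taxa by default. Scoring is vectorized: each topology rooted at leaf 0
  reduces to a fixed schedule of n−2 pairwise merges, and all topologies ×
  all characters are scored with a handful of numpy operations per merge
  step. The scalar implementations are the reference; tests assert the
  two routes agree.
* **Branch and bound** — stepwise taxon addition in input order with
  pruning on the partial length (inserting a taxon never shortens a
  tree); exact, returns the identical tie set.
* **Parsimony ratchet** — random-addition starts followed by alternating
  TBR hill-climbs on the original matrix and on a perturbed matrix in
  which a random character sample has doubled weight. The
  `random_constraint_level` knob is interpreted as the number of
  random-addition starts (its original meaning in the program that coined
  it is undocumented). First-descent climbing with deterministic
  tie-breaks and a seeded generator makes runs bit-reproducible.

## Bootstrap support

Each replicate resamples the characters with replacement and searches for
that replicate's MPTs; a clade is credited when it appears in the
replicate's strict consensus (conservative; `count_in_any_mpt=True`
relaxes this). Because parsimony length is additive over characters,
resampling only reweights the per-topology per-character step matrix, so
for matrices small enough for exact search the enumeration is scored once
and each replicate reduces to one matrix product — exactly equivalent to
exhaustive search per replicate, which is why 500 replicates on the
bundled matrix take well under a second. Larger matrices fall back to
per-replicate TBR searches with a configurable number of restarts and
held trees. Under outgroup rooting the full ingroup clade is present in
every replicate by construction and is reported at 100%; the
uninformative all-taxa "clade" is never reported.

The two sub-50% basal alternatives of the bundled analysis (clarae-basal
vs bicornis-basal) have true bootstrap frequencies only ~4 points apart
(~34% vs ~30%); their qualitative order is therefore not reliably
resolvable at 500 replicates, and the test that asserts the order uses
5000.

## Unambiguous change mapping

Character changes are mapped on the tree rooted by a degree-2 root node
on the outgroup's pendant edge. A Sankoff down-pass (unit costs for
unordered, |Δstate| for ordered) is followed by a top-down reachability
pass that computes, per branch, the set of (parent, child) state pairs
realizable in at least one most-parsimonious reconstruction. A change is
reported only when every realizable pair on the branch is the same
changing pair — present in all MPRs with fixed from/to states.

The root node's state is not fixed by the outgroup: the outgroup's
observed state enters as data, so derived reversals toward state 0 are
recoverable (the bundled Korean-clade synapomorphies are of this kind).
When the root state itself is tied among MPRs, the tie is resolved toward
the lowest state — the presumed plesiomorphic condition of the 0-based
coding. This single convention is what keeps a state found only in the
outgroup an outgroup autapomorphy instead of an apparent loss on the
ingroup stem, while leaving genuinely polarized stem changes unambiguous.

Classification: a character with per-tree ci = 1 yields synapomorphies on
internal branches and autapomorphies on pendant branches; ci < 1 flags
all of its changes homoplastic (the open-square convention of cladogram
plots). Records are keyed by the clade's leaf set, so change lists can be
intersected across MPTs that differ elsewhere in topology.

## Synthetic data

`simulate_yule_tree` draws uniformly from the (2n−5)!! topologies by
uniform sequential edge attachment. `simulate_characters` evolves each
character independently down the tree from the internal node adjacent to
the first taxon, root state 0: the number of change events is
Poisson(rate) — `rate` is the expected number of changes per character on
the whole tree, the quantity that governs parsimony behavior — events are
placed uniformly on branches, and an event either jumps to a uniformly
chosen different state (`mk_unordered`) or increments the state up to the
top (`irreversible_gain`, silent at the top state). A configurable
fraction of entries is then masked to `?` (never a whole column). The
latent tip states, and optionally the full internal history, are returned
so generative properties (e.g. monotone state gain under irreversibility)
are directly testable.

What the generator emulates: matrices of the bundled dataset's kind —
small taxon sets, binary/three-state characters, a plesiomorphic root,
tunable homoplasy and missing data. What it does not: branch-length
heterogeneity, correlated characters, or ascertainment toward variable
characters; conclusions from passing tests transfer to real data only to
that extent.

A note on topology recovery: with 41 characters on 7 taxa at rate 1.0,
the generating topology lies inside the exact MPT set in roughly two
thirds of replicates (about 83% under binary irreversible gain). The
dispersion of Poisson change counts is the limiting factor — a character
hit twice can support a spurious two-taxon group that saves a step and is
often unopposed at this character count — so near-certain recovery would
require either many more characters or a homoplasy-free (exactly one
change per character) generator, which would contradict the generator's
purpose of producing tunable homoplasy. The recovery experiment in the
acceptance suite documents this measured rate.

## Numerical and design choices

* States are capped at 0–9 (`?` = −1 internally); matrices are validated
  on construction (rectangularity, unique non-empty taxon names, no fully
  missing column) and immutable afterwards.
* Polymorphic NEXUS/TNT cells are rejected with a clear error rather than
  silently coerced.
* MPT sets are ordered canonically (by Newick string of the
  smallest-label rooting) so results are deterministic regardless of
  search order; all stochastic components take explicit integer seeds.
* `min_steps`/`max_steps` use the observed-state count (unordered) or the
  observed range and the best-center star length (ordered).
* Strict consensus is computed as the intersection of bipartition sets
  and rebuilt from the laminar cluster family; it is associative and
  commutative by construction.

## Limitations

No Sankoff step matrices, implied weighting, polymorphic-state scoring,
Bremer support, or likelihood/Bayesian scoring. Exact search is capped
near 9 taxa; the ratchet is the intended tool beyond that but its
neighborhood scan is pure Python and suited to tens, not hundreds, of
taxa. The irreversible mode is evaluated on a fixed rooting and is not
used by the bundled analysis (whose printed statistics correspond to
ordered optimization).
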