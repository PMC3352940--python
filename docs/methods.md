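# Methods

## Scope and model

`morphpars` implements unweighted maximum parsimony for discrete
morphological characters. A character is a column of *state sets*: a
singleton for an ordinary observation, a multi-member set for
polymorphism or partial uncertainty, and two markers — missing (`?`) and
inapplicable (`-`). Both markers are scored as full ambiguity by default,
matching the usual default of parsimony software for morphology; a
`gap_as_state` switch instead treats `-` as a dedicated extra state.
Polymorphic cells are treated as uncertainty sets for length computation
(any member state may be assigned to the terminal); programs that charge
extra steps for true within-terminal polymorphism will report longer
trees on matrices with such cells.

Character indices are 1-based in all I/O and reports, following the
convention of published character lists; internal indexing never leaks.

## Scoring

Unordered (non-additive) characters are scored with Hartigan's
minimum-mutation algorithm, which equals Fitch optimization on binary
trees and remains exact on polytomies — consensus trees are therefore
scored directly. Ordered (additive) characters use the Sankoff dynamic
program with Manhattan step costs; the general cost-matrix entry point
(`sankoff_length`) is public, and the Fitch = Sankoff(uniform-costs)
identity is exercised as a standing cross-check rather than collapsed
into one code path. Scoring is vectorized across characters with numpy
boolean state-membership arrays, and a `Scorer` caches the matrix
encoding so tree search can rescore thousands of candidate topologies
cheaply.

Per-character step bounds:

- minimum *m*: for unordered characters, (size of the smallest state set
  hitting every scored cell) − 1 — a minimum hitting set over the
  observed states, exact because state counts are small (≤ 5 in
  practice); for ordered characters, the width of the narrowest state
  window meeting every cell.
- maximum *g*: the star-tree length. Collapsing an edge only restricts
  the internal assignments, so the fully unresolved tree maximizes the
  parsimony length for any cost structure; for unordered characters this
  gives (scored cells) − (best modal-state frequency), with ambiguous
  cells resolved to inflate the modal state. Cells that are missing or
  fully ambiguous are excluded from both bounds.

Ensemble indices sum m, s, g over **all** characters, including
parsimony-uninformative ones; this is the convention under which the
printed CI and HI of the source analysis sum exactly to 1
(`include_uninformative=False` is available for comparison with programs
that drop uninformative characters).

## Tree search

Random addition sequences build a starting tree by stepwise insertion at
the edge of minimum incremental length (ties to the first edge in
canonical enumeration order), followed by branch swapping: TBR by
default, with SPR and NNI as strict subsets used for speed tiers and for
the neighborhood-inclusion test. Swapping is breadth-first over the
equal-length neighborhood with a visited set keyed on canonical
bipartition sets; any strictly better tree restarts the sweep, and all
equal-best trees are retained (subject to `maxtrees`, which flags
truncation instead of raising). Per-replicate seeds are spawned from the
master seed with numpy's `SeedSequence`, so a run is reproducible from
one integer; the replicate log records start and final lengths, and
islands are counted by merging replicate pools that share a tree.

Exhaustive enumeration over all (2n−5)!! unrooted binary topologies
(default cap 9 taxa) provides the exact optimum for oracle comparisons.

**Collapse rule.** Counting most-parsimonious trees requires a
convention for unsupported branches. The default collapses internal
branches whose minimum optimized length is zero, testing an edge by
contracting it and rescoring (equality of lengths means some
minimum-change reconstruction puts no change on the edge). Branches are
contracted one at a time with the collapsible set recomputed, because two
individually unsupported branches need not be jointly unsupported; each
contraction therefore preserves the tree length exactly, and every
retained tree — collapsed or not — rescores to the best length.
`collapse="never"` keeps the binary trees. Published MPT counts depend on
the (usually unstated) convention of the software used, so counts are
reported but tree lengths and consensus topology are the primary
outputs.

## Clade support

The Bremer decay index of a clade is computed by a converse-constraint
heuristic: the same replicate/seed policy as the main search, but any
addition or swap product containing the constrained bipartition is
rejected (a starting tree that contains it is first broken by the
cheapest NNI across its stem). The exact alternative enumerates all
topologies and bins them by clade presence; on every instance small
enough to enumerate, the two routes agree in the test suite. Clades
present in the strict consensus necessarily have decay ≥ 1.

## Ancestral states

ACCTRAN and DELTRAN are computed on the Sankoff cost-vector DP, so the
change count per character always equals that character's parsimony
length. The modes differ only in preorder tie-breaking among equally
parsimonious child states: DELTRAN keeps the parent's state whenever it
remains optimal (changes delayed tipward, parallelisms favored); ACCTRAN
switches away from the parent's state as soon as doing so is cost-free
(changes accelerated rootward, reversals favored). Residual ties go to
the lowest state label, and the root takes the lowest-labeled
minimum-cost state, which makes both reconstructions deterministic and
invariant to child order. Rooting uses a configured outgroup (default:
the first matrix taxon, since the source analysis does not name its
outgroup in the body text).

## Tail-evolution scenario

The packaged comparative table transcribes the published caudal data:
caudal count NC, last transverse-process caudal TP, first elongated
centrum E, first caudotheca-contributing caudal PZ, first contacted
caudal C, 2× elongation, and transition-point presence. Tokens may be
exact, ranges, lower bounds, or carry estimated extras; all become
closed integer intervals. Encoding produces seven characters:
caudotheca (absent / caudotheca / hemicaudotheca), transition point
(none / type 1 / type 2), 2× elongation, and binned NC (≤24 / 25–30 /
>30), TP (≤6 / 7–10 / ≥11), PZ (≤6 / ≥7) and C (≤4 / ≥5). Binning uses
interval containment: an interval straddling bin edges becomes an
ambiguity set over the bins it touches (or a missing cell when it
touches all), never a point guess. The NC bin edges are a documented
choice sized to express the early caudal-count decrease and the later
eudromaeosaurian increase; TP/PZ/C edges follow the cutoffs stated for
the microraptorian and eudromaeosaurian patterns.

Hemicaudotheca bearers (*Utahraptor*, *Achillobator*) have no rows in
the comparative table; they are injected from a separate side table to
keep the transcription and the supplementary assignment distinct.

The mapping tree is a reference topology assembled from the study's
*textual* topology statements (the synapomorphy table's clade ladder,
the four successive caudothecate sister groups of the hemicaudothecate
clade, and the placement discussion), restricted to taxa with caudal
data; within-group relationships the text does not resolve are left as
polytomies, which the Hartigan scorer handles exactly. The published
figure-only tree and its decay numbers are not machine-readable from the
article text, so they are not claimed as inputs.

Specimen classification: microraptorian pattern requires TP ≤ 6, PZ ≤ 6
and C ∈ {3, 4} (all intervals entirely within bounds); eudromaeosaurian
pattern requires PZ ≥ 7 and C ≥ 6. Transverse-process extent is not
decisive for the eudromaeosaurian pattern because known eudromaeosaurian
tails carry distinct processes to caudal 11, and the sheath of the most
basal eudromaeosaur begins at caudal 9 — the PZ/C cutoffs are what
separate the two syndromes in the data. Anything else, including
intervals straddling a rule boundary, is `indeterminate`.

The caudotheca position bound is arithmetic on the preserved series: with
*p* missing proximal caudals and the first surrounded vertebra at 1-based
position *k* of the preserved series, the sheath extends no farther
forward than caudal *p + k* and its first contributing vertebra lies no
farther cranial than *p + k + 1*. The isolated proximal caudal of the
new specimen is excluded from the count, which refers to missing caudals
bearing transverse processes (the isolated element lacks them).

## Synthetic data

The generator emulates a fossil-grade morphological matrix: per-character
state counts drawn from a mostly-binary mixture (2 states with
probability 0.65, 3 with 0.20, 4 with 0.10, 5 with 0.05), a symmetric
change process (on each branch a character jumps to a uniformly chosen
different state with probability `change_rate`, default 0.12), uniform
background missingness (default 0.25) plus concentrated missingness
(default 0.8) on designated fragmentary taxa, and occasional polymorphic
cells (default 0.01). Defaults are sized to the regime the reanalysis
works in — a few hundred mostly-binary characters with substantial
homoplasy and fragmentary fossil terminals. The generating tree, true
per-character change counts, and degradation mask are recorded as ground
truth. What the generator does not emulate: correlated characters,
ordered-state asymmetries, coding biases, and non-random missingness
structured by body region; passing recovery tests therefore demonstrate
algorithmic correctness, not robustness of parsimony on real matrices.

Uniform random topologies come from stepwise addition onto a uniformly
chosen edge (exactly uniform over labeled topologies); a Yule-like mode
splits pendant edges instead.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen so the exact oracles
stay feasible: exhaustive comparisons at 5–8 taxa (up to 10 395
topologies), decay enumeration at ≤ 7 taxa, assignment-enumeration
scoring oracles at ≤ 6 taxa, and heuristic searches with 2–5 addition
replicates (the published protocol of 1000 replicates is a config
preset; best lengths on these instance sizes stabilize within a handful
of replicates). All integer arithmetic is exact; the only floating-point
quantities are the ensemble indices, whose algebraic identities
(CI + HI = 1, RC = CI·RI) are asserted to 1e-12.

## Known limitations

- Step-matrix (user-cost) characters are supported by the Sankoff core
  but not exposed in matrix I/O; only unordered and linear-ordered types
  are declared there.
- The maximum-steps bound for ordered characters with ambiguous cells
  resolves ambiguity against the star-tree center before maximizing,
  which can understate *g* in contrived cases; ordered characters are
  rare in the intended matrices and the unordered bound is exact.
- The converse-constraint decay search inherits the usual heuristic
  caveat: on instances too large to enumerate it can overestimate a
  decay index if the constrained search misses the true constrained
  optimum.
- True within-terminal polymorphism is scored as uncertainty (see
  above), so lengths can differ from programs using the
  extra-steps-for-polymorphism convention.
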