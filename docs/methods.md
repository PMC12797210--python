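# Methods

## Indel process

Evolution along a branch of length *t* (expected substitutions per site)
is simulated with a Gillespie scheme. At each step, with current
sequence length *n*:

1. a candidate deletion length *S* is drawn from the deletion length
   distribution (drawn *before* the event type is known, because it
   enters the deletion rate; it is discarded if the event turns out to
   be an insertion);
2. the sequence-wise rates are *R*_ins = (*n*+1)·*r*_ins and
   *R*_del = *r*_del·(*n* + *S* − 1);
3. the waiting time is drawn from Exp(*R*_ins + *R*_del) and added to the
   branch clock; an event whose cumulative time exceeds *t* is discarded
   and the branch ends (standard truncation of a Gillespie run);
4. the event is an insertion with probability *R*_ins/λ. Insertions pick
   one of the *n*+1 slots uniformly and draw a fresh length from the
   insertion length distribution. Deletions reuse the candidate *S* and
   draw their start uniformly from the *n*+*S*−1 positions
   {2−*S*, …, *n*}; the part overhanging either edge is trimmed, so the
   emitted event is always in-range with effective length ≥ 1.

The left-overhang correction in step 4 is what makes the per-position
deletion probability uniform (*S*/(*n*+*S*−1) for every position; exactly
1/*n* when *S* = 1); drawing starts only inside the sequence would bias
deletions away from the sequence start. An empty sequence has deletion
rate zero (there is nothing to delete); insertions can still lengthen it
again.

Default parameters (chosen to sit in the range reported for empirical
protein families): insertion rate 0.03 and deletion rate 0.09 per site
per substitution, indel lengths Zipf with exponent 2.0 truncated at 50
for both insertions and deletions. The truncation bound is inclusive by
default (support 1…M); the configuration also offers an exclusive
reading (support 1…M−1) because both conventions circulate — the Zipf
a = 2.0 mean is 2.77 characters under the inclusive reading and 2.76
under the exclusive one. Separate insertion/deletion length
distributions may be configured; rate heterogeneity across sites and
sequence-context-dependent indel rates are out of scope.

## Coordinates and blocks

Characters of the current sequence are 1-based; a virtual anchor
occupies position 0 so events to the left of the first character have a
home. An insertion event at slot *q* inserts immediately after anchored
element *q* (*q* = 0: before the first character); a deletion starting at
*p* removes anchored elements *p*…*p*+*S*−1 (the anchor itself is never
deletable).

A branch's edits relative to its parent are recorded as an ordered list
of blocks (*start*, *length*, *insertion*): a run of *length* contiguous
undisturbed parent positions (the original part, OP — the anchor is
counted inside the first block, which always starts at 0) followed by
*insertion* characters added on this branch (the added part, AP). A
parent of length n0 starts as the single block (0, n0+1, 0). Locating an
event scans blocks subtracting their totals *T* = *length* + *insertion*
until the residual offset falls inside a block.

Update rules:

- insertion with residual offset *o* strictly inside the OP (before its
  last element): split — the prefix keeps *o*+1 elements and carries the
  new AP, the suffix inherits the old AP;
- insertion at the last OP element or inside the AP: the AP grows (AP
  characters are anonymous on the branch, so their internal order is
  immaterial);
- deletion inside one OP: split with the old AP staying on the suffix;
  deletion reaching the OP end trims the block in place; spanning
  deletions consume block tails and continue rightward, dropping blocks
  whose OP is fully deleted. If such a block still has AP characters
  left, that orphan AP is appended to the AP of the nearest surviving
  block to the left (the anchor block always survives, so one exists).

One subtle convention deserves a note. With the anchor counted in the
first block, a single uniform rule — "the split prefix keeps residual+1
elements in *every* block" — makes the block engines agree exactly with
the naive engine (insert after anchored element *q*, wherever *q*
falls). An alternative arithmetic that keeps only *residual* elements
when the event resolves to a block after the first is seen in worked
material on this data structure; it is *not* consistent with a single
global coordinate convention, and under it the three engines could not
produce identical alignments from one event stream. This package
therefore uses the uniform rule throughout the engines, and exposes
`split_block(block, keep, new_ap)` with an explicit prefix size so
either arithmetic can be expressed directly when reproducing worked
examples.

The block count obeys b ≤ min(k+1, n+1) after every event (each event
adds at most one block; there cannot be more blocks than surviving
parent positions plus the anchor). The list engine costs O(b) per event;
the AVL engine stores the same blocks in an order-statistic tree
augmented with subtree block counts and subtree totals (no explicit
keys — positions shift after every event, cumulative aggregates do not),
giving O(log b) locate and edit. Spanning deletions remove the interior
nodes one by one (O(m log b) for m affected blocks). The naive engine
applies events to an explicit list of position identities at O(n) per
event and serves as the correctness oracle: all three engines are
required to induce the identical canonical branch recipe (maximal
copy/insert runs), identical lengths, and byte-identical alignments.

## True-MSA assembly

A super-sequence — a doubly linked list of every position that ever
existed — is grown during a preorder traversal of the tree. Each node
keeps a pointer sequence (ordered references into the super-sequence).
A child's pointer sequence is built from its branch's blocks: parent
references covered by each OP are copied, then the AP's fresh elements
are spliced into the super-sequence immediately after the last copied
reference and appended. A run inserted before any reference has been
copied goes immediately before the parent's first reference (at the
front of the super-sequence if the parent is empty). Runs anchored at
the same element by different lineages therefore appear in traversal
creation order; the relative order of non-homologous insertions is
biologically arbitrary, and this choice is deterministic and
seed-stable.

After the traversal, elements referenced by at least one emitted row
(leaves by default; ancestors optionally included, with flags computed
over whichever row set is emitted) are flagged; flagged elements become
alignment columns in super-sequence order, so gap-only columns cannot
occur. In template mode cells are the placeholder `N`; gaps are `-`.

## Substitutions

Substitutions are independent of indels, so they are simulated
separately and merged. A reversible rate matrix is built from symmetric
exchangeabilities and stationary frequencies, Q_ij = s_ij·π_j, scaled to
one expected substitution per site per unit time. P(t) = exp(Qt) is
computed by eigendecomposition of the similarity-symmetrized matrix
diag(√π)·Q·diag(1/√π) (numerically symmetric, so `eigh` applies); tiny
negative entries from round-off are clipped and rows renormalized
(deviations are ≤ 1e-12 at realistic branch lengths). A root sequence of
length L — the template alignment width — is drawn i.i.d. from π and
evolved down the tree site-by-site from the parent row of P(t), with
P(t) cached per distinct branch length. Residues are simulated at all L
columns and simply discarded where a row is gapped; simulating only at
ungapped columns would yield the same distribution, but the columnwise
contract keeps the superposition a pure cell-replacement.

Shipped models: the JTT amino-acid replacement matrix (published
exchangeability counts and frequencies, embedded as constants and
cross-checked in the test suite against an independently computed
transition matrix), a one-parameter nucleotide model (uniform rates and
frequencies), and custom amino-acid matrices in PAML rate-file layout.

## Randomness and determinism

One master seed drives everything. Each branch gets its own substream
derived from (seed, branch index in preorder) via `numpy` seed
sequences, and the substitution simulation has a separate substream, so:
reruns are byte-identical; the event streams do not depend on the engine
choice; and changing the substitution model does not perturb the indel
history. All stochastic tests run on fixed seeds.

## Synthetic data

`generate_fixtures` produces random rooted binary trees by repeatedly
joining uniformly chosen subtrees, with i.i.d. exponential branch
lengths. Defaults (40 leaves, mean branch 0.038) emulate the shape of
mammalian single-gene ortholog trees that motivate the default rate
regime. These fixtures exercise the algorithms, not biology: real gene
trees have correlated, clock-deviating branch lengths and non-uniform
shapes, real indel processes are context-dependent, and none of that is
modelled — passing tests demonstrate algorithmic correctness
(equivalence, bounds, homology bookkeeping), not realism of any
particular dataset.

## Test problem sizes

The equivalence sweep uses 1000 random instances (2–10 leaves, root
lengths 10–200, rates up to 0.08/0.12); deletion uniformity uses 10⁶
draws at n = 100, S = 5 with a 3σ per-position band; locate-cost scaling
uses synthetic block sequences with b = 2³…2¹² and slope fits on
instrumented visit counts (no wall-clock assertions — timing is
hardware- and interpreter-dependent, operation counts are not). These
sizes give tight Monte-Carlo bands while keeping the whole suite fast.

## Known limitations

- The naive engine is intentionally slow; the block engines are the
  point. All engines are pure Python — the algorithmic gap (O(b) vs
  O(log b) locate) is what the benchmark harness measures, not absolute
  speed.
- Indel rates and lengths are context-independent and homogeneous
  across sites and branches.
- No codon models or among-site rate variation in the substitution
  layer.
- The order of non-homologous insertion runs sharing an anchor is a
  convention (creation order), not an inference.
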