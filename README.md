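# evosim

Simulation of sequence evolution — substitutions plus insertions and
deletions (indels) — along a rooted phylogenetic tree, with the **true
multiple sequence alignment** emitted alongside the leaf sequences.

Simulated alignments with a known ground truth are the standard way to
benchmark aligners, ancestral-reconstruction methods and tree inference,
and they are the workhorse of simulation-heavy inference schemes such as
Approximate Bayesian Computation, where millions of indel-only
simulations may be needed. The speed-limiting step in such simulators is
the handling of indel events, and that is what this package is about.

## The model

Indels follow a Gillespie process along each branch (branch lengths in
expected substitutions per site). For a sequence of current length *n*:

- the sequence-wise insertion rate is *R*<sub>ins</sub> = (*n* + 1) *r*<sub>ins</sub>
  (one slot before each character plus one at the end);
- a candidate deletion length *S* is drawn first from the length
  distribution, and the deletion start is drawn uniformly from the
  *n* + *S* − 1 slots that let the event overlap the sequence, so
  *R*<sub>del</sub> = *r*<sub>del</sub>(*n* + *S* − 1). This edge
  correction makes every position's deletion probability exactly
  *S*/(*n* + *S* − 1); deletions overhanging an edge are trimmed;
- waiting times are exponential with rate λ = *R*<sub>ins</sub> + *R*<sub>del</sub>,
  and an event is an insertion with probability *R*<sub>ins</sub>/λ;
- indel lengths come from a truncated Zipf (mass ∝ *k*<sup>−a</sup>) or
  truncated geometric distribution.

Substitutions are simulated independently of indels with the
probability-matrix approach — *P*(*t*) = exp(*Qt*) per branch by spectral
decomposition of a reversible rate matrix (JTT for amino acids, a
one-parameter nucleotide model, or a custom PAML-format matrix) — and the
two simulations are superimposed on the alignment template at the end.

The same event stream can be applied by three interchangeable engines:

| engine  | representation                | cost per event |
|---------|-------------------------------|----------------|
| `naive` | explicit character list       | O(*n*)         |
| `list`  | run-length **block** list     | O(*b*)         |
| `avl`   | AVL order-statistic block tree| O(log *b*)     |

A block (*start*, *length*, *insertion*) records a run of undisturbed
parent positions plus the characters inserted after it on the current
branch; *b* ≤ min(*k* + 1, *n* + 1) blocks suffice for *k* events. The
true MSA is assembled from a *super-sequence* — a linked list of every
position that ever existed — with per-node pointer sequences referencing
into it; positions deleted in every emitted row are flagged off so the
alignment has no gap-only columns.

## Worked example

```python
import evosim as es

tree = es.read_newick("((human:0.12,mouse:0.08):0.05,chicken:0.25);")
cfg = es.SimConfig(root_length=60, engine="avl", seed=11)   # JTT model,
res = es.simulate(tree, cfg)                                # rates 0.03/0.09
print("alignment length:", res.final.width)
print("indel events:", len(res.events))
for name, row in res.final:
    print(f"{name:8s} {row}")
```

prints

```
alignment length: 70
indel events: 4
human    SSLFQGLYKEREDLG--GYKKTAILNDHRGIFHKALEGTSCWHKSSALRAESPCFLKNYL-GQDPKTGDQ
mouse    SHL------ERDDLG--GCKKTAILNEHRKIFHKALEGTGCWHNASALRSESPCFL-NYLVGQDAKAGEQ
chicken  CHL------ERDDLGVRGCKKQTILNDHKSVFHKALGGTNYWHKASALRAESPCFL-NYL-GQEAKAGDQ
```

The 60-residue root gained four insertions (one of six residues on the
branch to `human`, visible as the gap block in the other two rows), so
the true alignment is 70 columns wide; gaps mark positions absent from a
lineage, and every column is backed by a real homology relation from the
simulated history. The same seed with `engine="naive"` or
`engine="list"` produces a byte-identical alignment — the engines differ
only in how they apply the shared event stream.

The same run is available from the shell:

```bash
evosim simulate --tree tree.nwk --root-length 60 --engine avl \
    --seed 11 --out run/
```

which writes `leaves.fasta`, `true_msa.fasta`, `events.tsv` and a
`manifest.yaml` recording the configuration. `evosim fixtures` generates
reproducible random trees and `evosim bench` tabulates per-branch
operation counts of the three engines (element updates vs. block visits
vs. AVL node visits).

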