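# quantest2

Toolkit for *embedded-reference* multiple sequence alignment (MSA)
benchmarking: scoring test alignments against structure-verified reference
sequences, analysing the guide-tree structure that bounds what those scores
can see, and selecting reference / non-reference sequence sets so that the
scores actually measure whole-alignment quality.

## The problem

Protein MSA benchmarks embed a handful of reference sequences — whose
correct alignment is known from 3-D structure — inside a large pool of
homologs (e.g. 3 structural references among 997 family sequences).  Two
kinds of accuracy score are then compared:

- **SP** (sum-of-pairs): the number of correctly aligned residue pairs of
  the references divided by the number of aligned pairs in the reference
  alignment, and **TC** (total-column): the fraction of entire reference
  columns reproduced exactly.
- **SSPA** (secondary structure prediction accuracy): the fraction of
  reference residues whose 3-state secondary structure (H/E/C), predicted
  from the whole alignment, matches the known structure.

Progressive aligners merge sequences pairwise following a *guide-tree*, so
the SP score only probes the **effective alignment**: the smallest profile
containing every reference, produced by the smallest guide-tree clade
subtending all of them (the *effective guide-tree*).  If the references sit
in a tiny clade, SP measures almost nothing about the full alignment and
decorrelates from SSPA.  This package provides the machinery to quantify and
fix that:

- `scoring` — SP, TC and SSPA with exact residue-identity bookkeeping;
- `guidetree` — effective-subtree size, reference balance, and re-rooting
  with a guaranteed minimum effective size (rooting on any edge of the
  subtree spanning the references makes the effective size equal the leaf
  count, so a rooting passing any feasible threshold always exists);
- `selection` — reference triples that maximize spread in alignment-distance
  space, and non-references drawn from three geometric categories:
  neighbourhood of the references, close-to-one-far-from-two (margin), and
  "between" references as measured by the triangle-inequality deviation
  d(a,x) + d(x,b) − d(a,b);
- `analysis` — per-family SP-vs-SSPA regressions, slope distributions,
  aligner rankings with Pearson/Spearman correlations, and input-order
  shuffling for alignment-instability resampling;
- `synthetic_data` — seeded generators for families with known true
  alignments and planted distance geometries;
- `quantest2` CLI — `score`, `efftree`, `reroot`, `distances`, `select`,
  `analyze`, `shuffle`, `simulate`.

## Worked example

Scoring a test alignment in which sequence `b`'s third residue slipped one
column to the right of the reference columnization:

```python
from quantest2 import Alignment, SequenceRecord, sp_score, tc_score

mk = lambda rows: Alignment([SequenceRecord(k, v) for k, v in rows.items()])
ref  = mk({"a": "ACG-T",  "b": "ACGGT",  "c": "A-G-T"})
test = mk({"a": "ACG--T", "b": "AC-GGT", "c": "A-G--T"})
print(sp_score(ref, test))   # PairScore(score=0.8, n_correct=8, n_ref_pairs=10)
print(tc_score(ref, test))   # ColumnScore(score=0.8, n_shared=4, n_ref_columns=5)
```

The reference has 10 residue pairs sharing columns; 8 survive in the test
alignment, so SP = 0.8, and 4 of the 5 reference columns are reproduced
exactly (TC = 0.8).

Re-rooting a guide-tree whose references huddle in one clade:

```python
from quantest2 import parse_newick, effective_subtree, reroot_for_effective_size, RerootConfig

tree = parse_newick("(((r1,r2),r3),((((x1,x2),(x3,x4)),(x5,x6)),(x7,x8)));")
print(effective_subtree(tree, ["r1", "r2", "r3"]).effective_size)  # 3 (of 11)

rooted, res = reroot_for_effective_size(
    tree, ["r1", "r2", "r3"], RerootConfig(min_effective_size=10, seed=7))
print(res.effective_size)  # 11 (of 11)
```

Before re-rooting the SP score would reflect the alignment of only 3 of the
11 sequences (ratio 0.27); after re-rooting every merge on the path to the
root involves a reference, so the effective alignment is the whole family.

The same flows are available from the shell, e.g.

```sh
quantest2 simulate family --n 100 --annotated 3 --seed 7 --out fix/
quantest2 score --test fix/true_alignment.fa --ref-aln fix/true_alignment.fa \
    --refs fix/references.txt --pred fix/ss_predicted.fa \
    --actual fix/ss_actual.fa --out report.tsv
quantest2 reroot --tree fix/tree.nwk --refs fix/references.txt \
    --min-size 100 --seed 7 --out rerooted.nwk
```

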