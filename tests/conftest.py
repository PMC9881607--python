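"""Shared fixtures: random instance generators and brute-force oracles.

The oracles deliberately take the dumbest possible route — explicit
enumeration of residue pairs, column entries, clades and rootings — so they
stay independent of the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from quantest2 import Alignment, GuideTree, SequenceRecord, TreeNode
from quantest2.guidetree import enumerate_rootings

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_alignment(rows: dict[str, str]) -> Alignment:
    return Alignment([SequenceRecord(k, v) for k, v in rows.items()])


def random_gapping(rng: np.random.Generator, seqs: dict[str, str],
                   extra_cols: int = 4) -> Alignment:
    """Spread each ungapped sequence over random monotone column positions."""
    width = max(len(s) for s in seqs.values()) + int(rng.integers(0, extra_cols + 1))
    rows = {}
    for name, seq in seqs.items():
        cols = np.sort(rng.choice(width, size=len(seq), replace=False))
        row = ["-"] * width
        for c, ch in zip(cols, seq):
            row[c] = ch
        rows[name] = "".join(row)
    # drop columns that are all gap so the Alignment is tidy
    keep = [c for c in range(width) if any(r[c] != "-" for r in rows.values())]
    return make_alignment({k: "".join(v[c] for c in keep) for k, v in rows.items()})


def random_alignment_pair(rng: np.random.Generator, max_seqs: int = 6,
                          max_len: int = 20):
    """A reference/test alignment pair over the same ungapped sequences."""
    n = int(rng.integers(2, max_seqs + 1))
    seqs = {
        f"s{i}": "".join(rng.choice(list(AA), size=int(rng.integers(1, max_len + 1))))
        for i in range(n)
    }
    return random_gapping(rng, seqs), random_gapping(rng, seqs)


# -- scoring oracles --------------------------------------------------------


def _residue_entries(aln: Alignment):
    """Per column: list of (seq id, residue ordinal) entries."""
    counters = {rec.id: 0 for rec in aln}
    cols = []
    for c in range(aln.width):
        entries = []
        for rec in aln:
            if rec.residues[c] != "-":
                entries.append((rec.id, counters[rec.id]))
                counters[rec.id] += 1
        cols.append(entries)
    return cols


def brute_sp(reference: Alignment, test: Alignment):
    """Enumerate every co-aligned residue pair in both alignments, intersect."""
    def pair_set(aln):
        out = set()
        for entries in _residue_entries(aln):
            for a, b in combinations(entries, 2):
                out.add(frozenset((a, b)))
        return out

    ref_pairs = pair_set(reference)
    if not ref_pairs:
        return None, 0
    return len(ref_pairs & pair_set(test)) / len(ref_pairs), len(ref_pairs)


def brute_tc(reference: Alignment, test: Alignment):
    """Compare full column contents (residue entries + gapped-id set)."""
    ids = frozenset(rec.id for rec in reference)

    def column_set(aln):
        out = set()
        for entries in _residue_entries(aln):
            if entries:
                present = frozenset(entries)
                gapped = ids - frozenset(e[0] for e in entries)
                out.add((present, gapped))
        return out

    ref_cols = []
    for entries in _residue_entries(reference):
        if entries:
            present = frozenset(entries)
            gapped = ids - frozenset(e[0] for e in entries)
            ref_cols.append((present, gapped))
    if not ref_cols:
        return None, 0
    test_cols = column_set(test)
    shared = sum(1 for col in ref_cols if col in test_cols)
    return shared / len(ref_cols), len(ref_cols)


# -- tree oracles -----------------------------------------------------------


def brute_effective_size(tree: GuideTree, refs) -> int:
    """Scan every clade, keep the smallest containing all references."""
    refs = set(refs)
    best = None
    for node in tree.root.walk():
        below = {leaf.label for leaf in node.leaves()}
        if refs <= below and (best is None or len(below) < best):
            best = len(below)
    assert best is not None
    return best


def brute_best_rooting_size(tree: GuideTree, refs) -> int:
    """Max effective size over every rooting, by exhaustive enumeration."""
    return max(
        brute_effective_size(candidate, refs)
        for _, candidate in enumerate_rootings(tree)
    )


def caterpillar(n: int) -> GuideTree:
    """Fully unbalanced rooted tree ((..((L1,L2),L3)..),Ln)."""
    node = TreeNode()
    node.add(TreeNode("L1"))
    node.add(TreeNode("L2"))
    for i in range(3, n + 1):
        parent = TreeNode()
        parent.add(node)
        parent.add(TreeNode(f"L{i}"))
        node = parent
    return GuideTree(node, rooted=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
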