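"""Readers and writers for the formats the benchmark toolkit touches.

FASTA carries sequences, alignments and 3-state secondary-structure strings;
Newick carries guide-trees; the square PHYLIP dialect carries distance
matrices; TSV carries score tables.  All readers validate strictly and
normalize to one internal convention: gaps are ``'-'`` (``'.'`` accepted on
input), residues are uppercased, structure states are ``{H, E, C}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .guidetree import GuideTree, TreeError, TreeNode

GAP = "-"
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("XBZUO")
SEQUENCE_ALPHABET = AMINO_ACIDS | {GAP}
SS_STATES = frozenset("HEC")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed or invalid input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence, possibly gapped."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - SEQUENCE_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains illegal characters {sorted(bad)}"
            )

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """Ordered gapped rows sharing one column coordinate system."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise FormatError("alignment with no rows")
        width = len(records[0].residues)
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            if len(rec.residues) != width:
                raise FormatError(
                    f"ragged alignment: sequence {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {width}"
                )
        self.records = records
        self.width = width
        self._by_id = {rec.id: rec for rec in records}

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def row(self, seq_id: str) -> SequenceRecord:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise KeyError(f"no sequence {seq_id!r} in alignment") from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alignment) and self.records == other.records

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Alignment {len(self.records)}x{self.width}>"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _normalize_seq(raw: str) -> str:
    return raw.upper().replace(".", GAP)


def read_fasta(path: PathLike, aligned: bool = False):
    """Read a FASTA file, preserving record order.

    With ``aligned=True`` returns an :class:`Alignment` (gap characters
    preserved; ragged input is an error naming the offending id).  Otherwise
    returns a list of :class:`SequenceRecord` with gaps stripped.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        residues = _normalize_seq(str(entry.seq))
        if not aligned:
            residues = residues.replace(GAP, "")
        records.append(SequenceRecord(entry.id, residues))
    if aligned:
        widths = {len(r.residues) for r in records}
        if len(widths) > 1:
            culprit = next(
                r.id for r in records if len(r.residues) != len(records[0].residues)
            )
            raise FormatError(
                f"ragged alignment in {path}: sequence {culprit!r} length differs"
            )
        return Alignment(records)
    return records


def write_fasta(
    path: PathLike,
    data: Union[Alignment, Iterable[SequenceRecord]],
    line_width: int = 60,
) -> None:
    records = data.records if isinstance(data, Alignment) else list(data)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), line_width):
                fh.write(rec.residues[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Secondary-structure annotations (FASTA-like, body over {H,E,C})
# ---------------------------------------------------------------------------


def read_ss_annotations(path: PathLike) -> dict[str, str]:
    """Read per-sequence 3-state secondary-structure strings.

    States are H (helix), E (strand), C (coil), defined over ungapped residue
    positions; gap characters are not permitted.  Pairing annotations with
    same-id sequences (and length checks against them) happens at scoring
    time, not here.
    """
    out: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in out:
            raise FormatError(f"duplicate annotation id {entry.id!r} in {path}")
        body = str(entry.seq)
        bad = set(body) - SS_STATES
        if bad:
            raise FormatError(
                f"annotation {entry.id!r}: illegal state {sorted(bad)[0]!r} "
                f"(expected H, E or C)"
            )
        if not body:
            raise FormatError(f"annotation {entry.id!r} is empty")
        out[entry.id] = body
    return out


def write_ss_annotations(path: PathLike, annotations: Mapping[str, str],
                         line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, body in annotations.items():
            fh.write(f">{name}\n")
            for i in range(0, len(body), line_width):
                fh.write(body[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"unbalanced parenthesis: unexpected ')' at character {offset}"
                )
    if depth != 0:
        raise FormatError(
            f"unbalanced parentheses: {depth} '(' left open at end of tree "
            f"(character {len(text) - 1})"
        )


def parse_newick(text: str) -> GuideTree:
    """Parse a single Newick tree string into a :class:`GuideTree`.

    Accepts both the rooted (bifurcating root) and unrooted (trifurcating
    root) dialects; branch lengths are optional and preserved; internal node
    labels are tolerated and dropped.
    """
    import dendropy

    _check_parentheses(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
        )
    except Exception as exc:
        message = str(exc)
        if "Duplicate taxon labels" in message:
            label = message.rsplit(":", 1)[-1].strip()
            offset = text.find(label, text.find(label) + 1)
            raise FormatError(
                f"duplicate leaf label {label!r} at character {offset}"
            ) from exc
        raise FormatError(f"Newick parse error: {exc}") from exc

    def convert_one(dnode) -> TreeNode:
        label = None
        if not dnode.child_nodes():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        return TreeNode(label, dnode.edge.length)

    root = convert_one(dtree.seed_node)
    stack = [(dtree.seed_node, root)]
    while stack:
        dnode, node = stack.pop()
        for child in dnode.child_nodes():
            stack.append((child, node.add(convert_one(child))))
    root.length = None  # a root edge length has no meaning here
    labels: set[str] = set()
    for leaf in root.leaves():
        if leaf.label is None:
            raise FormatError("Newick parse error: unlabeled leaf")
        if leaf.label in labels:
            first = text.find(leaf.label)
            offset = text.find(leaf.label, first + 1)
            raise FormatError(
                f"duplicate leaf label {leaf.label!r} at character {offset}"
            )
        labels.add(leaf.label)
    try:
        return GuideTree(root)
    except TreeError as exc:
        raise FormatError(f"Newick parse error: {exc}") from exc


def read_newick(path: PathLike) -> GuideTree:
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"empty Newick file {path}")
    return parse_newick(text)


def write_newick(path: PathLike, tree: GuideTree) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Square PHYLIP distance matrices
# ---------------------------------------------------------------------------


class DistanceMatrix:
    """Labeled square symmetric distance matrix with zero diagonal.

    The triangle inequality is deliberately *not* assumed: deviation from it
    is a quantity the selection module measures.
    """

    def __init__(self, labels: Sequence[str], values):
        self.labels = list(labels)
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("duplicate labels in distance matrix")
        values = np.asarray(values, dtype=float)
        n = len(self.labels)
        if values.shape != (n, n):
            raise FormatError(
                f"distance matrix shape {values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(values, values.T, atol=1e-9, rtol=0.0):
            raise FormatError("distance matrix is not symmetric")
        if np.any(np.diag(values) != 0.0):
            raise FormatError("distance matrix diagonal must be exactly zero")
        if np.any(values < 0):
            raise FormatError("negative distances are not allowed")
        # symmetrize away sub-tolerance asymmetry so d(i,j) == d(j,i) exactly
        self.values = (values + values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown label {label!r}") from None

    def d(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def __len__(self) -> int:
        return len(self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DistanceMatrix {len(self.labels)} labels>"


def read_distance_matrix(path: PathLike) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (count line, then label + row)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"empty distance matrix file {path}")
    try:
        n = int(lines[0].split()[0])
    except ValueError:
        raise FormatError(
            f"{path}: first line must be the taxon count, got {lines[0]!r}"
        ) from None
    if len(lines) - 1 != n:
        raise FormatError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    labels: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise FormatError(
                f"{path}: row for {parts[0]!r} has {len(parts) - 1} values, "
                f"expected {n}"
            )
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return DistanceMatrix(labels, rows)


def write_distance_matrix(path: PathLike, dm: DistanceMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.values):
            fh.write(label + "  " + "  ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# TSV score tables
# ---------------------------------------------------------------------------

SCORE_COLUMNS = [
    "family", "aligner", "replicate", "sp", "tc", "sspa",
    "n_ref_pairs", "n_ref_columns", "n_ss_positions", "effective_size",
]


def read_score_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    missing = {"family", "aligner", "sp", "sspa"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: score table missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df


def write_score_table(path: PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
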