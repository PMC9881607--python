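"""SP, TC and SSPA: the three accuracy measures of the benchmark.

SP (sum-of-pairs) is the number of correctly aligned residue pairs divided by
the number of aligned pairs in the reference; TC (total-column) is the
fraction of entire reference columns reproduced in the test alignment; SSPA
(secondary structure prediction accuracy) is the fraction of reference
residue positions where an alignment-derived 3-state structure prediction
matches the known structure.

Residues are identified by (sequence id, ungapped residue ordinal), so gap
placement elsewhere in either alignment can never alias one residue for
another.  Columns that are all-gap across the scored rows carry no signal and
are ignored on both sides, which makes both scores invariant under all-gap
column insertion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .io_formats import GAP, Alignment, SequenceRecord


class ScoringError(ValueError):
    """Inconsistent scoring inputs."""


@dataclass(frozen=True)
class PairScore:
    """SP result: ``score`` is None when the reference has no aligned pairs."""

    score: Optional[float]
    n_correct: int
    n_ref_pairs: int

    @property
    def defined(self) -> bool:
        return self.score is not None


@dataclass(frozen=True)
class ColumnScore:
    """TC result: ``score`` is None when the reference has no columns."""

    score: Optional[float]
    n_shared: int
    n_ref_columns: int

    @property
    def defined(self) -> bool:
        return self.score is not None


@dataclass(frozen=True)
class SSPAScore:
    """Pooled and per-sequence structure prediction accuracy."""

    score: float
    per_id: dict[str, float]
    n_matches: int
    n_positions: int


@dataclass(frozen=True)
class ScoreReport:
    """One benchmark evaluation of a test alignment against its reference."""

    sp: Optional[float]
    tc: Optional[float]
    sspa: Optional[float]
    n_ref_pairs: int
    n_ref_columns: int
    n_ss_positions: int


def project_reference_rows(test: Alignment, ref_ids: Iterable[str]) -> Alignment:
    """Extract the embedded reference rows from a test alignment.

    Returns only the rows named in ``ref_ids`` (in test-alignment order),
    with columns that are all-gap across those rows removed; the ungapped
    content of each row is unchanged.  This is the "smallest profile that
    contains all embedded references" whose quality SP and TC measure.
    """
    wanted = set(ref_ids)
    if len(wanted) < 2:
        raise ScoringError("need at least two reference ids to project")
    missing = wanted - set(test.ids)
    if missing:
        raise ScoringError(
            f"reference id {sorted(missing)[0]!r} not present in test alignment"
        )
    rows = [rec for rec in test.records if rec.id in wanted]
    keep = [
        c for c in range(test.width)
        if any(rec.residues[c] != GAP for rec in rows)
    ]
    projected = [
        SequenceRecord(rec.id, "".join(rec.residues[c] for c in keep))
        for rec in rows
    ]
    return Alignment(projected)


def _residue_columns(aln: Alignment, ids: list[str]) -> dict[tuple[str, int], int]:
    """(sequence id, residue ordinal) -> column index, for the given rows."""
    out: dict[tuple[str, int], int] = {}
    for seq_id in ids:
        ordinal = 0
        for col, ch in enumerate(aln.row(seq_id).residues):
            if ch != GAP:
                out[(seq_id, ordinal)] = col
                ordinal += 1
    return out


def _check_same_sequences(reference: Alignment, test: Alignment) -> list[str]:
    ids = reference.ids
    for seq_id in ids:
        if seq_id not in test:
            raise ScoringError(f"sequence {seq_id!r} missing from test alignment")
        if reference.row(seq_id).ungapped() != test.row(seq_id).ungapped():
            raise ScoringError(
                f"ungapped sequence mismatch for {seq_id!r} between reference "
                f"and test alignments"
            )
    return ids


def sp_score(reference: Alignment, test: Alignment) -> PairScore:
    """Sum-of-pairs score of ``test`` against ``reference``.

    A pair is two residues from different sequences occupying the same
    column.  The score is the number of reference pairs that also share a
    column in the test alignment, divided by the number of reference pairs.
    Residues aligned to gaps are unscored.  A reference with zero aligned
    pairs yields an undefined (None) score, never 0.
    """
    ids = _check_same_sequences(reference, test)
    test_col = _residue_columns(test, ids)

    # group reference residues by reference column, then count pairs whose
    # two members land in one test column as well
    by_ref_col: dict[int, list[tuple[str, int]]] = {}
    for (seq_id, ordinal), col in _residue_columns(reference, ids).items():
        by_ref_col.setdefault(col, []).append((seq_id, ordinal))

    n_pairs = 0
    n_correct = 0
    for residues in by_ref_col.values():
        k = len(residues)
        n_pairs += k * (k - 1) // 2
        groups: dict[int, int] = {}
        for key in residues:
            tc = test_col[key]
            groups[tc] = groups.get(tc, 0) + 1
        n_correct += sum(g * (g - 1) // 2 for g in groups.values())

    if n_pairs == 0:
        return PairScore(score=None, n_correct=0, n_ref_pairs=0)
    return PairScore(score=n_correct / n_pairs, n_correct=n_correct, n_ref_pairs=n_pairs)


def _column_signatures(aln: Alignment, ids: list[str]) -> list[tuple]:
    """Per column: tuple of residue ordinals (None for gap), skipping
    columns that are all-gap over the scored rows."""
    ordinals = {seq_id: 0 for seq_id in ids}
    rows = {seq_id: aln.row(seq_id).residues for seq_id in ids}
    sigs: list[tuple] = []
    for col in range(aln.width):
        sig = []
        any_residue = False
        for seq_id in ids:
            if rows[seq_id][col] != GAP:
                sig.append(ordinals[seq_id])
                ordinals[seq_id] += 1
                any_residue = True
            else:
                sig.append(None)
        if any_residue:
            sigs.append(tuple(sig))
    return sigs


def tc_score(reference: Alignment, test: Alignment) -> ColumnScore:
    """Total-column score: fraction of reference columns reproduced exactly.

    A reference column is shared when some test column holds exactly the same
    residues-and-gaps pattern over the scored sequences.  All-gap columns are
    ignored on both sides.
    """
    ids = _check_same_sequences(reference, test)
    ref_sigs = _column_signatures(reference, ids)
    test_sigs = set(_column_signatures(test, ids))
    n_cols = len(ref_sigs)
    if n_cols == 0:
        return ColumnScore(score=None, n_shared=0, n_ref_columns=0)
    shared = sum(1 for sig in ref_sigs if sig in test_sigs)
    return ColumnScore(score=shared / n_cols, n_shared=shared, n_ref_columns=n_cols)


def sspa_score(
    predicted: Mapping[str, str],
    actual: Mapping[str, str],
    ref_ids: Iterable[str],
) -> SSPAScore:
    """Secondary structure prediction accuracy over the reference sequences.

    Per-sequence accuracy is matching positions / length; the pooled SSPA is
    total matches over total positions across all references, so longer
    references carry proportionally more weight.  Both are returned.
    """
    refs = list(dict.fromkeys(ref_ids))
    if not refs:
        raise ScoringError("empty reference set for SSPA")
    per_id: dict[str, float] = {}
    total_match = 0
    total_pos = 0
    for seq_id in refs:
        if seq_id not in predicted:
            raise ScoringError(f"no predicted structure for {seq_id!r}")
        if seq_id not in actual:
            raise ScoringError(f"no actual structure for {seq_id!r}")
        p, a = predicted[seq_id], actual[seq_id]
        if len(p) != len(a):
            raise ScoringError(
                f"structure length mismatch for {seq_id!r}: predicted "
                f"{len(p)}, actual {len(a)}"
            )
        matches = sum(1 for x, y in zip(p, a) if x == y)
        per_id[seq_id] = matches / len(a)
        total_match += matches
        total_pos += len(a)
    return SSPAScore(
        score=total_match / total_pos,
        per_id=per_id,
        n_matches=total_match,
        n_positions=total_pos,
    )


def score_family(
    test: Alignment,
    reference: Alignment,
    ref_ids: Iterable[str],
    predicted: Optional[Mapping[str, str]] = None,
    actual: Optional[Mapping[str, str]] = None,
) -> ScoreReport:
    """Full benchmark evaluation: project references out of ``test``, score
    SP and TC against ``reference``, and SSPA when structures are given."""
    refs = list(dict.fromkeys(ref_ids))
    projected = project_reference_rows(test, refs)
    ref_rows = project_reference_rows(reference, refs) if len(reference) > len(refs) \
        else reference
    sp = sp_score(ref_rows, projected)
    tc = tc_score(ref_rows, projected)
    if predicted is not None and actual is not None:
        ss = sspa_score(predicted, actual, refs)
        sspa, n_pos = ss.score, ss.n_positions
    else:
        sspa, n_pos = None, 0
    return ScoreReport(
        sp=sp.score,
        tc=tc.score,
        sspa=sspa,
        n_ref_pairs=sp.n_ref_pairs,
        n_ref_columns=tc.n_ref_columns,
        n_ss_positions=n_pos,
    )
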