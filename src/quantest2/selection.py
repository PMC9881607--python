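"""Reference and non-reference sequence selection in alignment-distance space.

A benchmark family embeds a few structure-verified reference sequences in a
large pool of homologs.  Scores are only informative when the references
cover the family well, so references are chosen to span a large volume of
the alignment-distance space, and non-references are drawn from three
geometric categories around them:

(i)   *neighbourhood* — closest to some reference,
(ii)  *near-one-far-two* — close to one reference but far from the others
      (largest margin between nearest and second-nearest reference), and
(iii) *between* — smallest deviation from the triangle inequality,
      delta(x; a, b) = d(a,x) + d(x,b) - d(a,b), minimized over reference
      pairs; delta = 0 means x lies exactly on a path between a and b.

Distances default to one minus fractional identity over mutually ungapped
columns of an existing family alignment; a classical multidimensional
scaling embeds them for visual inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .io_formats import GAP, Alignment, DistanceMatrix

# the selection machinery works on any labeled symmetric distance matrix
DistanceModel = DistanceMatrix

CATEGORY_NEIGHBOURHOOD = "neighbourhood"
CATEGORY_NEAR_FAR = "near-one-far-two"
CATEGORY_BETWEEN = "between"
CATEGORIES = (CATEGORY_NEIGHBOURHOOD, CATEGORY_NEAR_FAR, CATEGORY_BETWEEN)


class SelectionError(ValueError):
    """Invalid selection input."""


def pairwise_distances(aln: Alignment) -> DistanceMatrix:
    """Percent-identity distances: d = 1 - identical / mutually ungapped.

    Columns where either row has a gap are excluded; a pair that shares no
    residue column gets d = 1 with a warning.
    """
    if len(aln) < 2:
        raise SelectionError("need at least two rows for pairwise distances")
    codes = np.frombuffer(
        "".join(rec.residues for rec in aln).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln), aln.width)
    present = (codes != ord(GAP)).astype(np.float64)
    shared = present @ present.T
    matches = np.zeros_like(shared)
    for residue in np.unique(codes):
        if residue == ord(GAP):
            continue
        mask = (codes == residue).astype(np.float64)
        matches += mask @ mask.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - matches / shared
    if np.any(shared[~np.eye(len(aln), dtype=bool)] == 0):
        warnings.warn(
            "sequence pair(s) share no residue columns; their distance is set to 1",
            stacklevel=2,
        )
    d[shared == 0] = 1.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(aln.ids, d)


@dataclass(frozen=True)
class Embedding:
    """Low-dimensional coordinates from classical scaling (centered)."""

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    @property
    def dim(self) -> int:
        return self.coordinates.shape[1]


def classical_mds(dm: DistanceMatrix, dim: int = 2) -> Embedding:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix, takes the top ``dim``
    eigenpairs, truncates negative eigenvalues to zero.  A distance matrix
    that is Euclidean-realizable in ``dim`` dimensions is reproduced exactly
    (up to rotation); others are approximated in the least-squares sense of
    the centered Gram matrix.
    """
    n = len(dm)
    if n < dim + 1:
        raise SelectionError(f"need at least {dim + 1} labels for a {dim}-D embedding")
    d2 = dm.values ** 2
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    gram = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1][:dim]
    lams = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lams)
    coords = coords - coords.mean(axis=0)
    return Embedding(labels=list(dm.labels), coordinates=coords, eigenvalues=lams)


def spread_objective(dm: DistanceMatrix, subset: Sequence[str]) -> float:
    """Sum of pairwise distances — the volume proxy a reference set maximizes."""
    return float(sum(dm.d(a, b) for a, b in combinations(subset, 2)))


def select_references(
    dm: DistanceMatrix,
    structure_ids: Iterable[str],
    k: int = 3,
    seed: int = 0,
    exhaustive_limit: int = 25,
) -> tuple[str, ...]:
    """Pick the k structure-annotated sequences that best span distance space.

    Maximizes the sum of pairwise distances (for k = 3 the triangle
    perimeter).  Exhaustive over all k-subsets when the candidate set is
    small; otherwise greedy farthest-point with seeded restarts plus a swap
    improvement pass.  Ties break lexicographically on the sorted id tuple.
    """
    candidates = sorted(dict.fromkeys(structure_ids))
    if k < 2:
        raise SelectionError("k must be at least 2")
    if len(candidates) < k:
        raise SelectionError(
            f"only {len(candidates)} structure-annotated candidates for k={k}"
        )
    for c in candidates:
        dm.index(c)  # raises on unknown label
    if len(candidates) == k:
        return tuple(candidates)

    if len(candidates) <= exhaustive_limit:
        best: Optional[tuple[str, ...]] = None
        best_val = -np.inf
        for subset in combinations(candidates, k):  # lexicographic order
            val = spread_objective(dm, subset)
            if val > best_val + 1e-12:
                best, best_val = subset, val
        assert best is not None
        return best

    rng = np.random.default_rng(seed)
    idx = {c: dm.index(c) for c in candidates}
    best = None
    best_val = -np.inf
    for _ in range(8):
        chosen = [candidates[rng.integers(len(candidates))]]
        while len(chosen) < k:
            gains = [
                (sum(dm.values[idx[c], idx[ch]] for ch in chosen), c)
                for c in candidates if c not in chosen
            ]
            chosen.append(min(gains, key=lambda t: (-t[0], t[1]))[1])
        improved = True
        while improved:
            improved = False
            current = spread_objective(dm, chosen)
            for i, old in enumerate(list(chosen)):
                for c in candidates:
                    if c in chosen:
                        continue
                    trial = chosen[:i] + [c] + chosen[i + 1:]
                    if spread_objective(dm, trial) > current + 1e-12:
                        chosen = trial
                        current = spread_objective(dm, chosen)
                        improved = True
        val = spread_objective(dm, chosen)
        key = tuple(sorted(chosen))
        if val > best_val + 1e-12 or (abs(val - best_val) <= 1e-12 and
                                      (best is None or key < best)):
            best, best_val = key, val
    assert best is not None
    return best


def triangle_deviation(dm: DistanceMatrix, x: str, a: str, b: str) -> float:
    """delta(x; a, b) = d(a,x) + d(x,b) - d(a,b); small delta means x lies
    between a and b in distance space."""
    if len({x, a, b}) != 3:
        raise SelectionError("x, a and b must be three distinct labels")
    return dm.d(a, x) + dm.d(x, b) - dm.d(a, b)


@dataclass(frozen=True)
class CandidateClassification:
    """A non-reference candidate with its three geometric scores.

    ``category`` is the class in which the candidate's rank (among all
    candidates) is best; ``score`` is the category-specific scalar.
    """

    label: str
    category: str
    score: float
    nearest_ref_distance: float
    margin: float
    deviation: float


def classify_candidates(
    dm: DistanceMatrix,
    reference_ids: Iterable[str],
    candidate_ids: Optional[Iterable[str]] = None,
) -> list[CandidateClassification]:
    """Score and categorize every non-reference candidate.

    Each candidate gets all three scores — nearest-reference distance,
    margin (second-nearest minus nearest reference distance) and minimum
    triangle deviation over reference pairs — and is assigned the category
    in which its rank is best: ascending nearest distance for (i),
    descending margin for (ii), ascending deviation for (iii).  Rank ties
    resolve in category order (i), (ii), (iii).
    """
    refs = sorted(dict.fromkeys(reference_ids))
    if len(refs) < 2:
        raise SelectionError(
            "need at least two references: margin and betweenness are "
            "undefined otherwise"
        )
    if candidate_ids is None:
        candidates = [l for l in dm.labels if l not in set(refs)]
    else:
        candidates = list(dict.fromkeys(candidate_ids))
        overlap = set(candidates) & set(refs)
        if overlap:
            raise SelectionError(f"candidates overlap references: {sorted(overlap)}")
    if not candidates:
        raise SelectionError("no non-reference candidates to classify")

    ref_idx = np.array([dm.index(r) for r in refs])
    cand_idx = np.array([dm.index(c) for c in candidates])
    to_refs = dm.values[np.ix_(cand_idx, ref_idx)]  # candidates x refs
    part = np.sort(to_refs, axis=1)
    nearest = part[:, 0]
    margin = part[:, 1] - part[:, 0]
    deviation = np.min(
        [
            to_refs[:, i] + to_refs[:, j] - dm.values[ref_idx[i], ref_idx[j]]
            for i, j in combinations(range(len(refs)), 2)
        ],
        axis=0,
    )

    rank_i = rankdata(nearest, method="min")
    rank_ii = rankdata(-margin, method="min")
    rank_iii = rankdata(deviation, method="min")

    out: list[CandidateClassification] = []
    for pos, label in enumerate(candidates):
        ranks = (rank_i[pos], rank_ii[pos], rank_iii[pos])
        scores = (nearest[pos], margin[pos], deviation[pos])
        cat_pos = int(np.argmin(ranks))  # ties -> earliest, i.e. category (i)
        out.append(
            CandidateClassification(
                label=label,
                category=CATEGORIES[cat_pos],
                score=float(scores[cat_pos]),
                nearest_ref_distance=float(nearest[pos]),
                margin=float(margin[pos]),
                deviation=float(deviation[pos]),
            )
        )
    return out


@dataclass(frozen=True)
class FamilyBenchmark:
    """An assembled benchmark family: references plus categorized pool."""

    reference_ids: tuple[str, ...]
    nonreference_ids: tuple[str, ...]
    category_counts: dict[str, int]
    provenance: dict

    @property
    def family_size(self) -> int:
        return len(self.reference_ids) + len(self.nonreference_ids)


def assemble_family(
    dm: DistanceMatrix,
    structure_ids: Iterable[str],
    pool_ids: Iterable[str],
    k: int = 3,
    family_size: int = 1000,
    seed: int = 0,
    distance_source: str = "unspecified",
) -> FamilyBenchmark:
    """Assemble one benchmark family: k spread references + the non-reference
    pool drawn round-robin from the three category rankings.

    Defaults follow the published composition: 3 references and 997
    non-references for a family of 1000.  Round-robin interleaving keeps the
    per-category counts within one of each other; ranking ties break on
    sorted id, so output is deterministic given the seed.
    """
    structure = sorted(dict.fromkeys(structure_ids))
    pool = sorted(dict.fromkeys(pool_ids))
    refs = select_references(dm, structure, k=k, seed=seed)
    candidates = [p for p in pool if p not in set(refs)]
    m = family_size - k
    if len(candidates) < m:
        raise SelectionError(
            f"pool has only {len(candidates)} candidates; "
            f"{m - len(candidates)} short of the {m} non-references needed"
        )

    classified = classify_candidates(dm, refs, candidates)
    by_label = {c.label: c for c in classified}
    rankings = {
        CATEGORY_NEIGHBOURHOOD: sorted(
            candidates, key=lambda l: (by_label[l].nearest_ref_distance, l)
        ),
        CATEGORY_NEAR_FAR: sorted(
            candidates, key=lambda l: (-by_label[l].margin, l)
        ),
        CATEGORY_BETWEEN: sorted(
            candidates, key=lambda l: (by_label[l].deviation, l)
        ),
    }
    cursors = {cat: 0 for cat in CATEGORIES}
    counts = {cat: 0 for cat in CATEGORIES}
    chosen: list[str] = []
    taken: set[str] = set()
    while len(chosen) < m:
        for cat in CATEGORIES:
            if len(chosen) >= m:
                break
            order = rankings[cat]
            i = cursors[cat]
            while i < len(order) and order[i] in taken:
                i += 1
            if i < len(order):
                label = order[i]
                chosen.append(label)
                taken.add(label)
                counts[cat] += 1
                cursors[cat] = i + 1
    return FamilyBenchmark(
        reference_ids=refs,
        nonreference_ids=tuple(chosen),
        category_counts=counts,
        provenance={
            "seed": seed,
            "k": k,
            "family_size": family_size,
            "distance_source": distance_source,
            "n_structure_candidates": len(structure),
            "n_pool_candidates": len(candidates),
        },
    )
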