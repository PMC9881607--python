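"""Distance-space selection: distances, MDS, spread references, categories."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from quantest2 import (
    DistanceMatrix,
    assemble_family,
    classical_mds,
    classify_candidates,
    pairwise_distances,
    select_references,
    triangle_deviation,
)
from quantest2.selection import (
    CATEGORY_BETWEEN,
    CATEGORY_NEIGHBOURHOOD,
    SelectionError,
    spread_objective,
)

from conftest import make_alignment, random_alignment_pair


def euclidean_dm(points: np.ndarray, labels=None) -> DistanceMatrix:
    labels = labels or [f"p{i}" for i in range(len(points))]
    values = cdist(points, points)
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values)


class TestPairwiseDistances:
    def test_identical_rows_distance_zero(self):
        aln = make_alignment({"a": "ACDE", "b": "ACDE"})
        assert pairwise_distances(aln).d("a", "b") == 0.0

    def test_half_identity(self):
        aln = make_alignment({"a": "AAAA", "b": "AATT"})
        assert pairwise_distances(aln).d("a", "b") == 0.5

    def test_gapped_columns_excluded(self):
        aln = make_alignment({"a": "AC-E", "b": "AC-E", "c": "GC-E"})
        dm = pairwise_distances(aln)
        assert dm.d("a", "b") == 0.0
        assert dm.d("a", "c") == pytest.approx(1 / 3)

    def test_no_shared_columns_warns_and_gives_one(self):
        aln = make_alignment({"a": "AC--", "b": "--DE"})
        with pytest.warns(UserWarning, match="no residue columns"):
            dm = pairwise_distances(aln)
        assert dm.d("a", "b") == 1.0

    def test_matches_column_scan_oracle(self, rng):
        for _ in range(20):
            aln, _ = random_alignment_pair(rng, max_seqs=5, max_len=15)
            dm = pairwise_distances(aln)
            for x, y in combinations(aln.ids, 2):
                rx, ry = aln.row(x).residues, aln.row(y).residues
                shared = sum(
                    1 for a, b in zip(rx, ry) if a != "-" and b != "-"
                )
                same = sum(
                    1 for a, b in zip(rx, ry) if a != "-" and b != "-" and a == b
                )
                expected = 1 - same / shared if shared else 1.0
                assert dm.d(x, y) == pytest.approx(expected)


class TestClassicalMDS:
    def test_equilateral_triangle(self):
        dm = DistanceMatrix(list("abc"), [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        emb = classical_mds(dm, dim=2)
        assert np.allclose(pdist(emb.coordinates), [1, 1, 1], atol=1e-9)
        assert np.allclose(emb.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_collinear_configuration_is_rank_one(self):
        dm = DistanceMatrix(list("abc"), [[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        emb = classical_mds(dm, dim=2)
        assert np.allclose(emb.coordinates[:, 1], 0, atol=1e-6)

    def test_inverts_euclidean_distances(self, rng):
        for dim in (2, 3):
            points = rng.normal(size=(12, dim))
            dm = euclidean_dm(points)
            emb = classical_mds(dm, dim=dim)
            assert np.allclose(pdist(emb.coordinates), pdist(points), atol=1e-6)

    def test_too_few_labels_rejected(self):
        dm = DistanceMatrix(list("ab"), [[0, 1], [1, 0]])
        with pytest.raises(SelectionError, match="at least 3"):
            classical_mds(dm, dim=2)


class TestSelectReferences:
    def test_exactly_k_candidates_returned_as_is(self):
        dm = euclidean_dm(np.array([[0, 0], [1, 0], [0, 1], [5, 5]]))
        assert select_references(dm, ["p0", "p1", "p2"], k=3) == ("p0", "p1", "p2")

    def test_clumped_pair_avoided(self):
        # p0/p1 nearly coincide; the spread triple must skip one of them
        points = np.array([[0.0, 0.0], [0.05, 0.0], [4.0, 0.0], [2.0, 3.0]])
        dm = euclidean_dm(points)
        best = select_references(dm, dm.labels, k=3)
        expected = max(
            combinations(sorted(dm.labels), 3),
            key=lambda t: spread_objective(dm, t),
        )
        assert best == expected
        assert not {"p0", "p1"} <= set(best)

    def test_objective_beats_every_other_subset(self, rng):
        points = rng.random((8, 2))
        dm = euclidean_dm(points)
        best = select_references(dm, dm.labels, k=3)
        best_val = spread_objective(dm, best)
        for triple in combinations(dm.labels, 3):
            assert spread_objective(dm, triple) <= best_val + 1e-12

    def test_greedy_agrees_with_exhaustive_mostly(self, rng):
        agree = 0
        trials = 20
        for t in range(trials):
            points = rng.random((10, 2))
            dm = euclidean_dm(points)
            exhaustive = select_references(dm, dm.labels, k=3)
            greedy = select_references(
                dm, dm.labels, k=3, seed=t, exhaustive_limit=0
            )
            agree += exhaustive == greedy
        assert agree >= int(0.9 * trials)

    def test_too_few_candidates_rejected(self):
        dm = euclidean_dm(np.array([[0, 0], [1, 1], [2, 2]]))
        with pytest.raises(SelectionError, match="candidates"):
            select_references(dm, ["p0", "p1"], k=3)


class TestTriangleDeviation:
    def test_perfectly_between(self):
        dm = DistanceMatrix(
            list("axb"), [[0, 2, 5], [2, 0, 3], [5, 3, 0]]
        )
        assert triangle_deviation(dm, "x", "a", "b") == 0.0

    def test_coincident_with_endpoint(self):
        dm = DistanceMatrix(
            list("axb"), [[0, 0, 4], [0, 0, 4], [4, 4, 0]]
        )
        assert triangle_deviation(dm, "x", "a", "b") == 0.0

    def test_equilateral_deviation_is_one(self):
        dm = DistanceMatrix(list("axb"), [[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        assert triangle_deviation(dm, "x", "a", "b") == 1.0

    def test_symmetric_in_endpoints_and_nonnegative_for_metric(self, rng):
        points = rng.random((7, 2))
        dm = euclidean_dm(points)
        for x, a, b in combinations(dm.labels, 3):
            d1 = triangle_deviation(dm, x, a, b)
            assert d1 == pytest.approx(triangle_deviation(dm, x, b, a))
            assert d1 >= -1e-12

    def test_unknown_label_rejected(self):
        dm = euclidean_dm(np.zeros((3, 2)) + np.arange(3)[:, None])
        with pytest.raises(KeyError, match="'zz'"):
            triangle_deviation(dm, "zz", "p0", "p1")


class TestClassifyCandidates:
    def test_candidate_on_a_reference_is_neighbourhood(self):
        points = np.array(
            [[0.0, 0.0], [4.0, 0.0], [2.0, 3.0],  # refs
             [0.0, 0.0], [2.0, 0.5], [3.0, 1.0]]
        )
        dm = euclidean_dm(points)
        result = {
            c.label: c
            for c in classify_candidates(dm, ["p0", "p1", "p2"])
        }
        assert result["p3"].category == CATEGORY_NEIGHBOURHOOD
        assert result["p3"].score == 0.0

    def test_zero_deviation_far_candidate_is_between(self):
        points = np.array(
            [[0.0, 0.0], [4.0, 0.0], [2.0, 8.0],   # refs
             [2.0, 0.0],                            # exact midpoint, far
             [0.3, 0.2], [3.8, 0.3], [1.9, 7.6]]
        )
        dm = euclidean_dm(points)
        result = {c.label: c for c in classify_candidates(dm, ["p0", "p1", "p2"])}
        assert result["p3"].deviation == 0.0
        assert result["p3"].category == CATEGORY_BETWEEN

    def test_scores_match_direct_recomputation(self, rng):
        points = rng.random((12, 2)) * 3
        dm = euclidean_dm(points)
        refs = ["p0", "p1", "p2"]
        for c in classify_candidates(dm, refs):
            dists = sorted(dm.d(c.label, r) for r in refs)
            assert c.nearest_ref_distance == pytest.approx(dists[0])
            assert c.margin == pytest.approx(dists[1] - dists[0])
            expected_dev = min(
                dm.d(a, c.label) + dm.d(c.label, b) - dm.d(a, b)
                for a, b in combinations(refs, 2)
            )
            assert c.deviation == pytest.approx(expected_dev)

    def test_single_reference_rejected(self):
        dm = euclidean_dm(np.arange(6).reshape(3, 2).astype(float))
        with pytest.raises(SelectionError, match="two references"):
            classify_candidates(dm, ["p0"])


class TestAssembleFamily:
    def _dm(self, rng, n):
        return euclidean_dm(rng.random((n, 2)) * 4)

    def test_pool_exactly_family_size_takes_everything(self, rng):
        dm = self._dm(rng, 15)
        fam = assemble_family(
            dm, dm.labels[:3], dm.labels, k=3, family_size=15, seed=0
        )
        assert set(fam.reference_ids) | set(fam.nonreference_ids) == set(dm.labels)
        assert not set(fam.reference_ids) & set(fam.nonreference_ids)

    def test_category_counts_within_one(self, rng):
        dm = self._dm(rng, 40)
        fam = assemble_family(
            dm, dm.labels[:5], dm.labels, k=3, family_size=25, seed=1
        )
        assert len(fam.nonreference_ids) == 22
        counts = fam.category_counts.values()
        assert max(counts) - min(counts) <= 1
        assert sum(counts) == 22

    def test_deterministic_given_seed(self, rng):
        dm = self._dm(rng, 30)
        one = assemble_family(dm, dm.labels[:4], dm.labels, k=3,
                              family_size=20, seed=9)
        two = assemble_family(dm, dm.labels[:4], dm.labels, k=3,
                              family_size=20, seed=9)
        assert one.reference_ids == two.reference_ids
        assert one.nonreference_ids == two.nonreference_ids

    def test_pool_shortfall_reported(self, rng):
        dm = self._dm(rng, 10)
        with pytest.raises(SelectionError, match="short"):
            assemble_family(dm, dm.labels[:3], dm.labels, k=3,
                            family_size=50, seed=0)
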