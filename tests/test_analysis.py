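"""Regression, slope-distribution, aligner-ranking and shuffling analyses."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from quantest2 import (
    SequenceRecord,
    fit_family_regression,
    rank_aligners,
    shuffle_inputs,
    slope_distribution,
)
from quantest2.analysis import AnalysisError


def ols_oracle(x, y):
    """Normal-equations fit, independent of the implementation."""
    X = np.column_stack([np.asarray(x, dtype=float), np.ones(len(x))])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, dtype=float))
    return beta[0], beta[1]


class TestFitFamilyRegression:
    def test_perfect_diagonal(self):
        fit = fit_family_regression([(0, 0), (0.5, 0.5), (1, 1)])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.rms_residual == pytest.approx(0.0)

    def test_two_points_exact(self):
        fit = fit_family_regression([(0.2, 0.9), (0.8, 0.3)])
        assert fit.slope == pytest.approx(-1.0)
        assert fit.rms_residual == pytest.approx(0.0)

    def test_matches_normal_equations_on_random_clouds(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.random(n)
            y = 0.5 * x + rng.normal(scale=0.1, size=n)
            fit = fit_family_regression(list(zip(x, y)))
            slope, intercept = ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_zero_variance_is_singular_without_slope(self):
        fit = fit_family_regression([(0.5, 0.1), (0.5, 0.9), (0.5, 0.4)])
        assert fit.singular and fit.slope is None

    def test_na_points_dropped(self):
        fit = fit_family_regression(
            [(0, 0), (None, 0.4), (float("nan"), 0.2), (1, 1)]
        )
        assert fit.n == 2 and fit.slope == pytest.approx(1.0)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(AnalysisError, match="at least 2"):
            fit_family_regression([(0.1, 0.2)])

    def test_scale_equivariance(self, rng):
        x = rng.random(20)
        y = rng.random(20)
        base = fit_family_regression(list(zip(x, y)))
        scaled = fit_family_regression(list(zip(x, 3.0 * y)))
        assert scaled.slope == pytest.approx(3.0 * base.slope)
        assert scaled.rms_residual == pytest.approx(3.0 * base.rms_residual)


class TestSlopeDistribution:
    def _summary(self, family, slope, singular=False):
        from quantest2 import RegressionSummary

        return RegressionSummary(
            family=family, n=5, slope=None if singular else slope,
            intercept=0.0 if not singular else None,
            rms_residual=0.0 if not singular else None,
            ss_residual=0.0 if not singular else None, singular=singular,
        )

    def test_negative_count(self):
        dist = slope_distribution(
            [self._summary("a", -1.0), self._summary("b", 1.0),
             self._summary("c", 2.0)]
        )
        assert dist.n_negative == 1
        assert dist.fraction_negative == pytest.approx(1 / 3)

    def test_all_positive(self):
        dist = slope_distribution(
            [self._summary("a", 0.5), self._summary("b", 1.5)]
        )
        assert dist.n_negative == 0

    def test_singular_families_tracked_separately(self):
        summaries = [
            self._summary("a", -0.5),
            self._summary("b", 0.5),
            self._summary("c", 0.0, singular=True),
        ]
        dist = slope_distribution(summaries)
        assert dist.n_singular == 1
        assert dist.slopes.size + dist.n_singular == dist.n_families

    def test_random_slopes_match_direct_count(self, rng):
        slopes = rng.normal(size=50)
        dist = slope_distribution(
            [self._summary(f"f{i}", s) for i, s in enumerate(slopes)]
        )
        assert dist.n_negative == int(np.sum(slopes < 0))
        assert np.all(np.diff(dist.slopes) >= 0)
        assert dist.cdf[-1] == 1.0

    def test_all_singular_rejected(self):
        with pytest.raises(AnalysisError, match="singular"):
            slope_distribution([self._summary("a", 0.0, singular=True)])


def score_frame(rows):
    return pd.DataFrame(
        rows, columns=["family", "aligner", "replicate", "sp", "sspa"]
    )


class TestRankAligners:
    def test_dominating_aligner_ranked_first(self):
        table = score_frame([
            ("f1", "A", 0, 0.9, 0.8), ("f1", "B", 0, 0.5, 0.4),
            ("f2", "A", 0, 0.8, 0.9), ("f2", "B", 0, 0.4, 0.5),
            ("f1", "C", 0, 0.7, 0.6), ("f2", "C", 0, 0.6, 0.7),
        ])
        ranking = rank_aligners(table)
        assert ranking.table.iloc[0]["aligner"] == "A"
        assert ranking.table.iloc[0]["rank_sp"] == 1.0
        assert ranking.table.iloc[0]["rank_sspa"] == 1.0

    def test_monotone_scores_give_perfect_spearman(self, rng):
        rows = []
        for i, aligner in enumerate("ABCDE"):
            sspa = 0.5 + 0.08 * i
            rows.append(("f1", aligner, 0, sspa ** 3, sspa))
        ranking = rank_aligners(score_frame(rows))
        assert ranking.spearman_rho == pytest.approx(1.0)

    def test_matches_textbook_formulas(self, rng):
        rows = []
        for family in ("f1", "f2", "f3"):
            for aligner in ("A", "B", "C", "D"):
                for rep in (0, 1):
                    rows.append(
                        (family, aligner, rep, rng.random(), rng.random())
                    )
        table = score_frame(rows)
        ranking = rank_aligners(table)
        # oracle: replicate means within family, then family means
        means = {}
        for aligner in "ABCD":
            sub = table[table["aligner"] == aligner]
            fam_means = sub.groupby("family")[["sp", "sspa"]].mean()
            means[aligner] = (fam_means["sp"].mean(), fam_means["sspa"].mean())
        got = ranking.table.set_index("aligner")
        for aligner, (sp_mean, sspa_mean) in means.items():
            assert got.loc[aligner, "mean_sp"] == pytest.approx(sp_mean)
            assert got.loc[aligner, "mean_sspa"] == pytest.approx(sspa_mean)
        xs = np.array([means[a][1] for a in "ABCD"])
        ys = np.array([means[a][0] for a in "ABCD"])
        r_oracle = np.corrcoef(xs, ys)[0, 1]
        assert ranking.pearson_r == pytest.approx(r_oracle, abs=1e-12)
        rho_oracle = np.corrcoef(
            stats.rankdata(xs), stats.rankdata(ys)
        )[0, 1]
        assert ranking.spearman_rho == pytest.approx(rho_oracle, abs=1e-12)

    def test_na_family_dropped_listwise(self):
        table = score_frame([
            ("f1", "A", 0, 0.9, 0.8), ("f1", "B", 0, None, 0.4),
            ("f2", "A", 0, 0.8, 0.9), ("f2", "B", 0, 0.4, 0.5),
            ("f1", "C", 0, 0.7, 0.6), ("f2", "C", 0, 0.6, 0.7),
        ])
        ranking = rank_aligners(table)
        assert ranking.n_families == 1  # f1 has an NA somewhere -> dropped

    def test_fewer_than_three_aligners_gives_na_correlations(self):
        table = score_frame([
            ("f1", "A", 0, 0.9, 0.8), ("f1", "B", 0, 0.5, 0.4),
        ])
        ranking = rank_aligners(table)
        assert ranking.pearson_r is None and ranking.spearman_rho is None


class TestShuffleInputs:
    def _records(self, n):
        return [SequenceRecord(f"s{i}", "ACDE") for i in range(n)]

    def test_zero_shuffles_returns_original_only(self):
        records = self._records(4)
        out = shuffle_inputs(records, 0, seed=1)
        assert out == [records]

    def test_original_always_first_and_count(self):
        records = self._records(5)
        out = shuffle_inputs(records, 7, seed=3)
        assert len(out) == 8
        assert out[0] == records
        for ordering in out:
            assert sorted(r.id for r in ordering) == sorted(r.id for r in records)

    def test_deterministic_given_seed(self):
        records = self._records(6)
        assert shuffle_inputs(records, 5, seed=9) == shuffle_inputs(records, 5, seed=9)

    def test_permutations_approximately_uniform(self):
        records = self._records(3)
        n_draws = 1200
        counts = {p: 0 for p in permutations(range(3))}
        orderings = shuffle_inputs(records, n_draws, seed=17)[1:]
        id_pos = {rec.id: i for i, rec in enumerate(records)}
        for ordering in orderings:
            counts[tuple(id_pos[r.id] for r in ordering)] += 1
        chi2, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3
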