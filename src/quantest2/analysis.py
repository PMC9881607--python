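"""Per-family SP-vs-SSPA regression, slope distributions and aligner ranking.

A benchmark is only coherent if its two accuracy measures agree.  For each
family we regress SP on SSPA over many alignments of the same sequences
(different aligners, options, or input-order shuffles); the slope sign and
residual size say whether the two scores rank alignments consistently for
that family.  Across aligners, per-aligner mean scores are compared with
Pearson and Spearman correlations.

The linear fit is ordinary least squares; for a model linear in its
parameters the iteratively fitted optimum coincides with the closed-form OLS
solution, so the closed form is used directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SequenceRecord


class AnalysisError(ValueError):
    """Invalid analysis input."""


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit of SP on SSPA for one family.

    ``singular`` marks families whose SSPA values have zero variance: the
    slope is undefined there and the family is excluded from slope
    statistics (recorded separately, never coerced to 0).
    """

    family: str
    n: int
    slope: Optional[float]
    intercept: Optional[float]
    rms_residual: Optional[float]
    ss_residual: Optional[float]
    singular: bool = False


def _clean_points(points: Iterable[tuple]) -> np.ndarray:
    arr = []
    for x, y in points:
        if x is None or y is None:
            continue
        x, y = float(x), float(y)
        if np.isnan(x) or np.isnan(y):
            continue
        arr.append((x, y))
    return np.array(arr, dtype=float).reshape(-1, 2)


def fit_family_regression(
    points: Iterable[tuple], family: str = ""
) -> RegressionSummary:
    """Least-squares line through (sspa, sp) points for one family.

    NA points are dropped first.  Zero SSPA variance gives a singular
    summary carrying no slope; fewer than two usable points is an error.
    """
    pts = _clean_points(points)
    n = len(pts)
    if n < 2:
        raise AnalysisError(f"family {family!r}: need at least 2 points, got {n}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0.0:
        return RegressionSummary(
            family=family, n=n, slope=None, intercept=None,
            rms_residual=None, ss_residual=None, singular=True,
        )
    xbar, ybar = x.mean(), y.mean()
    slope = float(np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2))
    intercept = float(ybar - slope * xbar)
    resid = y - (slope * x + intercept)
    ss = float(np.sum(resid ** 2))
    return RegressionSummary(
        family=family, n=n, slope=slope, intercept=intercept,
        rms_residual=float(np.sqrt(ss / n)), ss_residual=ss, singular=False,
    )


@dataclass(frozen=True)
class SlopeDistribution:
    """Empirical CDF of family regression slopes."""

    slopes: np.ndarray          # sorted
    cdf: np.ndarray             # P(slope <= slopes[i])
    n_negative: int
    fraction_negative: float
    n_singular: int
    n_families: int             # non-singular + singular


def slope_distribution(summaries: Sequence[RegressionSummary]) -> SlopeDistribution:
    """Cumulative slope distribution and the negative-slope tally.

    Singular families are counted separately and excluded from the CDF;
    where every family is singular there is no distribution to report.
    """
    n_singular = sum(1 for s in summaries if s.singular)
    slopes = np.sort([s.slope for s in summaries if not s.singular])
    if slopes.size == 0:
        raise AnalysisError("all families are singular; no slopes to summarize")
    cdf = np.arange(1, slopes.size + 1) / slopes.size
    n_neg = int(np.sum(slopes < 0))
    return SlopeDistribution(
        slopes=slopes,
        cdf=cdf,
        n_negative=n_neg,
        fraction_negative=n_neg / slopes.size,
        n_singular=n_singular,
        n_families=len(summaries),
    )


@dataclass(frozen=True)
class AlignerRanking:
    """Per-aligner mean scores with cross-aligner correlations.

    ``table`` has one row per aligner: replicate scores are averaged within
    each family first, then across families, over an identical family set
    for every aligner.  ``pooled_mean_*`` columns average all rows at once
    (the other reading of "averaged over families and re-samples").
    """

    table: pd.DataFrame
    pearson_r: Optional[float]
    spearman_rho: Optional[float]
    n_families: int


def rank_aligners(table: pd.DataFrame) -> AlignerRanking:
    """Rank aligners by mean SP and SSPA with correlation statistics.

    Families with any NA score for any aligner are dropped listwise so every
    aligner is averaged over the same families.  Correlations need at least
    three aligners, otherwise they are NA.  Spearman uses average ranks on
    ties.
    """
    required = {"family", "aligner", "sp", "sspa"}
    missing = required - set(table.columns)
    if missing:
        raise AnalysisError(f"score table missing columns {sorted(missing)}")
    df = table.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 0

    bad_families = df.loc[df["sp"].isna() | df["sspa"].isna(), "family"].unique()
    df = df[~df["family"].isin(bad_families)]
    if df.empty:
        raise AnalysisError("no families left after dropping NA-bearing ones")

    # every aligner must cover the same family set
    per_aligner = df.groupby("aligner")["family"].agg(lambda s: frozenset(s))
    common = frozenset.intersection(*per_aligner.tolist())
    df = df[df["family"].isin(common)]
    if df.empty:
        raise AnalysisError("aligners share no families")

    within = df.groupby(["aligner", "family"], sort=True)[["sp", "sspa"]].mean()
    means = within.groupby("aligner").mean().rename(
        columns={"sp": "mean_sp", "sspa": "mean_sspa"}
    )
    pooled = df.groupby("aligner")[["sp", "sspa"]].mean().rename(
        columns={"sp": "pooled_mean_sp", "sspa": "pooled_mean_sspa"}
    )
    out = means.join(pooled).reset_index()
    out["rank_sp"] = out["mean_sp"].rank(ascending=False, method="average")
    out["rank_sspa"] = out["mean_sspa"].rank(ascending=False, method="average")
    out = out.sort_values("mean_sp", ascending=False).reset_index(drop=True)

    if len(out) >= 3:
        pearson = float(stats.pearsonr(out["mean_sspa"], out["mean_sp"]).statistic)
        spearman = float(stats.spearmanr(out["mean_sspa"], out["mean_sp"]).statistic)
    else:
        pearson = spearman = None
    return AlignerRanking(
        table=out,
        pearson_r=pearson,
        spearman_rho=spearman,
        n_families=len(common),
    )


def shuffle_inputs(
    records: Sequence[SequenceRecord], n_shuffles: int, seed: int
) -> list[list[SequenceRecord]]:
    """Input-order resampling for alignment-instability experiments.

    Returns ``n_shuffles + 1`` orderings: the original order first, then
    seeded uniform permutations (content untouched).  Progressive aligners
    are order-sensitive, so each ordering yields one more alignment of the
    same sequences — e.g. 100 shuffles turn 1 input into 101 alignments.
    """
    records = list(records)
    if len(records) < 2:
        raise AnalysisError("need at least two records to shuffle")
    rng = np.random.default_rng(seed)
    out = [records[:]]
    for _ in range(n_shuffles):
        perm = rng.permutation(len(records))
        out.append([records[i] for i in perm])
    return out


def regressions_to_frame(summaries: Sequence[RegressionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [s.family for s in summaries],
            "n": [s.n for s in summaries],
            "slope": [s.slope for s in summaries],
            "intercept": [s.intercept for s in summaries],
            "rms_residual": [s.rms_residual for s in summaries],
            "ss_residual": [s.ss_residual for s in summaries],
            "singular": [s.singular for s in summaries],
        }
    )
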