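"""Dominance analysis of the regional multilinear models.

Dominance analysis decomposes a regression's explained variance into
per-predictor contributions: all 2^p - 1 non-empty predictor subsets are
fitted and, for each predictor, the incremental gain in adjusted R^2 from
adding it is averaged within each subset size and then across sizes
("total dominance"). Percent relative importance normalizes a predictor's
total dominance by the summed dominance of all predictors; the sum of
total dominances equals the full-model adjusted R^2 exactly.

Band contrasts across regions are assessed with a one-way ANOVA (regions
as observations, bands as groups) followed by all pairwise two-sample t
tests with Bonferroni correction and pooled-SD Cohen's d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import BandFCSet, ConnectivityMatrix
from .mapping import adjusted_r2

__all__ = [
    "DominanceResult",
    "BandContrastTable",
    "dominance_analysis",
    "dominance_all_regions",
    "band_contribution_anova",
]

logger = logging.getLogger(__name__)


@dataclass
class DominanceResult:
    """Per-predictor dominance decomposition for one target."""

    total_dominance: np.ndarray  # per-predictor average incremental gain
    percent_importance: np.ndarray  # per-predictor percentage (sums to 100)
    full_adj_r2: float
    n_submodels: int


@dataclass
class BandContrastTable:
    """One-way ANOVA plus all pairwise band contrasts."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    table: pd.DataFrame  # columns: pair, mean_diff, t, p_bonf, cohens_d


def _subset_adj_r2(y: np.ndarray, x: np.ndarray, mask: tuple[int, ...]) -> float:
    if not mask:
        return 0.0
    design = np.column_stack([np.ones(y.shape[0]), x[:, list(mask)]])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return adjusted_r2(r2, y.shape[0], len(mask))


def dominance_analysis(target: np.ndarray, predictors: np.ndarray) -> DominanceResult:
    """Classical dominance decomposition of one multilinear model.

    ``predictors`` is an (n, p) matrix; all 2^p - 1 non-empty subsets are
    fitted. Negative incremental gains are kept, so the total dominances
    sum exactly to the full-model adjusted R^2.
    """
    y = np.asarray(target, dtype=float)
    x = np.asarray(predictors, dtype=float)
    if x.ndim != 2 or y.shape[0] != x.shape[0]:
        raise ValueError("target and predictors must share the observation dimension")
    n, p = x.shape
    if n <= 8 or n <= p + 2:
        raise ValueError(f"too few observations (n={n}) for dominance over p={p}")

    fits: dict[tuple[int, ...], float] = {(): 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            fits[subset] = _subset_adj_r2(y, x, subset)

    total = np.empty(p)
    for k in range(p):
        size_means = []
        for size in range(p):  # size of the subset *before* adding k
            gains = [
                fits[tuple(sorted(subset + (k,)))] - fits[subset]
                for subset in combinations([q for q in range(p) if q != k], size)
            ]
            size_means.append(np.mean(gains))
        total[k] = np.mean(size_means)

    full = fits[tuple(range(p))]
    denom = total.sum()
    if denom != 0.0:
        percent = 100.0 * total / denom
    else:
        percent = np.full(p, np.nan)
    return DominanceResult(
        total_dominance=total,
        percent_importance=percent,
        full_adj_r2=full,
        n_submodels=len(fits) - 1,
    )


def dominance_all_regions(
    haemo: ConnectivityMatrix, bands: BandFCSet
) -> tuple[list[DominanceResult], np.ndarray, np.ndarray]:
    """Dominance decomposition for every regional model.

    Returns (per-region results, region x band percent-contribution map,
    most-dominant band label per region). Ties are broken by canonical
    band order with a logged note.
    """
    n = haemo.n
    names = np.array(bands.band_names)
    results: list[DominanceResult] = []
    contributions = np.empty((n, bands.n_bands))
    for i in range(n):
        res = dominance_analysis(haemo.row_profile(i), bands.profiles(i))
        results.append(res)
        contributions[i] = res.percent_importance
    winners = contributions.argmax(axis=1)
    n_ties = sum(
        (contributions[i] == contributions[i, winners[i]]).sum() > 1 for i in range(n)
    )
    if n_ties:
        logger.info("%d regions had tied top contributions; canonical band order used", n_ties)
    return results, contributions, names[winners]


def band_contribution_anova(
    contributions: np.ndarray, band_names: list[str] | None = None
) -> BandContrastTable:
    """One-way ANOVA and pairwise contrasts of per-region band contributions.

    ``contributions`` is a region x band table; regions are treated as
    observations and bands as groups. Pairwise two-tailed t tests are
    Bonferroni-corrected by the number of pairs; mean differences and
    Cohen's d (pooled SD) are reported as absolute values, t keeps its
    sign (first band minus second).
    """
    c = np.asarray(contributions, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("need a (regions >= 2) x (bands >= 2) contribution table")
    n_regions, n_bands = c.shape
    if band_names is None:
        band_names = [f"band{b}" for b in range(n_bands)]
    groups = [c[:, b] for b in range(n_bands)]
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance in all groups: F undefined")
    f_stat, p_val = stats.f_oneway(*groups)
    df_between = n_bands - 1
    df_within = n_bands * n_regions - n_bands

    pairs = list(combinations(range(n_bands), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        t, p = stats.ttest_ind(ga, gb, equal_var=True)
        pooled = np.sqrt(
            ((ga.shape[0] - 1) * ga.var(ddof=1) + (gb.shape[0] - 1) * gb.var(ddof=1))
            / (ga.shape[0] + gb.shape[0] - 2)
        )
        d = abs(ga.mean() - gb.mean()) / pooled if pooled > 0 else 0.0
        rows.append(
            {
                "pair": f"{band_names[a]} vs {band_names[b]}",
                "mean_diff": abs(ga.mean() - gb.mean()),
                "t": float(t),
                "p_bonf": min(1.0, float(p) * m),
                "cohens_d": float(d),
            }
        )
    return BandContrastTable(
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=float(p_val),
        table=pd.DataFrame(rows),
    )
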