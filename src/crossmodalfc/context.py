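"""Microarchitectural and hierarchical context statistics.

Contains the diffusion-map principal functional gradient (the
unimodal-to-transmodal hierarchy axis), per-region structure-function
coupling, depth-wise association of a map with laminar staining-intensity
profiles (with spin p values and FDR), and the expression-panel utilities:
robust-sigmoid normalization, unit-interval rescaling, cross-donor
differential stability, and map-expression association tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csgraph

from .datatypes import ConnectivityMatrix
from .nulls import NullTestResult, SpinEnsemble, bh_fdr, spin_pvalue
from .synthetic import DepthProfileSet, ExpressionPanel

__all__ = [
    "GradientMap",
    "DepthAssociation",
    "principal_gradient",
    "structure_function_coupling",
    "depth_profile_association",
    "robust_sigmoid",
    "unit_rescale",
    "differential_stability",
    "expression_map_association",
]

logger = logging.getLogger(__name__)


@dataclass
class GradientMap:
    """Per-region score on one diffusion-embedding component."""

    scores: np.ndarray
    component: int
    eigenvalue: float


@dataclass
class DepthAssociation:
    """Depth-wise map-profile correlations with spin inference."""

    correlations: np.ndarray  # one rank correlation per depth
    p_spin: np.ndarray
    fdr_mask: np.ndarray
    fdr_threshold: float


def _threshold_rows(values: np.ndarray, keep_frac: float = 0.10) -> np.ndarray:
    """Keep the top ``keep_frac`` of each row's off-diagonal values by rank
    (ties broken by index order); everything else, negatives included, is
    zeroed."""
    n = values.shape[0]
    k = max(1, int(np.ceil(keep_frac * (n - 1))))
    out = np.zeros_like(values)
    for i in range(n):
        row = values[i].copy()
        row[i] = -np.inf
        top = np.argsort(-row, kind="stable")[:k]
        out[i, top] = values[i, top]
    return out


def principal_gradient(
    fc: ConnectivityMatrix,
    anchor: np.ndarray | None = None,
    component: int = 1,
    alpha: float = 0.5,
) -> GradientMap:
    """Principal axis of variation of a functional connectivity matrix.

    Each row is thresholded to its top 10% of connections, pairwise cosine
    similarity of the thresholded rows is computed and negative
    similarities are clipped to zero, and a diffusion-map embedding
    (anisotropic normalization ``alpha``; eigenvalue-scaled automatic
    diffusion time) of the resulting affinity matrix is returned as its
    first non-trivial component.

    The sign is aligned so the correlation with ``anchor`` is positive
    when an anchor map is given; otherwise the entry of largest magnitude
    is made positive.
    """
    n = fc.n
    if n < 10:
        raise ValueError("need at least 10 regions")
    thr = _threshold_rows(fc.values)
    norms = np.linalg.norm(thr, axis=1)
    if (norms == 0).any():
        raise ValueError(
            f"empty thresholded profile for region(s) {np.flatnonzero(norms == 0).tolist()}"
        )
    affinity = (thr / norms[:, None]) @ (thr / norms[:, None]).T
    affinity = np.clip(affinity, 0.0, None)
    np.fill_diagonal(affinity, 1.0)

    n_comp, labels = csgraph.connected_components(affinity > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        logger.warning(
            "affinity graph is disconnected into %d components (sizes %s); "
            "uniform epsilon regularization makes the diffusion chain "
            "irreducible, so the leading component separates the islands",
            n_comp,
            sizes.tolist(),
        )
    # tiny uniform offset: keeps the chain irreducible (deterministic
    # embedding even for block-diagonal affinities), negligible otherwise
    affinity = affinity + 1e-8

    d = affinity.sum(axis=1)
    l_alpha = affinity / np.outer(d, d) ** alpha
    d_alpha = l_alpha.sum(axis=1)
    # symmetric conjugate of the Markov matrix diag(d_alpha)^-1 L
    s = l_alpha / np.sqrt(np.outer(d_alpha, d_alpha))
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / np.sqrt(d_alpha)[:, None]
    psi = psi / psi[:, 0][:, None]  # normalize by the trivial component
    lam = evals[component]
    scores = psi[:, component] * (lam / (1.0 - lam))

    if anchor is not None:
        anchor = np.asarray(anchor, dtype=float)
        if np.corrcoef(scores, anchor)[0, 1] < 0:
            scores = -scores
    elif scores[np.argmax(np.abs(scores))] < 0:
        scores = -scores
    return GradientMap(scores=scores, component=component, eigenvalue=float(lam))


def structure_function_coupling(
    sc: ConnectivityMatrix, fc: ConnectivityMatrix
) -> np.ndarray:
    """Per-region Spearman correlation between structural and functional
    profiles, restricted to edges with nonzero structural weight.

    Regions with fewer than 3 nonzero structural connections get NaN and a
    logged warning.
    """
    if sc.n != fc.n:
        raise ValueError("structural and functional parcellations must agree")
    if (sc.values < 0).any():
        raise ValueError("structural connectivity must be non-negative")
    n = sc.n
    out = np.empty(n)
    for i in range(n):
        s_row = sc.row_profile(i)
        f_row = fc.row_profile(i)
        nz = np.flatnonzero(s_row != 0)
        if nz.size < 3:
            logger.warning(
                "region %d has %d nonzero structural connections; coupling undefined",
                i,
                nz.size,
            )
            out[i] = np.nan
            continue
        out[i] = stats.spearmanr(s_row[nz], f_row[nz]).statistic
    return out


def depth_profile_association(
    region_map: np.ndarray,
    profiles: DepthProfileSet,
    spins: SpinEnsemble,
    alpha: float = 0.05,
) -> DepthAssociation:
    """Rank-correlate a region map with staining intensity at every depth.

    Each depth gets a spin p value (shared ensemble, two-tailed); the
    family of depth comparisons is BH-FDR controlled at ``alpha``.
    """
    region_map = np.asarray(region_map, dtype=float)
    if region_map.shape[0] != profiles.values.shape[0]:
        raise ValueError("map and depth profiles disagree on region count")
    n_depths = profiles.n_depths
    corrs = np.empty(n_depths)
    pvals = np.empty(n_depths)
    for d in range(n_depths):
        res = spin_pvalue(region_map, profiles.values[:, d], spins)
        corrs[d] = res.r
        pvals[d] = res.p_spin
    mask, crit = bh_fdr(pvals, alpha)
    return DepthAssociation(
        correlations=corrs, p_spin=pvals, fdr_mask=mask, fdr_threshold=crit
    )


def robust_sigmoid(x: np.ndarray) -> np.ndarray:
    """Outlier-robust sigmoid normalization.

    ``1 / (1 + exp(-(x - median) / iqr_n))`` with ``iqr_n`` the
    interquartile range divided by 1.349 (the IQR of a standard normal),
    so the scale estimate is consistent with a standard deviation.
    """
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = (q3 - q1) / 1.349
    if iqr == 0:
        raise ValueError("zero interquartile range: robust sigmoid undefined")
    return 1.0 / (1.0 + np.exp(-(x - med) / iqr))


def unit_rescale(x: np.ndarray) -> np.ndarray:
    """Affine rescaling to the unit interval: (x - min) / (max - min)."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant input cannot be rescaled to the unit interval")
    return (x - lo) / (hi - lo)


def differential_stability(panel: ExpressionPanel, gene: str) -> float:
    """Mean cross-donor Spearman correlation of a gene's regional pattern.

    Averages the rank correlation over all donor pairs; pairs involving a
    donor with a constant pattern are excluded with a warning.
    """
    g = panel.gene_index(gene)
    patterns = panel.values[:, :, g]  # (n_donors, N)
    n_donors = patterns.shape[0]
    vals = []
    for i in range(n_donors - 1):
        for j in range(i + 1, n_donors):
            if np.ptp(patterns[i]) == 0 or np.ptp(patterns[j]) == 0:
                logger.warning(
                    "constant pattern for donor pair (%d, %d); pair excluded", i, j
                )
                continue
            vals.append(stats.spearmanr(patterns[i], patterns[j]).statistic)
    if not vals:
        raise ValueError(f"no valid donor pairs for gene {gene!r}")
    return float(np.mean(vals))


def expression_map_association(
    region_map: np.ndarray,
    panel: ExpressionPanel,
    gene: str,
    spins: SpinEnsemble,
) -> NullTestResult:
    """Spin-tested rank correlation between a region map and the
    donor-averaged, normalized regional expression of one gene.

    Each donor's regional pattern is robust-sigmoid normalized and
    rescaled to the unit interval before averaging across donors.
    """
    region_map = np.asarray(region_map, dtype=float)
    g = panel.gene_index(gene)
    normed = np.stack(
        [unit_rescale(robust_sigmoid(panel.values[k, :, g])) for k in range(panel.values.shape[0])]
    )
    expression = normed.mean(axis=0)
    if region_map.shape != expression.shape:
        raise ValueError("map and panel disagree on region count")
    return spin_pvalue(region_map, expression, spins)
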