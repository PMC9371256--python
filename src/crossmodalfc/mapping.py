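"""Region-wise and global multilinear cross-modal mapping.

For each region i the haemodynamic connectivity profile (row i of the
haemodynamic matrix, self connection excluded) is regressed on the six
band-limited electromagnetic profiles of the same region:

    FC_i = b1 FC(delta)_i + b2 FC(theta)_i + b3 FC(alpha)_i
         + b4 FC(beta)_i + b5 FC(lo-gamma)_i + b6 FC(hi-gamma)_i + b0

Goodness of fit is the adjusted coefficient of determination with
n = N - 1 observations and p = 6 predictors. A single global variant fits
the N(N-1)/2 upper-triangle edges of all matrices at once, and
single-predictor variants fit each band separately.

Predictors and target enter on their raw correlation scales (adjusted R^2
is scale invariant); negative edges are retained. Rank-deficient designs
fall back to the minimum-norm least-squares solution with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import BandFCSet, ConnectivityMatrix

__all__ = [
    "RegionalModelResult",
    "GlobalModelResult",
    "regional_profile",
    "fit_regional_model",
    "fit_all_regions",
    "fit_global_model",
    "fit_band_specific_models",
    "adjusted_r2",
]

logger = logging.getLogger(__name__)


@dataclass
class RegionalModelResult:
    """OLS fit of one region's cross-modal model."""

    region: int
    coefficients: np.ndarray  # b0 (intercept), b1..b6 in band order
    r2: float
    adj_r2: float
    predicted_profile: np.ndarray  # length N-1, off-diagonal order of region i


@dataclass
class GlobalModelResult:
    """OLS fit of the edge-wise global model."""

    coefficients: np.ndarray
    r2: float
    adj_r2: float
    predicted_upper_triangle: np.ndarray


def adjusted_r2(r2: float, n_obs: int, n_predictors: int) -> float:
    """Ezekiel-adjusted coefficient of determination.

    ``1 - (1 - r2) (n - 1) / (n - p - 1)``; with p = 0 the statistic is
    returned unchanged.
    """
    if n_obs <= n_predictors + 1:
        raise ValueError(
            f"need n_obs > n_predictors + 1 (got n={n_obs}, p={n_predictors})"
        )
    if n_predictors == 0:
        return float(r2)
    return float(1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - n_predictors - 1))


def regional_profile(matrix: ConnectivityMatrix, i: int) -> np.ndarray:
    """Row ``i`` with the diagonal element removed, region order preserved."""
    return matrix.row_profile(i)


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares of y on [1, x]; returns (beta, fitted, r2).

    Rank deficiency yields the minimum-norm solution and a logged warning.
    """
    design = np.column_stack([np.ones(y.shape[0]), x])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d); minimum-norm solution used",
            rank,
            design.shape[1],
        )
    fitted = design @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return beta, fitted, r2


def fit_regional_model(
    haemo: ConnectivityMatrix, bands: BandFCSet, i: int
) -> RegionalModelResult:
    """Fit the six-band multilinear model for region ``i``."""
    if haemo.n != bands.n:
        raise ValueError(
            f"parcellation mismatch: haemodynamic N={haemo.n}, bands N={bands.n}"
        )
    n_obs = haemo.n - 1
    p = bands.n_bands
    if n_obs <= p + 1:
        raise ValueError(f"too few observations ({n_obs}) for {p} predictors")
    y = haemo.row_profile(i)
    x = bands.profiles(i)
    beta, fitted, r2 = _ols(y, x)
    return RegionalModelResult(
        region=i,
        coefficients=beta,
        r2=r2,
        adj_r2=adjusted_r2(r2, n_obs, p),
        predicted_profile=fitted,
    )


def fit_all_regions(
    haemo: ConnectivityMatrix, bands: BandFCSet
) -> tuple[list[RegionalModelResult], np.ndarray]:
    """Fit every region; the adjusted-R^2 vector is the cross-modal
    correspondence map."""
    results = [fit_regional_model(haemo, bands, i) for i in range(haemo.n)]
    r2_map = np.array([r.adj_r2 for r in results])
    return results, r2_map


def fit_global_model(haemo: ConnectivityMatrix, bands: BandFCSet) -> GlobalModelResult:
    """Single fit on the N(N-1)/2 upper-triangle edges of all matrices."""
    if haemo.n != bands.n:
        raise ValueError("parcellation mismatch between haemodynamic and band matrices")
    if haemo.n < 5:
        raise ValueError("need at least 5 regions for the global model")
    y = haemo.upper_triangle()
    x = np.column_stack([m.upper_triangle() for m in bands.matrices])
    beta, fitted, r2 = _ols(y, x)
    return GlobalModelResult(
        coefficients=beta,
        r2=r2,
        adj_r2=adjusted_r2(r2, y.shape[0], x.shape[1]),
        predicted_upper_triangle=fitted,
    )


def fit_band_specific_models(
    haemo: ConnectivityMatrix, bands: BandFCSet
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Single-predictor regional fits per band.

    Returns (adjusted maps, unadjusted maps), each a dict keyed by band
    name holding a length-N vector.
    """
    n = haemo.n
    n_obs = n - 1
    adj_maps: dict[str, np.ndarray] = {}
    raw_maps: dict[str, np.ndarray] = {}
    for band, matrix in bands:
        adj = np.empty(n)
        raw = np.empty(n)
        for i in range(n):
            y = haemo.row_profile(i)
            x = matrix.row_profile(i)[:, None]
            _, _, r2 = _ols(y, x)
            raw[i] = r2
            adj[i] = adjusted_r2(r2, n_obs, 1)
        adj_maps[band.name] = adj
        raw_maps[band.name] = raw
    return adj_maps, raw_maps
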