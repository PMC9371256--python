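"""Spatial-autocorrelation-preserving spin null models and FDR control.

A spin null draws a uniform random 3-D rotation, applies it to one
hemisphere's unit-sphere parcel coordinates and the midline-mirrored
rotation to the other hemisphere, and reassigns each parcel the value of
the original parcel nearest to its rotated position (within hemisphere;
duplicates permitted). Correlating spun copies of one map with the intact
other map yields a null distribution that preserves each map's spatial
autocorrelation.

The permutation p value uses the (1 + k) / (n + 1) convention on absolute
correlations (two-tailed), so p is never zero. Benjamini-Hochberg step-up
FDR control is provided for families of such tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .datatypes import ParcelGeometry

__all__ = [
    "SpinEnsemble",
    "NullTestResult",
    "generate_spins",
    "spin_pvalue",
    "bh_fdr",
]


@dataclass
class SpinEnsemble:
    """Nearest-parcel reassignment indices from random sphere rotations.

    ``assignment[k, j]`` is the parcel whose value parcel ``j`` takes in
    null repetition ``k``.
    """

    assignment: np.ndarray  # (n_spin, N) integer table
    seed: int
    n_spin: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment)
        if self.assignment.ndim != 2:
            raise ValueError("assignment must be (n_spin, N)")
        n = self.assignment.shape[1]
        if self.assignment.min() < 0 or self.assignment.max() >= n:
            raise ValueError("assignment indices out of range")

    @property
    def n(self) -> int:
        return self.assignment.shape[1]

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Spun copies of ``values``: one row per repetition."""
        return np.asarray(values)[self.assignment]


@dataclass
class NullTestResult:
    """Empirical map-map correlation with its spin-null distribution."""

    r: float
    nulls: np.ndarray
    p_spin: float
    method: str = "spearman"


def rotation_assignment(geometry: ParcelGeometry, rotation: np.ndarray) -> np.ndarray:
    """Nearest-parcel reassignment for one rotation matrix.

    The rotation is applied to the right hemisphere and its midline mirror
    (x -> -x conjugation) to the left, so the two hemispheres rotate as
    mirror images. For each parcel j, ``out[j]`` is the index of the
    original same-hemisphere parcel closest to j's rotated position.
    """
    mirror = np.diag([-1.0, 1.0, 1.0])
    out = np.empty(geometry.n, dtype=np.intp)
    for hemi, rot in (("R", rotation), ("L", mirror @ rotation @ mirror)):
        idx = geometry.indices(hemi)
        if idx.size == 0:
            raise ValueError(f"hemisphere {hemi} is empty")
        coords = geometry.coords[idx]
        tree = cKDTree(coords)
        _, nearest = tree.query(coords @ rot.T)
        out[idx] = idx[nearest]
    return out


def generate_spins(geometry: ParcelGeometry, n_spin: int, seed: int = 0) -> SpinEnsemble:
    """Ensemble of ``n_spin`` hemisphere-respecting spin reassignments.

    Rotations are drawn from the Haar (uniform) measure on SO(3).
    """
    if n_spin < 1:
        raise ValueError("n_spin must be >= 1")
    rng = np.random.default_rng([7, seed & 0x7FFFFFFF])
    rotations = stats.special_ortho_group.rvs(3, size=n_spin, random_state=rng)
    if n_spin == 1:
        rotations = rotations[None]
    mirror = np.diag([-1.0, 1.0, 1.0])
    assignment = np.empty((n_spin, geometry.n), dtype=np.intp)
    for hemi in ("R", "L"):
        idx = geometry.indices(hemi)
        coords = geometry.coords[idx]
        tree = cKDTree(coords)
        rots = rotations if hemi == "R" else mirror @ rotations @ mirror
        # (n_spin, m, 3) rotated positions, queried in one batch
        rotated = np.einsum("kab,mb->kma", rots, coords)
        _, nearest = tree.query(rotated.reshape(-1, 3))
        assignment[:, idx] = idx[nearest.reshape(n_spin, idx.size)]
    return SpinEnsemble(assignment=assignment, seed=seed, n_spin=n_spin)


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def _row_correlations(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    rows = rows - rows.mean(axis=1, keepdims=True)
    vec = vec - vec.mean()
    denom = np.sqrt((rows**2).sum(axis=1) * (vec**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rows @ vec) / denom


def spin_pvalue(
    map_a: np.ndarray,
    map_b: np.ndarray,
    spins: SpinEnsemble,
    method: str = "spearman",
) -> NullTestResult:
    """Two-tailed spin-permutation test of a map-map association.

    The null distribution correlates spun copies of ``map_a`` with the
    intact ``map_b``; ``p = (1 + #{|r_null| >= |r_emp|}) / (n_spin + 1)``.
    Rank correlation by default; ``method="pearson"`` for product-moment.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be equal-length 1-D vectors")
    if a.shape[0] != spins.n:
        raise ValueError("maps and spin ensemble disagree on parcellation size")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("maps must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant map: correlation undefined")
    if method == "spearman":
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        emp = _row_correlations(ra[None], rb)[0]
        spun = _rank_rows(spins.apply(a))
        nulls = _row_correlations(spun, rb)
    elif method == "pearson":
        emp = _row_correlations(a[None], b)[0]
        nulls = _row_correlations(spins.apply(a), b)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    nulls = np.nan_to_num(nulls, nan=0.0)
    k = int(np.sum(np.abs(nulls) >= abs(emp)))
    p = (1.0 + k) / (spins.n_spin + 1.0)
    return NullTestResult(r=float(emp), nulls=nulls, p_spin=float(p), method=method)


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up procedure.

    Returns a boolean rejection mask aligned to the input order and the
    critical p threshold ``(k / m) * alpha`` of the largest passing rank
    (0.0 when nothing is rejected).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if not np.isfinite(p).all():
        raise ValueError("non-finite p values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = (np.arange(1, m + 1) / m) * alpha
    passing = np.flatnonzero(ranked <= thresholds)
    mask = np.zeros(m, dtype=bool)
    if passing.size == 0:
        return mask, 0.0
    k = passing[-1]
    mask[order[: k + 1]] = True
    return mask, float(thresholds[k])
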