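"""Core containers shared across the package.

Conventions
-----------
* Connectivity matrices are dense N x N arrays. The diagonal (self
  connection) is excluded from every analysis; it is stored as 0.
* Parcel coordinates live on the unit sphere, one hemisphere mirrored
  to the other across the x = 0 midline (left: x < 0, right: x > 0).
* The six canonical electrophysiological bands are fixed in the order
  delta, theta, alpha, beta, low gamma, high gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FrequencyBand",
    "CANONICAL_BANDS",
    "ParcelTimeSeries",
    "ConnectivityMatrix",
    "BandFCSet",
    "ParcelGeometry",
    "SYMMETRY_TOL",
]

#: tolerance used when validating matrix symmetry
SYMMETRY_TOL = 1e-12


@dataclass(frozen=True)
class FrequencyBand:
    """A frequency band with inclusive edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"invalid band {self.name!r}: need 0 < lo < hi, got "
                f"lo={self.lo}, hi={self.hi}"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


#: Canonical six electrophysiological bands (Hz).
CANONICAL_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 2.0, 4.0),
    FrequencyBand("theta", 5.0, 7.0),
    FrequencyBand("alpha", 8.0, 12.0),
    FrequencyBand("beta", 15.0, 29.0),
    FrequencyBand("lo-gamma", 30.0, 59.0),
    FrequencyBand("hi-gamma", 60.0, 90.0),
)

CANONICAL_BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)


@dataclass
class ParcelTimeSeries:
    """Region x sample real-valued time series with a sampling rate."""

    values: np.ndarray
    fs: float
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (regions x samples) array")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.labels is None:
            self.labels = [f"region{i:03d}" for i in range(self.values.shape[0])]
        elif len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match region count")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class ConnectivityMatrix:
    """Symmetric region-pair association values with a modality tag.

    The diagonal is excluded from all analyses and stored as 0.
    """

    values: np.ndarray
    modality: str = "haemodynamic"
    band: Optional[FrequencyBand] = None
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        off = ~np.eye(self.values.shape[0], dtype=bool)
        if not np.isfinite(self.values[off]).all():
            raise ValueError("non-finite off-diagonal connectivity values")
        asym = np.abs(self.values - self.values.T).max() if self.values.size else 0.0
        if asym > SYMMETRY_TOL:
            i, j = np.unravel_index(
                np.abs(self.values - self.values.T).argmax(), self.values.shape
            )
            raise ValueError(
                f"asymmetric connectivity matrix: entry ({i},{j}) differs from "
                f"({j},{i}) by {asym:.3g}"
            )
        if self.labels is None:
            self.labels = [f"region{i:03d}" for i in range(self.values.shape[0])]
        elif len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def row_profile(self, i: int) -> np.ndarray:
        """Row ``i`` with the self connection removed (length N-1)."""
        if not (0 <= i < self.n):
            raise IndexError(f"region index {i} out of range for N={self.n}")
        return np.delete(self.values[i], i)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class BandFCSet:
    """Ordered set of band-limited connectivity matrices on one parcellation."""

    bands: Sequence[FrequencyBand]
    matrices: Sequence[ConnectivityMatrix]

    def __post_init__(self) -> None:
        if len(self.bands) != len(self.matrices):
            raise ValueError("one matrix per band required")
        sizes = {m.n for m in self.matrices}
        if len(sizes) > 1:
            raise ValueError(f"band matrices disagree on parcellation size: {sizes}")

    @property
    def n(self) -> int:
        return self.matrices[0].n

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]

    def __iter__(self):
        return iter(zip(self.bands, self.matrices))

    def __getitem__(self, key):
        if isinstance(key, int):
            return self.matrices[key]
        for b, m in zip(self.bands, self.matrices):
            if b.name == key:
                return m
        raise KeyError(key)

    def profiles(self, i: int) -> np.ndarray:
        """(N-1) x n_bands design block: band profiles of region ``i``."""
        return np.column_stack([m.row_profile(i) for m in self.matrices])


@dataclass
class ParcelGeometry:
    """Parcel centroids on the unit sphere with hemisphere labels."""

    coords: np.ndarray
    hemispheres: np.ndarray
    ids: Optional[Sequence[str]] = None
    _dist: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.hemispheres = np.asarray(self.hemispheres)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if self.hemispheres.shape[0] != self.coords.shape[0]:
            raise ValueError("hemisphere labels must match coordinate count")
        bad = set(np.unique(self.hemispheres)) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere labels must be 'L'/'R', got {bad}")
        norms = np.linalg.norm(self.coords, axis=1)
        if np.abs(norms - 1.0).max() > 1e-9:
            raise ValueError("parcel coordinates must be unit norm (±1e-9)")
        if (self.hemispheres == "L").sum() == 0 or (self.hemispheres == "R").sum() == 0:
            raise ValueError("both hemispheres must be non-empty")
        if self.ids is None:
            self.ids = [f"parcel{i:03d}" for i in range(self.coords.shape[0])]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def indices(self, hemisphere: str) -> np.ndarray:
        return np.flatnonzero(self.hemispheres == hemisphere)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean (chord) distances between parcel centroids."""
        if self._dist is None:
            diff = self.coords[:, None, :] - self.coords[None, :, :]
            self._dist = np.sqrt((diff**2).sum(-1))
        return self._dist
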