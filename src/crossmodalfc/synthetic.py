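"""Synthetic multimodal connectivity data with planted ground truth.

Every input the analysis pipeline consumes can be generated here with a
known answer: six band-limited electromagnetic connectivity matrices with
distance-dependent decay and smooth band-specific spatial structure, a
haemodynamic matrix built as a region-wise linear mixture of the band
matrices with regionally heterogeneous noise graded along a synthetic
unimodal-to-transmodal hierarchy, subject ensembles around the group mean,
laminar staining-intensity depth profiles, a multi-donor expression panel,
a sparse structural matrix, and narrowband time series with planted
envelope-coupled and phase-locked pairs.

The analytic target R^2 of each region (signal variance over signal plus
noise variance, computed from the noiseless mixture) serves as an exact
recovery oracle for the downstream regional regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .datatypes import (
    CANONICAL_BANDS,
    BandFCSet,
    ConnectivityMatrix,
    FrequencyBand,
    ParcelGeometry,
    ParcelTimeSeries,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "DepthProfileSet",
    "ExpressionPanel",
    "make_geometry",
    "make_band_fc_set",
    "make_crossmodal_truth",
    "make_subject_ensemble",
    "make_context_maps",
    "make_band_timeseries",
    "smooth_field",
]

# per-operation stream identifiers so each operation draws from its own
# deterministic child of the configured seed
_STREAM_GEOMETRY = 1
_STREAM_BAND_FC = 2
_STREAM_TRUTH = 3
_STREAM_SUBJECTS = 4
_STREAM_CONTEXT = 5
_STREAM_TIMESERIES = 6

# default mixing profile across the six canonical bands: beta dominates,
# followed by theta and alpha; gamma bands contribute least
_BASE_WEIGHTS = np.array([0.10, 0.16, 0.14, 0.30, 0.08, 0.06])
# relative tilt of each weight along the hierarchy (smooth variation)
_WEIGHT_TILT = np.array([0.50, 0.25, -0.20, -0.45, 0.30, 0.40])
# overall signal amplitude declines along the hierarchy: transmodal
# regions carry genuinely weaker cross-modal signal
_AMPLITUDE_SPAN = (1.4, 0.8)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Parameters
    ----------
    n_parcels : even integer >= 10, split equally across hemispheres.
    band_names : six band labels (canonical order by default).
    decay_length : distance constant of the connectivity decay, in
        unit-sphere chord units (the sphere has radius 1).
    weight_smoothness : spatial correlation length of the smooth fields
        behind mixing weights, hierarchy, and context maps.
    fc_amplitude : amplitude of the distance-decaying connectivity mean.
    mod_amplitude : amplitude of the band-specific smooth modulation.
    edge_noise_sd : SD of symmetric edge noise in the band matrices.
    noise_profile : "constant" or "graded" (noise SD increases along the
        hierarchy, so model fit decreases toward transmodal regions).
    noise_sd : per-edge haemodynamic noise SD for the constant profile.
    noise_range : (low, high) noise SD at the two hierarchy extremes for
        the graded profile (quadratic grading along the hierarchy).
    n_subjects : ensemble size for subject-level analyses.
    subject_noise_sd : per-edge SD of subject deviations from the group.
    seed : integer controlling all randomness.
    """

    n_parcels: int = 200
    band_names: Sequence[str] = field(default_factory=lambda: [b.name for b in CANONICAL_BANDS])
    decay_length: float = 0.5
    weight_smoothness: float = 0.5
    fc_amplitude: float = 0.6
    mod_amplitude: float = 0.2
    edge_noise_sd: float = 0.15
    noise_profile: str = "graded"
    noise_sd: float = 0.1
    noise_range: tuple[float, float] = (0.0, 0.5)
    n_subjects: int = 10
    subject_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parcels < 10 or self.n_parcels % 2:
            raise ValueError("n_parcels must be even and >= 10")
        if len(self.band_names) != 6:
            raise ValueError("exactly six band names required")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if self.noise_profile not in ("constant", "graded"):
            raise ValueError("noise_profile must be 'constant' or 'graded'")
        if self.noise_sd < 0 or min(self.noise_range) < 0 or self.edge_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def bands(self) -> tuple[FrequencyBand, ...]:
        canon = {b.name: b for b in CANONICAL_BANDS}
        return tuple(
            canon.get(name, FrequencyBand(name, 1.0, 2.0)) for name in self.band_names
        )


@dataclass
class GroundTruth:
    """Planted generative quantities behind a synthetic haemodynamic matrix."""

    weights: np.ndarray  # (N, 6) region x band mixing coefficients
    noise_sd: np.ndarray  # (N,) per-region haemodynamic noise scale
    hierarchy: np.ndarray  # (N,) synthetic unimodal->transmodal axis in [0, 1]
    target_r2: np.ndarray  # (N,) analytic expected variance explained

    def __post_init__(self) -> None:
        n = self.weights.shape[0]
        if not (self.noise_sd.shape[0] == self.hierarchy.shape[0] == self.target_r2.shape[0] == n):
            raise ValueError("ground-truth arrays must share the region dimension")
        if self.target_r2.min() < -1e-12 or self.target_r2.max() > 1 + 1e-12:
            raise ValueError("target_r2 must lie in [0, 1]")


@dataclass
class DepthProfileSet:
    """Region x depth staining-intensity profiles (50 depths by default)."""

    values: np.ndarray
    peak_depth: int

    @property
    def n_depths(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionPanel:
    """Donor-indexed region x gene expression matrices."""

    values: np.ndarray  # (n_donors, N, n_genes)
    genes: Sequence[str]
    donors: Sequence[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("expression panel must be (donors, regions, genes)")
        if self.values.shape[0] < 2:
            raise ValueError("need >= 2 donors")
        if self.values.shape[2] != len(self.genes):
            raise ValueError("gene labels must match the gene dimension")

    def gene_index(self, gene: str) -> int:
        try:
            return list(self.genes).index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in panel") from None

    def donor_matrix(self, k: int) -> np.ndarray:
        return self.values[k]


def _rng(stream: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed & 0x7FFFFFFF])


def make_geometry(n_parcels: int, seed: int = 0) -> ParcelGeometry:
    """Quasi-uniform parcel centroids on the unit sphere, mirrored hemispheres.

    One hemisphere (x > 0, labelled "R") is filled with a Fibonacci lattice
    randomly rotated about the mirror axis; the other hemisphere is its
    exact mirror image (-x, y, z).
    """
    if n_parcels < 10 or n_parcels % 2:
        raise ValueError("n_parcels must be even and >= 10")
    rng = _rng(_STREAM_GEOMETRY, seed)
    m = n_parcels // 2
    i = np.arange(m)
    # uniform-area Fibonacci lattice on the x > 0 hemisphere
    x = (i + 0.5) / m
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = phi0 + i * golden
    r = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    right = np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])
    right /= np.linalg.norm(right, axis=1, keepdims=True)
    left = right * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([left, right])
    hemis = np.array(["L"] * m + ["R"] * m)
    return ParcelGeometry(coords=coords, hemispheres=hemis)


def smooth_field(
    geometry: ParcelGeometry, length: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with spatial correlation
    length ``length`` (squared-exponential kernel on chord distance)."""
    d = geometry.distance_matrix()
    k = np.exp(-(d**2) / (2.0 * length**2))
    k[np.diag_indices_from(k)] += 1e-8
    chol = np.linalg.cholesky(k)
    f = chol @ rng.standard_normal(geometry.n)
    f = (f - f.mean()) / f.std()
    return f


def _symmetric_noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric matrix with iid N(0, sd^2) entries on each off-diagonal pair."""
    e = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    e[iu] = rng.normal(0.0, sd, size=iu[0].shape[0])
    return e + e.T


def make_band_fc_set(geometry: ParcelGeometry, config: SyntheticConfig) -> BandFCSet:
    """Six symmetric band-limited connectivity matrices.

    Each matrix decays in expectation with interregional Euclidean distance
    at scale ``decay_length`` and carries a band-specific smooth spatial
    modulation plus symmetric edge noise. Entries are bounded in [-1, 1];
    the diagonal is stored as 0 (excluded).
    """
    if config.decay_length <= 0:
        raise ValueError("decay_length must be positive")
    rng = _rng(_STREAM_BAND_FC, config.seed)
    d = geometry.distance_matrix()
    base = config.fc_amplitude * np.exp(-d / config.decay_length)
    matrices = []
    for band in config.bands:
        if config.mod_amplitude > 0:
            f = smooth_field(geometry, config.weight_smoothness, rng)
            mod = 0.5 * config.mod_amplitude * (f[:, None] + f[None, :])
        else:
            # keep the stream position deterministic regardless of amplitude
            rng.standard_normal(geometry.n)
            mod = 0.0
        noise = _symmetric_noise(geometry.n, config.edge_noise_sd, rng)
        m = np.clip(base + mod + noise, -1.0, 1.0)
        np.fill_diagonal(m, 0.0)
        matrices.append(
            ConnectivityMatrix(values=m, modality="electromagnetic", band=band)
        )
    return BandFCSet(bands=config.bands, matrices=matrices)


def _lstsq_variances(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Population variances of fitted values and residuals of an OLS fit
    of ``y`` on ``x`` with intercept."""
    design = np.column_stack([np.ones_like(y), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    return float(fitted.var()), float((y - fitted).var())


def make_crossmodal_truth(
    band_fc_set: BandFCSet,
    geometry: ParcelGeometry,
    config: SyntheticConfig,
    weights: Optional[np.ndarray] = None,
    noise_sd: Optional[np.ndarray] = None,
) -> tuple[ConnectivityMatrix, GroundTruth]:
    """Haemodynamic matrix as a region-wise linear mixture of band matrices.

    Row i of the noiseless matrix is ``sum_b weights[i, b] * band_fc[b][i, :]``;
    independent Gaussian noise with per-region scale ``noise_sd[i]`` is added
    to the rows and the result symmetrized by averaging (i, j) and (j, i).

    ``target_r2[i]`` is the analytic expected variance explained: the
    symmetrized noiseless row is regressed on the band profiles and the
    fitted-value variance divided by fitted + structural-residual +
    closed-form noise variance.

    ``weights`` / ``noise_sd`` override the defaults (hierarchy-tilted
    weights; constant or hierarchy-graded noise).
    """
    n = band_fc_set.n
    if geometry.n != n:
        raise ValueError(
            f"parcellation mismatch: geometry has {geometry.n} parcels, "
            f"band set has {n}"
        )
    if band_fc_set.n_bands != 6:
        raise ValueError("band set must contain six bands")
    rng = _rng(_STREAM_TRUTH, config.seed)

    hierarchy = smooth_field(geometry, config.weight_smoothness, rng)
    hierarchy = (hierarchy - hierarchy.min()) / (hierarchy.max() - hierarchy.min())

    if weights is None:
        a0, a1 = _AMPLITUDE_SPAN
        weights = (
            _BASE_WEIGHTS[None, :]
            * (1.0 + _WEIGHT_TILT[None, :] * (hierarchy[:, None] - 0.5))
            * (a0 - a1 * hierarchy[:, None])
        )
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n, 6):
            raise ValueError("weights must be (N, 6)")

    if noise_sd is None:
        if config.noise_profile == "constant":
            noise_sd = np.full(n, config.noise_sd)
        else:
            lo, hi = config.noise_range
            noise_sd = lo + (hi - lo) * hierarchy**2
    else:
        noise_sd = np.asarray(noise_sd, dtype=float)
        if noise_sd.shape != (n,):
            raise ValueError("noise_sd must be length N")

    stack = np.stack([m.values for m in band_fc_set.matrices])  # (6, N, N)
    signal = np.einsum("ib,bij->ij", weights, stack)
    signal_sym = 0.5 * (signal + signal.T)

    e = rng.normal(0.0, 1.0, size=(n, n)) * noise_sd[:, None]
    e_sym = 0.5 * (e + e.T)
    haemo = signal_sym + e_sym
    np.fill_diagonal(haemo, 0.0)

    # analytic target R^2 per region
    off = ~np.eye(n, dtype=bool)
    var_noise = np.array(
        [np.mean(0.25 * (noise_sd[i] ** 2 + noise_sd[off[i]] ** 2)) for i in range(n)]
    )
    target = np.empty(n)
    for i in range(n):
        y = np.delete(signal_sym[i], i)
        x = band_fc_set.profiles(i)
        v_fit, v_res = _lstsq_variances(y, x)
        target[i] = v_fit / (v_fit + v_res + var_noise[i])

    truth = GroundTruth(
        weights=weights, noise_sd=noise_sd, hierarchy=hierarchy, target_r2=target
    )
    return ConnectivityMatrix(values=haemo, modality="haemodynamic"), truth


def make_subject_ensemble(
    group_haemo: ConnectivityMatrix,
    group_bands: BandFCSet,
    n_subjects: int,
    subject_noise_sd: float,
    seed: int = 0,
) -> tuple[list[ConnectivityMatrix], list[BandFCSet]]:
    """Per-subject matrices as the group matrix plus symmetric noise.

    Each off-diagonal pair receives an independent N(0, subject_noise_sd^2)
    deviation, so the subject mean converges to the group matrix.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = _rng(_STREAM_SUBJECTS, seed)
    n = group_haemo.n
    haemos: list[ConnectivityMatrix] = []
    band_sets: list[BandFCSet] = []
    for _ in range(n_subjects):
        m = group_haemo.values + _symmetric_noise(n, subject_noise_sd, rng)
        np.fill_diagonal(m, 0.0)
        haemos.append(ConnectivityMatrix(values=m, modality="haemodynamic"))
        mats = []
        for band, bm in group_bands:
            v = bm.values + _symmetric_noise(n, subject_noise_sd, rng)
            np.fill_diagonal(v, 0.0)
            mats.append(ConnectivityMatrix(values=v, modality="electromagnetic", band=band))
        band_sets.append(BandFCSet(bands=group_bands.bands, matrices=mats))
    return haemos, band_sets


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _mix_with_anchor(
    anchor_z: np.ndarray, field: np.ndarray, rho: float
) -> np.ndarray:
    """Linear mixture with in-sample correlation exactly ``rho``.

    The field is residualized against the anchor before mixing, so the
    sample (not just population) Pearson correlation of the output with
    the anchor equals ``rho`` — smooth fields have few effective spatial
    degrees of freedom, which would otherwise jitter planted correlations.
    """
    f = field - field.mean()
    f = f - (f @ anchor_z) / (anchor_z @ anchor_z) * anchor_z
    f = f / f.std()
    return rho * anchor_z + np.sqrt(1.0 - rho**2) * f


def make_context_maps(
    geometry: ParcelGeometry,
    anchor_map: np.ndarray,
    config: SyntheticConfig,
    n_depths: int = 50,
    peak_depth: int = 25,
    peak_strength: float = 0.9,
    depth_width: float = 3.0,
    n_genes: int = 40,
    n_donors: int = 6,
    donor_consistency: float = 0.8,
    designated_gene: str = "NPY1R",
    designated_correlation: float = -0.6,
    sc_density: float = 0.4,
) -> tuple[DepthProfileSet, ExpressionPanel, ConnectivityMatrix]:
    """Microarchitectural context inputs tied to an anchor map.

    * Depth profiles over ``n_depths`` equivolumetric depths whose
      correlation with ``anchor_map`` peaks at ``peak_depth`` with strength
      ``peak_strength`` (Gaussian profile of width ``depth_width`` depths).
    * An expression panel of ``n_donors`` donors whose gene patterns share
      a fraction ``donor_consistency`` of variance across donors, plus a
      designated gene with planted correlation ``designated_correlation``
      to the anchor.
    * A sparse non-negative structural matrix with distance decay, keeping
      the closest ``sc_density`` fraction of edges.
    """
    anchor_map = np.asarray(anchor_map, dtype=float)
    if anchor_map.shape != (geometry.n,):
        raise ValueError("anchor_map length must equal n_parcels")
    if not np.isfinite(anchor_map).all():
        raise ValueError("anchor_map contains non-finite values")
    if not 0 <= donor_consistency <= 1:
        raise ValueError("donor_consistency must be in [0, 1]")
    if not -1 <= designated_correlation <= 1:
        raise ValueError("designated_correlation must be in [-1, 1]")
    rng = _rng(_STREAM_CONTEXT, config.seed)
    n = geometry.n
    za = _zscore(anchor_map)

    # laminar depth profiles
    depths = np.arange(n_depths)
    a = peak_strength * np.exp(-((depths - peak_depth) ** 2) / (2.0 * depth_width**2))
    profiles = np.empty((n, n_depths))
    for d in range(n_depths):
        noise = smooth_field(geometry, config.weight_smoothness, rng)
        profiles[:, d] = _mix_with_anchor(za, noise, a[d])
    depth_set = DepthProfileSet(values=profiles, peak_depth=peak_depth)

    # expression panel
    genes = [f"GENE{g:03d}" for g in range(n_genes)] + [designated_gene]
    c = donor_consistency
    base_patterns = np.empty((n, n_genes + 1))
    for g in range(n_genes):
        base_patterns[:, g] = _zscore(smooth_field(geometry, config.weight_smoothness, rng))
    indep = smooth_field(geometry, config.weight_smoothness, rng)
    base_patterns[:, -1] = _mix_with_anchor(za, indep, designated_correlation)
    panel = np.empty((n_donors, n, n_genes + 1))
    for k in range(n_donors):
        donor_noise = rng.standard_normal((n, n_genes + 1))
        donor_noise = (donor_noise - donor_noise.mean(0)) / donor_noise.std(0)
        panel[k] = c * base_patterns + np.sqrt(1.0 - c**2) * donor_noise
    expr = ExpressionPanel(values=panel, genes=genes, donors=[f"donor{k}" for k in range(n_donors)])

    # sparse structural matrix with distance decay
    d_mat = geometry.distance_matrix()
    w = np.exp(-d_mat / config.decay_length)
    np.fill_diagonal(w, 0.0)
    iu = np.triu_indices(n, k=1)
    cut = np.quantile(w[iu], 1.0 - sc_density)
    sc = np.where(w > cut, w, 0.0)
    np.fill_diagonal(sc, 0.0)
    sc_mat = ConnectivityMatrix(values=sc, modality="structural")
    return depth_set, expr, sc_mat


def make_band_timeseries(
    n_regions: int,
    duration_s: float,
    fs: float,
    band: FrequencyBand = CANONICAL_BANDS[3],
    envelope_pairs: Sequence[tuple[int, int]] = (),
    locking_pairs: Sequence[tuple[int, int]] = (),
    locking_phase: float = np.pi / 4,
    seed: int = 0,
) -> ParcelTimeSeries:
    """Narrowband carriers with planted envelope and phase couplings.

    Unlisted regions carry independent band-limited Gaussian noise. Each
    envelope pair shares a slow common amplitude envelope modulating two
    independent pure-tone carriers at distinct frequencies inside the band
    (so leakage correction removes almost nothing). Each locking pair
    shares one narrowband carrier with a fixed phase offset
    ``locking_phase`` (phase-locking value 1).
    """
    if fs <= 2.0 * band.hi:
        raise ValueError(
            f"sampling rate {fs} Hz aliases band {band.name} "
            f"(upper edge {band.hi} Hz); need fs > {2 * band.hi} Hz"
        )
    rng = _rng(_STREAM_TIMESERIES, seed)
    n_samples = int(round(duration_s * fs))
    t = np.arange(n_samples) / fs
    sos = sps.butter(4, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_regions, n_samples)), axis=1)
    x /= x.std(axis=1, keepdims=True)

    env_cutoff = max(0.2, min(0.25 * (band.hi - band.lo), 2.0))
    sos_lo = sps.butter(4, env_cutoff, btype="lowpass", fs=fs, output="sos")

    for k, (i, j) in enumerate(envelope_pairs):
        env = np.abs(
            sps.hilbert(sps.sosfiltfilt(sos_lo, rng.standard_normal(n_samples)))
        )
        span = band.hi - band.lo
        f_i = band.lo + span * (0.35 + 0.02 * k)
        f_j = band.lo + span * (0.65 + 0.02 * k)
        for r, f in ((i, f_i), (j, f_j)):
            carrier = np.cos(2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            s = env * carrier
            x[r] = s / s.std()

    for i, j in locking_pairs:
        base = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
        analytic = sps.hilbert(base)
        x[i] = np.real(analytic)
        x[j] = np.real(analytic * np.exp(1j * locking_phase))
        x[i] /= x[i].std()
        x[j] /= x[j].std()

    return ParcelTimeSeries(values=x, fs=fs)
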