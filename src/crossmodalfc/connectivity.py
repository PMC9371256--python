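"""Band-limited electromagnetic and haemodynamic connectivity measures.

Amplitude envelope correlation (AEC) with pairwise leakage correction,
phase-locking value (PLV), Pearson haemodynamic functional connectivity,
and a decibel source signal-to-noise ratio.

Filters are zero-phase forward-backward 4th-order Butterworth band-passes;
envelopes are the modulus of the analytic signal, with one filter length
of edge samples discarded at each end before correlating.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .datatypes import ConnectivityMatrix, FrequencyBand, ParcelTimeSeries

__all__ = [
    "SnrInputs",
    "bandpass",
    "orthogonalize_pair",
    "aec",
    "plv",
    "haemodynamic_fc",
    "source_snr",
]

logger = logging.getLogger(__name__)

#: relative residual RMS below which an orthogonalized signal is treated
#: as identically zero (duplicated channels)
_ZERO_RESIDUAL_RTOL = 1e-10


@dataclass(frozen=True)
class SnrInputs:
    """Inputs of the decibel source SNR.

    ``a`` is the source amplitude in nAm (a typical dipole is 10 nAm),
    ``gains`` the per-sensor forward signal of a unit-amplitude source,
    and ``noise_vars`` the per-sensor noise variances.
    """

    a: float
    gains: np.ndarray
    noise_vars: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gains", np.asarray(self.gains, dtype=float))
        object.__setattr__(self, "noise_vars", np.asarray(self.noise_vars, dtype=float))
        if self.gains.shape != self.noise_vars.shape or self.gains.ndim != 1:
            raise ValueError("gains and noise_vars must be 1-D and equal length")
        if self.gains.shape[0] < 1:
            raise ValueError("need at least one sensor")
        if (self.noise_vars <= 0).any():
            raise ValueError("noise variances must all be > 0")


def _band_sos(band: FrequencyBand, fs: float) -> np.ndarray:
    if band.hi >= fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.hi} Hz at or above Nyquist "
            f"({fs / 2} Hz)"
        )
    return sps.butter(4, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")


def bandpass(ts: ParcelTimeSeries, band: FrequencyBand) -> ParcelTimeSeries:
    """Zero-phase narrowband filtering of every region's time series."""
    sos = _band_sos(band, ts.fs)
    out = sps.sosfiltfilt(sos, ts.values, axis=1)
    return ParcelTimeSeries(values=out, fs=ts.fs, labels=list(ts.labels))


def orthogonalize_pair(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Component of ``y`` with no instantaneous linear dependence on ``x``.

    Least-squares residual of ``y`` after projection onto ``x``. If ``x``
    is identically zero there is nothing to remove and ``y`` is returned
    unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.shape[0] < 2:
        raise ValueError("x and y must be equal-length 1-D signals with >= 2 samples")
    xx = float(np.dot(x, x))
    if xx == 0.0:
        return y.copy()
    return y - (float(np.dot(x, y)) / xx) * x


def _edge_trim(band: FrequencyBand, fs: float, n_samples: int) -> int:
    """Samples to discard at each end: one effective filter length.

    The zero-phase band-pass has transients far longer than one carrier
    period (its ring-down scales with the inverse bandwidth), so the trim
    is 32 cycles of the band's lower edge, capped at a quarter record.
    """
    return min(int(round(32.0 * fs / band.lo)), n_samples // 4)


def _check_duration(ts: ParcelTimeSeries, band: FrequencyBand) -> None:
    if ts.duration < 10.0 / band.lo:
        raise ValueError(
            f"recording of {ts.duration:.2f}s too short for band {band.name}: "
            f"need >= 10 cycles of {band.lo} Hz"
        )


def _envelope(x: np.ndarray) -> np.ndarray:
    return np.abs(sps.hilbert(x))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return 0.0
    return float(a @ b / denom)


def aec(
    ts: ParcelTimeSeries,
    band: FrequencyBand,
    leakage_correction: bool = True,
) -> ConnectivityMatrix:
    """Amplitude envelope correlation in one band.

    With leakage correction, each member of a pair is orthogonalized with
    respect to the other (both directions), the analytic-signal envelopes
    are correlated after edge trimming, and the two directed values are
    averaged. A pair whose orthogonalized residual is (numerically)
    identically zero gets entry 0 and a logged warning.
    """
    _check_duration(ts, band)
    bp = bandpass(ts, band).values
    n = bp.shape[0]
    trim = _edge_trim(band, ts.fs, bp.shape[1])
    sl = slice(trim, bp.shape[1] - trim if trim else None)
    out = np.zeros((n, n))

    if not leakage_correction:
        env = np.array([_envelope(bp[i])[sl] for i in range(n)])
        c = np.corrcoef(env)
        out = np.asarray(c)
        np.fill_diagonal(out, 0.0)
        return ConnectivityMatrix(values=out, modality="electromagnetic", band=band)

    for i in range(n):
        env_i = _envelope(bp[i])[sl]
        for j in range(i + 1, n):
            env_j = _envelope(bp[j])[sl]
            vals = []
            for a_sig, b_sig, env_a in ((bp[i], bp[j], env_i), (bp[j], bp[i], env_j)):
                resid = orthogonalize_pair(a_sig, b_sig)
                rms_ref = np.sqrt(np.mean(b_sig**2))
                if rms_ref == 0.0 or np.sqrt(np.mean(resid**2)) < _ZERO_RESIDUAL_RTOL * rms_ref:
                    logger.warning(
                        "orthogonalized residual of pair (%d, %d) is zero; "
                        "AEC entry set to 0",
                        i,
                        j,
                    )
                    vals.append(0.0)
                    continue
                vals.append(_corr(env_a, _envelope(resid)[sl]))
            out[i, j] = out[j, i] = 0.5 * (vals[0] + vals[1])
    return ConnectivityMatrix(values=out, modality="electromagnetic", band=band)


def plv(ts: ParcelTimeSeries, band: FrequencyBand) -> ConnectivityMatrix:
    """Phase-locking value: modulus of the time-averaged unit phasor of the
    instantaneous phase difference; entries in [0, 1]."""
    _check_duration(ts, band)
    const = np.flatnonzero(ts.values.std(axis=1) == 0.0)
    if const.size:
        raise ValueError(
            f"constant signal (undefined phase) for region(s) {const.tolist()}"
        )
    bp = bandpass(ts, band).values
    n, n_samp = bp.shape
    trim = _edge_trim(band, ts.fs, n_samp)
    sl = slice(trim, n_samp - trim if trim else None)
    analytic = sps.hilbert(bp, axis=1)[:, sl]
    phasors = analytic / np.abs(analytic)
    m = phasors.shape[1]
    out = np.abs(phasors @ phasors.conj().T) / m
    out = 0.5 * (out + out.T)  # exact symmetry against float round-off
    np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(values=out, modality="electromagnetic", band=band)


def haemodynamic_fc(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Pearson product-moment correlation matrix of regional time series."""
    if ts.n_samples < 3:
        raise ValueError("need at least 3 samples")
    const = np.flatnonzero(ts.values.std(axis=1) == 0.0)
    if const.size:
        names = [ts.labels[i] for i in const]
        raise ValueError(f"constant time series for region(s) {names}")
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        c = np.corrcoef(ts.values)
    c = 0.5 * (c + c.T)
    np.fill_diagonal(c, 0.0)
    return ConnectivityMatrix(values=c, modality="haemodynamic")


def source_snr(inputs: SnrInputs) -> float:
    """Source SNR in decibels: ``10 log10((a^2 / N) * sum_k b_k^2 / s_k^2)``."""
    n = inputs.gains.shape[0]
    ratio = (inputs.a**2 / n) * float(np.sum(inputs.gains**2 / inputs.noise_vars))
    return float(10.0 * np.log10(ratio))
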