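"""Plain-text I/O for matrices, geometry, maps, and time series.

All formats are tab-delimited text with a one-line header so results can
be consumed without this package. Matrices carry region labels as the
header row; geometry files hold (parcel_id, hemisphere, x, y, z); time
series are stored with a JSON sidecar holding the sampling rate.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ConnectivityMatrix, ParcelGeometry, ParcelTimeSeries
from .nulls import SpinEnsemble

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_geometry",
    "write_geometry",
    "read_timeseries",
    "write_timeseries",
    "write_map",
    "read_map",
    "write_spins",
    "read_spins",
]

_ASYM_TOL = 1e-8


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    """Tab-delimited matrix with region labels as the header row."""
    df = pd.DataFrame(matrix.values, columns=list(matrix.labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_matrix(path: str | Path, modality: str = "haemodynamic") -> ConnectivityMatrix:
    """Read a matrix written by :func:`write_matrix`.

    Rejects non-square or non-numeric bodies and asymmetry beyond 1e-8,
    naming the offending entry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix body ({exc})") from None
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path}: matrix body is {values.shape[0]} rows x {values.shape[1]} "
            "columns; expected square"
        )
    asym = np.abs(values - values.T)
    if asym.size and asym.max() > _ASYM_TOL:
        i, j = np.unravel_index(asym.argmax(), asym.shape)
        raise ValueError(
            f"{path}: asymmetric input, entries ({i},{j}) and ({j},{i}) differ "
            f"by {asym.max():.3g}"
        )
    values = 0.5 * (values + values.T)
    return ConnectivityMatrix(values=values, modality=modality, labels=list(df.columns))


def write_geometry(geometry: ParcelGeometry, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "parcel_id": list(geometry.ids),
            "hemisphere": geometry.hemispheres,
            "x": geometry.coords[:, 0],
            "y": geometry.coords[:, 1],
            "z": geometry.coords[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_geometry(path: str | Path) -> ParcelGeometry:
    df = pd.read_csv(path, sep="\t")
    required = {"parcel_id", "hemisphere", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: geometry file must have columns {sorted(required)}")
    return ParcelGeometry(
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        hemispheres=df["hemisphere"].to_numpy(),
        ids=df["parcel_id"].tolist(),
    )


def write_timeseries(ts: ParcelTimeSeries, path: str | Path) -> None:
    """Region-per-row samples table plus a JSON sidecar with the rate."""
    path = Path(path)
    df = pd.DataFrame(ts.values)
    df.insert(0, "region", list(ts.labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"fs": ts.fs}))


def read_timeseries(path: str | Path) -> ParcelTimeSeries:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sampling-rate sidecar {sidecar}")
    fs = float(json.loads(sidecar.read_text())["fs"])
    df = pd.read_csv(path, sep="\t")
    labels = df.iloc[:, 0].tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return ParcelTimeSeries(values=values, fs=fs, labels=labels)


def write_map(values: np.ndarray, path: str | Path, name: str = "value",
              labels: Sequence[str] | None = None) -> None:
    """One-column region table (with optional region labels)."""
    values = np.asarray(values)
    data = {name: values}
    if labels is not None:
        data = {"region": list(labels), name: values}
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_map(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, -1].to_numpy(dtype=float)


def write_spins(spins: SpinEnsemble, path: str | Path) -> None:
    np.savetxt(path, spins.assignment, fmt="%d", delimiter="\t",
               header=f"seed={spins.seed} n_spin={spins.n_spin}")


def read_spins(path: str | Path, seed: int = -1) -> SpinEnsemble:
    assignment = np.loadtxt(path, dtype=np.intp, delimiter="\t", ndmin=2)
    return SpinEnsemble(assignment=assignment, seed=seed, n_spin=assignment.shape[0])
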