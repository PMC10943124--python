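"""File I/O for spaces, dense time series, scalar maps, and pairings.

Three dense-matrix dialects are supported:

``hdf5_matrix``
    HDF5 with datasets ``/data`` (grayordinates x frames), ``/tr``
    (scalar seconds) and ``/fd`` (per-frame mm).  Lossless (float64).
``tsv_matrix``
    Plain TSV matrix (rows = grayordinates) plus a JSON sidecar
    ``<path>.json`` with keys ``tr`` and ``fd``.  Meant for tiny fixtures.
``cifti_dtseries``
    CIFTI-2 dense time series via nibabel; TR comes from the series axis
    and FD from an optional JSON sidecar ``<path>.fd.json``.  Stored in
    float32, so round-trips are only float32-exact.

Spaces travel as a TSV with columns ``vertex_id, hemi, x, y, z, parcel``.
Vertex ids in files may be declared 1-based (``one_based=True``); they are
converted to the internal 0-based convention at this boundary and the
conversion is logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import DenseTimeSeries
from .space import HEMI_CODES, HEMI_NAMES, HomologousPairing, ScalarMap, SurfaceSpace

logger = logging.getLogger(__name__)

__all__ = [
    "read_space_tsv",
    "write_space_tsv",
    "read_dense_timeseries",
    "write_dense_timeseries",
    "read_scalar_map",
    "write_scalar_map",
    "write_pairing_tsv",
    "dtseries_structure_counts",
]

STRUCT_LEFT = "CIFTI_STRUCTURE_CORTEX_LEFT"
STRUCT_RIGHT = "CIFTI_STRUCTURE_CORTEX_RIGHT"


# ---------------------------------------------------------------------------
# spaces

def write_space_tsv(path: str | Path, space: SurfaceSpace) -> None:
    df = pd.DataFrame(
        {
            "vertex_id": np.arange(space.n_vertices),
            "hemi": [HEMI_NAMES[h] for h in space.hemisphere],
            "x": space.coords[:, 0],
            "y": space.coords[:, 1],
            "z": space.coords[:, 2],
            "parcel": space.parcel_id if space.parcel_id is not None else -1,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_space_tsv(path: str | Path, one_based: bool = False) -> SurfaceSpace:
    df = pd.read_csv(path, sep="\t")
    ids = df["vertex_id"].to_numpy()
    if one_based:
        logger.info("converting 1-based vertex ids to 0-based for %s", path)
        ids = ids - 1
    order = np.argsort(ids)
    df = df.iloc[order]
    ids = ids[order]
    if not np.array_equal(ids, np.arange(len(df))):
        raise ValueError("vertex_id column must be dense in [0, N)")
    hemi = np.array([HEMI_CODES[str(h).upper()] for h in df["hemi"]], dtype=np.int8)
    parcel = None
    if "parcel" in df.columns and (df["parcel"].to_numpy() >= 0).any():
        parcel = df["parcel"].to_numpy()
    return SurfaceSpace(
        coords=df[["x", "y", "z"]].to_numpy(float), hemisphere=hemi, parcel_id=parcel
    )


# ---------------------------------------------------------------------------
# dense time series

def _check_matrix(data: np.ndarray, space: SurfaceSpace | None, path: str | Path) -> None:
    if space is not None and data.shape[0] != space.n_vertices:
        raise ValueError(
            f"{path}: matrix has {data.shape[0]} rows but the declared space "
            f"has {space.n_vertices} vertices"
        )
    bad = ~np.isfinite(data)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"{path}: non-finite entry at vertex {i}, frame {j}")


def write_dense_timeseries(
    path: str | Path,
    ts: DenseTimeSeries,
    format: str = "hdf5_matrix",
    space: SurfaceSpace | None = None,
) -> None:
    path = Path(path)
    if format == "hdf5_matrix":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=ts.data)
            f.create_dataset("tr", data=float(ts.tr))
            f.create_dataset("fd", data=ts.fd)
    elif format == "tsv_matrix":
        np.savetxt(path, ts.data, delimiter="\t")
        sidecar = {"tr": float(ts.tr), "fd": [float(v) for v in ts.fd]}
        Path(f"{path}.json").write_text(json.dumps(sidecar))
    elif format == "cifti_dtseries":
        _write_dtseries(path, ts, space)
    else:
        raise ValueError(f"unknown dense time-series format: {format!r}")


def read_dense_timeseries(
    path: str | Path,
    format: str = "hdf5_matrix",
    space: SurfaceSpace | None = None,
    subject_id: str = "",
) -> DenseTimeSeries:
    """Read a grayordinates-by-frames matrix with TR and FD metadata.

    The returned series has an all-true frame mask.  A row count that
    disagrees with ``space``, a missing TR, or any non-finite entry is a
    hard error.
    """
    path = Path(path)
    if format == "hdf5_matrix":
        with h5py.File(path, "r") as f:
            if "tr" not in f:
                raise ValueError(f"{path}: missing /tr dataset (repetition time)")
            data = f["data"][()]
            tr = float(f["tr"][()])
            fd = f["fd"][()] if "fd" in f else None
    elif format == "tsv_matrix":
        data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
        sidecar_path = Path(f"{path}.json")
        if not sidecar_path.exists():
            raise ValueError(f"{path}: missing JSON sidecar with tr/fd")
        sidecar = json.loads(sidecar_path.read_text())
        if "tr" not in sidecar:
            raise ValueError(f"{path}: sidecar does not declare tr")
        tr = float(sidecar["tr"])
        fd = np.asarray(sidecar.get("fd", np.zeros(data.shape[1])), dtype=float)
    elif format == "cifti_dtseries":
        data, tr, fd = _read_dtseries(path)
    else:
        raise ValueError(f"unknown dense time-series format: {format!r}")
    data = np.asarray(data, dtype=float)
    _check_matrix(data, space, path)
    return DenseTimeSeries(data=data, tr=tr, fd=fd, subject_id=subject_id)


def _series_and_brain_axes(ts: DenseTimeSeries, space: SurfaceSpace | None):
    import nibabel as nib

    series = nib.cifti2.SeriesAxis(start=0.0, step=float(ts.tr), size=ts.n_frames)
    n = ts.n_vertices
    if space is not None:
        from .space import LEFT

        n_left = int(np.count_nonzero(space.hemisphere == LEFT))
    else:
        n_left = n // 2
    n_right = n - n_left
    names = [STRUCT_LEFT] * n_left + [STRUCT_RIGHT] * n_right
    vertex = np.concatenate([np.arange(n_left), np.arange(n_right)])
    bm = nib.cifti2.BrainModelAxis(
        name=names,
        vertex=vertex,
        nvertices={STRUCT_LEFT: n_left, STRUCT_RIGHT: n_right},
    )
    return series, bm


def _write_dtseries(path: Path, ts: DenseTimeSeries, space: SurfaceSpace | None) -> None:
    import nibabel as nib

    series, bm = _series_and_brain_axes(ts, space)
    img = nib.cifti2.Cifti2Image(
        ts.data.T.astype(np.float32), header=(series, bm)
    )
    img.to_filename(str(path))
    if ts.fd is not None and np.any(ts.fd):
        Path(f"{path}.fd.json").write_text(json.dumps({"fd": [float(v) for v in ts.fd]}))


def _read_dtseries(path: Path):
    import nibabel as nib

    img = nib.load(str(path))
    axis0 = img.header.get_axis(0)
    if not isinstance(axis0, nib.cifti2.SeriesAxis):
        raise ValueError(f"{path}: first CIFTI axis is not a time series (no TR)")
    tr = float(axis0.step)
    data = np.asarray(img.get_fdata()).T  # -> grayordinates x frames
    fd = None
    sidecar = Path(f"{path}.fd.json")
    if sidecar.exists():
        fd = np.asarray(json.loads(sidecar.read_text())["fd"], dtype=float)
    return data, tr, fd


def dtseries_structure_counts(path: str | Path) -> dict[str, int]:
    """Grayordinate counts per brain structure of a dtseries file."""
    import nibabel as nib

    img = nib.load(str(path))
    bm = img.header.get_axis(1)
    counts: dict[str, int] = {}
    for name, slc, _ in bm.iter_structures():
        counts[str(name)] = slc.stop - slc.start if slc.stop else len(bm.name[slc])
    return counts


# ---------------------------------------------------------------------------
# scalar maps

def write_scalar_map(path: str | Path, smap: ScalarMap, format: str = "hdf5_matrix") -> None:
    path = Path(path)
    if format == "hdf5_matrix":
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=smap.values)
            f.attrs["name"] = smap.name
            f.attrs["units"] = smap.units
    elif format == "tsv_matrix":
        pd.DataFrame(
            {"vertex_id": np.arange(smap.values.size), "value": smap.values}
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown scalar-map format: {format!r}")


def read_scalar_map(
    path: str | Path, space: SurfaceSpace, format: str = "hdf5_matrix"
) -> ScalarMap:
    path = Path(path)
    if format == "hdf5_matrix":
        with h5py.File(path, "r") as f:
            values = f["values"][()]
            name = str(f.attrs.get("name", ""))
            units = str(f.attrs.get("units", ""))
    elif format == "tsv_matrix":
        df = pd.read_csv(path, sep="\t")
        values = df.sort_values("vertex_id")["value"].to_numpy()
        name, units = "", ""
    else:
        raise ValueError(f"unknown scalar-map format: {format!r}")
    return ScalarMap(values=values, space=space, name=name, units=units)


# ---------------------------------------------------------------------------
# pairings

def write_pairing_tsv(path: str | Path, pairing: HomologousPairing) -> None:
    pd.DataFrame(
        {
            "left_id": pairing.left,
            "right_id": pairing.right,
            "residual_mm": pairing.match_residual,
        }
    ).to_csv(path, sep="\t", index=False)
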