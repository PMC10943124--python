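"""Scalar and map-valued laterality indices.

* handedness index: normalized difference of mean hub density between the
  right-hand (left-hemisphere, Ml) and left-hand (right-hemisphere, Mr)
  motor ROIs; positive values indicate right-hand-area dominance, so the
  index correlates positively with a handedness score where fully
  right-handed scores +100.
* laterality map (delta): per-vertex normalized difference of the
  connectivity with the Ml vs Mr seeds.
* asymmetry map: value(right) - value(left) over homologous vertex pairs;
  positive = rightward asymmetry.
* specialization index: max-minus-mean of pairwise absolute differences of
  per-parcel association weights, normalized across the parcel set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .seedfc import SeedFcMap
from .space import ROI, HomologousPairing, ScalarMap

__all__ = [
    "EPS",
    "SubjectIndexRecord",
    "LateralityMap",
    "ParcelSpecialization",
    "handedness_index",
    "laterality_map",
    "roi_delta",
    "asymmetry_map",
    "specialization_index",
]

# denominator guard for every normalized index: below this, the index is NaN
EPS = 1e-9


@dataclass(frozen=True)
class SubjectIndexRecord:
    subject_id: str
    gfcd_ml: float
    gfcd_mr: float
    handedness_index: float


@dataclass
class LateralityMap:
    delta: ScalarMap
    source_ml: SeedFcMap
    source_mr: SeedFcMap


@dataclass(frozen=True)
class ParcelSpecialization:
    parcel_id: int
    rgb: tuple[float, float, float]
    s_values: tuple[float, float, float]
    raw_index: float
    index: float


def handedness_index(
    gfcd: ScalarMap, ml: ROI, mr: ROI, subject_id: str = "", eps: float = EPS
) -> SubjectIndexRecord:
    """(mean gFCD in Ml - mean in Mr) / (mean in Ml + mean in Mr).

    ``gfcd`` should already be grand-mean scaled when sex/race effects are
    to be removed.  A denominator at or below ``eps`` yields NaN with a
    warning.
    """
    a = float(np.nanmean(gfcd.values[ml.members]))
    b = float(np.nanmean(gfcd.values[mr.members]))
    denom = a + b
    if not np.isfinite(denom) or abs(denom) <= eps:
        warnings.warn(
            f"handedness index undefined for {subject_id or 'subject'} "
            f"(denominator {denom!r})",
            stacklevel=2,
        )
        idx = np.nan
    else:
        idx = (a - b) / denom
    return SubjectIndexRecord(
        subject_id=subject_id, gfcd_ml=a, gfcd_mr=b, handedness_index=idx
    )


def laterality_map(z_ml: SeedFcMap, z_mr: SeedFcMap, eps: float = EPS) -> LateralityMap:
    """delta(v) = (z_ml(v) - z_mr(v)) / (|z_ml(v)| + |z_mr(v)|), elementwise.

    NaN wherever the denominator is below ``eps`` or either input is NaN.
    """
    if z_ml.z.space is not z_mr.z.space and z_ml.z.space.n_vertices != z_mr.z.space.n_vertices:
        raise ValueError("seed maps live on different spaces")
    a = z_ml.z.values
    b = z_mr.z.values
    denom = np.abs(a) + np.abs(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(denom > eps, (a - b) / denom, np.nan)
    delta[~np.isfinite(a) | ~np.isfinite(b)] = np.nan
    return LateralityMap(
        delta=ScalarMap(delta, z_ml.z.space, name="laterality_delta"),
        source_ml=z_ml,
        source_mr=z_mr,
    )


def roi_delta(
    z_ml: SeedFcMap,
    z_mr: SeedFcMap,
    roi: ROI,
    exclude: np.ndarray | None = None,
    eps: float = EPS,
) -> float:
    """ROI-level laterality from ROI-mean seed connectivity.

    Computed on the ROI means of the two z maps (not the mean of the
    vertexwise delta).  ``exclude`` removes vertices (typically the seed
    members themselves) from the ROI before averaging; an ROI left empty
    by the exclusion yields NaN.
    """
    members = roi.members
    if exclude is not None:
        members = np.setdiff1d(members, exclude)
    if members.size == 0:
        return float("nan")
    a = float(np.nanmean(z_ml.z.values[members]))
    b = float(np.nanmean(z_mr.z.values[members]))
    denom = abs(a) + abs(b)
    if not np.isfinite(denom) or denom <= eps:
        return float("nan")
    return (a - b) / denom


def asymmetry_map(smap: ScalarMap, pairing: HomologousPairing) -> np.ndarray:
    """value(right vertex) - value(left vertex), one entry per homologous pair."""
    n = smap.values.size
    if pairing.pairs.size and pairing.pairs.max() >= n:
        raise ValueError("pairing references vertices outside the map's space")
    return smap.values[pairing.right] - smap.values[pairing.left]


def specialization_index(parcels) -> list[ParcelSpecialization]:
    """Specialization of each parcel from its (aud, som, vis) weight triplet.

    S1 = |aud - som|, S2 = |aud - vis|, S3 = |som - vis|;
    raw index = max(S) - mean(S); all raw indices are divided by the set
    maximum (when positive) so the most specialized parcel scores 1.
    """
    rgb = np.asarray([tuple(p) for p in parcels], dtype=float)
    if rgb.size == 0:
        raise ValueError("empty parcel list")
    if rgb.ndim != 2 or rgb.shape[1] != 3:
        raise ValueError("each parcel needs exactly 3 association weights")
    if (rgb < 0).any() or (rgb > 1).any():
        raise ValueError("association weights must lie in [0, 1]")
    aud, som, vis = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    S = np.column_stack((np.abs(aud - som), np.abs(aud - vis), np.abs(som - vis)))
    raw = S.max(axis=1) - S.mean(axis=1)
    top = raw.max()
    norm = raw / top if top > 0 else raw.copy()
    return [
        ParcelSpecialization(
            parcel_id=i,
            rgb=tuple(rgb[i]),
            s_values=tuple(S[i]),
            raw_index=float(raw[i]),
            index=float(norm[i]),
        )
        for i in range(rgb.shape[0])
    ]
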