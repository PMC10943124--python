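"""Grayordinate data model: surfaces, ROIs, and interhemispheric pairing.

A :class:`SurfaceSpace` is the universe of grayordinates on which every
dense map lives: per-vertex 3D coordinates plus a left/right hemisphere
label.  :func:`roi_from_center` grows spherical (Euclidean) regions of
interest on one hemisphere, and :func:`build_homologous_pairing` matches
each left-hemisphere vertex to its mirror twin on the right so that
asymmetry maps can subtract homologous locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LEFT",
    "RIGHT",
    "SurfaceSpace",
    "ROI",
    "HomologousPairing",
    "ScalarMap",
    "roi_from_center",
    "build_homologous_pairing",
]

LEFT = 0
RIGHT = 1

HEMI_NAMES = {LEFT: "L", RIGHT: "R"}
HEMI_CODES = {"L": LEFT, "LEFT": LEFT, "R": RIGHT, "RIGHT": RIGHT}


@dataclass(frozen=True)
class SurfaceSpace:
    """Vertex coordinates and hemisphere labels for a dense surface space.

    Parameters
    ----------
    coords
        ``(N, 3)`` float array of vertex coordinates in mm.
    hemisphere
        ``(N,)`` integer array with values :data:`LEFT` (0) or
        :data:`RIGHT` (1).
    parcel_id
        Optional ``(N,)`` integer parcel assignment.

    Vertex ids are implicit: vertex ``i`` is row ``i`` (0-based, dense).
    """

    coords: np.ndarray
    hemisphere: np.ndarray
    parcel_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        hemi = np.asarray(self.hemisphere, dtype=np.int8)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if hemi.shape != (coords.shape[0],):
            raise ValueError("hemisphere must be a 1-D array matching coords")
        if not np.all(np.isfinite(coords)):
            bad = int(np.argwhere(~np.isfinite(coords).all(axis=1))[0, 0])
            raise ValueError(f"non-finite coordinates at vertex {bad}")
        if not np.all(np.isin(hemi, (LEFT, RIGHT))):
            raise ValueError("hemisphere labels must be LEFT (0) or RIGHT (1)")
        if not (np.any(hemi == LEFT) and np.any(hemi == RIGHT)):
            raise ValueError("both hemispheres must be non-empty")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "hemisphere", hemi)
        if self.parcel_id is not None:
            parcel = np.asarray(self.parcel_id, dtype=np.int64)
            if parcel.shape != (coords.shape[0],):
                raise ValueError("parcel_id must match the vertex count")
            object.__setattr__(self, "parcel_id", parcel)

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    def hemi_mask(self, hemi: int) -> np.ndarray:
        return self.hemisphere == hemi

    def vertices_of(self, hemi: int) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    def bounding_box_center(self) -> np.ndarray:
        return 0.5 * (self.coords.min(axis=0) + self.coords.max(axis=0))


@dataclass(frozen=True)
class ROI:
    """A named spherical region of interest on one hemisphere."""

    name: str
    center_vertex: int
    radius: float
    hemisphere: int
    members: np.ndarray

    def __post_init__(self) -> None:
        members = np.asarray(self.members, dtype=np.int64)
        object.__setattr__(self, "members", np.sort(members))
        if self.center_vertex not in self.members:
            raise ValueError("center_vertex must be a member of the ROI")

    @property
    def size(self) -> int:
        return self.members.size


@dataclass(frozen=True)
class HomologousPairing:
    """One-to-one left/right vertex correspondence.

    ``pairs`` is ``(P, 2)`` with columns (left_vertex_id, right_vertex_id);
    ``match_residual`` is the mm distance between the mirrored left
    coordinate and its matched right coordinate; ``coordinate_correlation``
    pools all three axes of the mirrored-left vs matched-right coordinates.
    """

    pairs: np.ndarray
    match_residual: np.ndarray
    coordinate_correlation: float
    n_unmatched: int = 0

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64)
        resid = np.asarray(self.match_residual, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("pairs must be (P, 2)")
        if resid.shape != (pairs.shape[0],):
            raise ValueError("match_residual must have one entry per pair")
        flat = pairs.ravel()
        if np.unique(flat).size != flat.size:
            raise ValueError("pairing must be one-to-one (a vertex repeats)")
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "match_residual", resid)

    @property
    def left(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def right(self) -> np.ndarray:
        return self.pairs[:, 1]

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


@dataclass
class ScalarMap:
    """One real value per grayordinate of a :class:`SurfaceSpace`.

    NaN encodes "undefined at this vertex".
    """

    values: np.ndarray
    space: SurfaceSpace
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.space.n_vertices,):
            raise ValueError(
                f"map has {values.shape} values for a space of "
                f"{self.space.n_vertices} vertices"
            )
        self.values = values


def roi_from_center(
    space: SurfaceSpace,
    center_vertex: int,
    radius: float,
    name: str | None = None,
    metric: str = "euclidean",
) -> ROI:
    """Grow a spherical ROI around ``center_vertex`` on its own hemisphere.

    Membership is every same-hemisphere vertex whose Euclidean distance to
    the center is ``<= radius``.  ``metric`` is reserved for a future
    geodesic option; only ``"euclidean"`` is implemented.
    """
    if metric != "euclidean":
        raise NotImplementedError(f"unsupported ROI metric: {metric!r}")
    if not (0 <= center_vertex < space.n_vertices):
        raise ValueError(f"center_vertex {center_vertex} out of range")
    if radius <= 0:
        raise ValueError("radius must be positive")
    hemi = int(space.hemisphere[center_vertex])
    candidates = space.vertices_of(hemi)
    d = np.linalg.norm(space.coords[candidates] - space.coords[center_vertex], axis=1)
    members = candidates[d <= radius]
    return ROI(
        name=name or f"roi_v{center_vertex}",
        center_vertex=int(center_vertex),
        radius=float(radius),
        hemisphere=hemi,
        members=members,
    )


def _greedy_one_to_one(
    mirrored: np.ndarray,
    left_ids: np.ndarray,
    right_coords: np.ndarray,
    right_ids: np.ndarray,
    n_pairs: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour matching with greedy ascending-residual resolution.

    Candidate (left, right) links are consumed best-first; ties break on the
    lower left id then lower right id.  Left vertices whose candidate lists
    are exhausted are re-queried with a growing neighbour count, falling
    back to an exhaustive scan for stragglers.
    """
    tree = cKDTree(right_coords)
    n_left = mirrored.shape[0]
    n_right = right_coords.shape[0]
    taken_right = np.zeros(n_right, dtype=bool)
    matched_left = np.full(n_left, -1, dtype=np.int64)  # local right index
    resid = np.full(n_left, np.nan)

    pending = np.arange(n_left)
    k = min(8, n_right)
    while pending.size and np.count_nonzero(matched_left >= 0) < n_pairs:
        d, j = tree.query(mirrored[pending], k=k)
        d = np.atleast_2d(d)
        j = np.atleast_2d(j)
        # flatten candidates, sort by (distance, left id, right id)
        li = np.repeat(pending, d.shape[1])
        dd = d.ravel()
        jj = j.ravel()
        valid = np.isfinite(dd) & (jj < n_right)
        li, dd, jj = li[valid], dd[valid], jj[valid]
        order = np.lexsort((jj, li, dd))
        for idx in order:
            l, r = li[idx], jj[idx]
            if matched_left[l] >= 0 or taken_right[r]:
                continue
            matched_left[l] = r
            taken_right[r] = True
            resid[l] = dd[idx]
        pending = np.flatnonzero(matched_left < 0)
        if k >= n_right:
            break
        k = min(k * 4, n_right)

    if pending.size and np.count_nonzero(matched_left >= 0) < n_pairs:
        # exhaustive fallback for the few remaining vertices
        free_r = np.flatnonzero(~taken_right)
        links = []
        for l in pending:
            dd = np.linalg.norm(right_coords[free_r] - mirrored[l], axis=1)
            links.extend(zip(dd, [l] * free_r.size, free_r))
        links.sort()
        for dd, l, r in links:
            if matched_left[l] >= 0 or taken_right[r]:
                continue
            matched_left[l] = r
            taken_right[r] = True
            resid[l] = dd

    done = np.flatnonzero(matched_left >= 0)
    pairs = np.column_stack((left_ids[done], right_ids[matched_left[done]]))
    return pairs, resid[done]


def build_homologous_pairing(
    space: SurfaceSpace,
    box_center: np.ndarray | None = None,
) -> HomologousPairing:
    """Match each left vertex to its mirror twin on the right hemisphere.

    Left coordinates are reflected in the left-right (x) axis about
    ``box_center`` (default: the space's actual bounding-box center) and
    matched to the nearest right-hemisphere vertex, one-to-one, resolving
    conflicts greedily in ascending residual order.  If the hemispheres
    have unequal sizes, ``min(nL, nR)`` pairs are formed and the unmatched
    count is recorded with a warning.
    """
    if box_center is None:
        box_center = space.bounding_box_center()
    box_center = np.asarray(box_center, dtype=float)

    left_ids = space.vertices_of(LEFT)
    right_ids = space.vertices_of(RIGHT)
    n_pairs = min(left_ids.size, right_ids.size)
    n_unmatched = abs(left_ids.size - right_ids.size)
    if n_unmatched:
        warnings.warn(
            f"hemispheres have unequal sizes ({left_ids.size} L vs "
            f"{right_ids.size} R); {n_unmatched} vertices left unmatched",
            stacklevel=2,
        )

    mirrored = space.coords[left_ids].copy()
    mirrored[:, 0] = 2.0 * box_center[0] - mirrored[:, 0]
    pairs, resid = _greedy_one_to_one(
        mirrored, left_ids, space.coords[right_ids], right_ids, n_pairs
    )

    # correlation of mirrored-left vs matched-right coordinates, axes pooled
    lpos = space.coords[pairs[:, 0]].copy()
    lpos[:, 0] = 2.0 * box_center[0] - lpos[:, 0]
    rpos = space.coords[pairs[:, 1]]
    a, b = lpos.ravel(), rpos.ravel()
    if a.size >= 2 and np.std(a) > 0 and np.std(b) > 0:
        corr = float(np.corrcoef(a, b)[0, 1])
    else:
        corr = 1.0 if np.allclose(a, b) else np.nan

    return HomologousPairing(
        pairs=pairs,
        match_residual=resid,
        coordinate_correlation=corr,
        n_unmatched=n_unmatched,
    )
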