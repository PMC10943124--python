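"""Seed-based functional connectivity of the hand-motor ROIs.

The seed signal is the unweighted mean of the member rows over retained
frames; the map is the Fisher-transformed Pearson correlation of that
signal with every grayordinate.  Seed vertices are not excluded from the
target map (ROI-level statistics exclude self-overlap downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import DenseTimeSeries
from .space import ROI, ScalarMap, SurfaceSpace

__all__ = ["SeedFcMap", "seed_timeseries", "seed_fc_map", "R_CLIP"]

# |r| is clipped to this bound before atanh so z stays finite
R_CLIP = 1.0 - 1e-7


@dataclass
class SeedFcMap:
    z: ScalarMap
    seed: ROI
    n_frames_used: int


def seed_timeseries(ts: DenseTimeSeries, roi: ROI) -> np.ndarray:
    """Unweighted mean of the ROI member rows, restricted to retained frames."""
    if roi.size == 0:
        raise ValueError(f"ROI {roi.name!r} is empty")
    if roi.members.max() >= ts.n_vertices:
        raise ValueError(f"ROI {roi.name!r} references vertices outside the series")
    if ts.n_retained < 3:
        raise ValueError(f"need >= 3 retained frames, have {ts.n_retained}")
    return ts.retained()[roi.members].mean(axis=0)


def seed_fc_map(ts: DenseTimeSeries, roi: ROI, space: SurfaceSpace) -> SeedFcMap:
    """Fisher-z map of the seed-mean signal against every grayordinate.

    r is clipped to ``|r| <= 1 - 1e-7`` before atanh; zero-variance target
    vertices get NaN.  A zero-variance seed mean is an error.
    """
    seed = seed_timeseries(ts, roi)
    seed_c = seed - seed.mean()
    seed_norm = np.linalg.norm(seed_c)
    if seed_norm == 0:
        raise ValueError(f"seed {roi.name!r} mean signal has zero variance")

    X = ts.retained()
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    ok = norms > 0
    r = np.full(ts.n_vertices, np.nan)
    r[ok] = (Xc[ok] @ seed_c) / (norms[ok] * seed_norm)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    if ts.n_vertices != space.n_vertices:
        raise ValueError("time series and space disagree on vertex count")
    return SeedFcMap(
        z=ScalarMap(z, space, name=f"rsfc_z_{roi.name}", units="z"),
        seed=roi,
        n_frames_used=ts.n_retained,
    )
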