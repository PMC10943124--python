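"""Subject-level temporal cleaning and group-level covariate removal.

The temporal stage is deliberately simple: a zero-phase Butterworth
band-pass on the full series, then frame censoring of high-motion frames
(the order is fixed — filter first, censor after — so that deleted frames
cannot leak spectral energy into their neighbours; the order is recorded
in pipeline provenance).  The group stage removes nuisance covariates
from per-subject measures either by least-squares residualization or by
multiplicative grand-mean scaling across strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "DenseTimeSeries",
    "ExclusionFlag",
    "PreprocessParams",
    "bandpass",
    "censor_high_motion",
    "build_design",
    "residualize_group",
    "residualize_matrix",
    "grand_mean_scale",
]

PROCESSING_ORDER = ("bandpass", "censor")


@dataclass
class DenseTimeSeries:
    """One subject's grayordinates-by-frames signal matrix.

    ``frame_mask`` marks frames retained for analysis; downstream
    correlation operations must use :meth:`retained` so that censored
    frames never contribute.
    """

    data: np.ndarray
    tr: float
    fd: np.ndarray | None = None
    frame_mask: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (grayordinates x frames)")
        if not self.tr or self.tr <= 0:
            raise ValueError("tr (seconds) must be positive")
        n_frames = self.data.shape[1]
        if self.fd is None:
            self.fd = np.zeros(n_frames)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.frame_mask is None:
            self.frame_mask = np.ones(n_frames, dtype=bool)
        self.frame_mask = np.asarray(self.frame_mask, dtype=bool)
        if self.fd.shape != (n_frames,) or self.frame_mask.shape != (n_frames,):
            raise ValueError("fd and frame_mask must have one entry per frame")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.frame_mask.sum())

    def retained(self) -> np.ndarray:
        """Signal restricted to retained frames."""
        return self.data[:, self.frame_mask]


@dataclass(frozen=True)
class ExclusionFlag:
    """Returned instead of a time series when a subject fails motion QC."""

    subject_id: str
    retained_fraction: float
    reason: str


@dataclass(frozen=True)
class PreprocessParams:
    band_low: float = 0.01
    band_high: float = 0.10
    fd_threshold: float = 0.5
    min_retained_fraction: float = 0.5
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if not (0 < self.min_retained_fraction <= 1):
            raise ValueError("min_retained_fraction must be in (0, 1]")


def bandpass(
    ts: DenseTimeSeries,
    band_low: float = 0.01,
    band_high: float = 0.10,
    order: int = 4,
) -> DenseTimeSeries:
    """Zero-phase Butterworth band-pass, applied identically to every row.

    The filter runs forward and backward (``sosfiltfilt``) so it has no
    temporal shift; output rows are explicitly demeaned.
    """
    nyquist = 0.5 / ts.tr
    if not (0 < band_low < band_high):
        raise ValueError("need 0 < band_low < band_high")
    if band_high >= nyquist:
        raise ValueError(
            f"band_high {band_high} Hz is at or above Nyquist {nyquist:.4f} Hz"
        )
    if ts.n_frames < 16:
        raise ValueError("need at least 16 frames to band-pass filter")
    sos = signal.butter(
        order, [band_low, band_high], btype="bandpass", fs=1.0 / ts.tr, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    filtered = filtered - filtered.mean(axis=1, keepdims=True)
    return replace(ts, data=filtered)


def censor_high_motion(
    ts: DenseTimeSeries,
    fd_threshold: float = 0.5,
    min_retained_fraction: float = 0.5,
) -> DenseTimeSeries | ExclusionFlag:
    """Clear the frame mask wherever FD exceeds the threshold.

    If fewer than ``min_retained_fraction`` of the frames survive, the
    subject is excluded: an :class:`ExclusionFlag` is returned instead of
    a time series (exclusion is a value, not an error).
    """
    mask = ts.frame_mask & (ts.fd <= fd_threshold)
    fraction = mask.sum() / ts.n_frames
    if fraction < min_retained_fraction:
        return ExclusionFlag(
            subject_id=ts.subject_id,
            retained_fraction=float(fraction),
            reason=(
                f"only {fraction:.1%} of frames with FD <= {fd_threshold} mm "
                f"(minimum {min_retained_fraction:.0%})"
            ),
        )
    return replace(ts, frame_mask=mask)


def build_design(
    covariates: pd.DataFrame, add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Build a numeric design matrix from a covariate table.

    Categorical columns (object / category / bool dtype) are one-hot
    encoded dropping the first level; constant columns are dropped with a
    log message (nothing to remove); a rank-deficient result raises with
    the offending column names.
    """
    pieces: list[pd.Series] = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            for dcol in dummies.columns:
                pieces.append(dummies[dcol].astype(float))
        else:
            pieces.append(s.astype(float))
    kept: list[pd.Series] = []
    for s in pieces:
        if np.ptp(s.to_numpy()) == 0:
            logger.info("dropping constant covariate column %r", s.name)
            continue
        kept.append(s)
    names = [str(s.name) for s in kept]
    n = len(covariates)
    cols = [np.ones(n)] if add_intercept else []
    cols.extend(s.to_numpy() for s in kept)
    if not cols:
        return np.empty((n, 0)), []
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that do not increase the rank incrementally
        collinear = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                label = "intercept" if (add_intercept and j == 0) else names[j - int(add_intercept)]
                collinear.append(label)
            r = rj
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return X, names


def residualize_group(
    values: np.ndarray, covariates: pd.DataFrame
) -> np.ndarray:
    """Remove covariate effects from a per-subject vector, keeping the mean.

    Fits ordinary least squares of ``values`` on an intercept plus the
    covariates and returns residuals plus the grand mean, so the output is
    orthogonal to every covariate column but preserves the original scale.
    """
    values = np.asarray(values, dtype=float)
    X, names = build_design(covariates)
    if X.shape[1] - 1 >= len(values) - 1:
        raise ValueError(
            f"need at least 2 more subjects ({len(values)}) than covariate "
            f"columns ({X.shape[1] - 1})"
        )
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    return resid + values.mean()


def residualize_matrix(Y: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """Column-wise :func:`residualize_group` for a subjects-by-vertices matrix.

    NaN entries propagate: a column containing NaN is residualized over its
    finite rows only, leaving NaN in place.
    """
    Y = np.asarray(Y, dtype=float)
    X, _ = build_design(covariates)
    out = np.empty_like(Y)
    finite_all = np.isfinite(Y).all(axis=0)
    if finite_all.any():
        Yf = Y[:, finite_all]
        beta, *_ = np.linalg.lstsq(X, Yf, rcond=None)
        out[:, finite_all] = Yf - X @ beta + Yf.mean(axis=0, keepdims=True)
    for j in np.flatnonzero(~finite_all):
        ok = np.isfinite(Y[:, j])
        col = np.full(Y.shape[0], np.nan)
        if ok.sum() > X.shape[1] + 1:
            beta, *_ = np.linalg.lstsq(X[ok], Y[ok, j], rcond=None)
            col[ok] = Y[ok, j] - X[ok] @ beta + Y[ok, j].mean()
        out[:, j] = col
    return out


def grand_mean_scale(values: np.ndarray, strata: np.ndarray) -> np.ndarray:
    """Multiplicative grand-mean scaling of a per-subject vector by stratum.

    Each subject's value is multiplied by (grand mean / stratum mean), so
    every stratum mean afterwards equals the grand mean.  Undefined (and an
    error) when any stratum mean is non-positive.
    """
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    if values.shape != strata.shape:
        raise ValueError("values and strata must align")
    grand = values.mean()
    out = values.copy()
    for s in np.unique(strata):
        sel = strata == s
        m = values[sel].mean()
        if m <= 0:
            raise ValueError(f"stratum {s!r} has non-positive mean {m}; scaling undefined")
        out[sel] = values[sel] * (grand / m)
    return out
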