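"""Group statistics: vertexwise t-maps, FDR, effect sizes, overlap, ROI models.

t-maps use the Student (pooled-variance) convention; Welch is available
as a switch.  Multiple-comparison control is Benjamini-Hochberg by
default with a Benjamini-Yekutieli option.  NaN vertices are handled
per-vertex with degree-of-freedom adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import build_design
from .space import ScalarMap, SurfaceSpace

logger = logging.getLogger(__name__)

__all__ = [
    "GroupContrastResult",
    "two_sample_t_map",
    "one_sample_t_map",
    "fdr_bh",
    "cohens_d",
    "dice",
    "roi_group_model",
    "ZERO_VARIANCE_T_SENTINEL",
]

# finite stand-in for an infinite one-sample t (zero variance, nonzero mean)
ZERO_VARIANCE_T_SENTINEL = 1e9


@dataclass
class GroupContrastResult:
    t: ScalarMap
    df: np.ndarray
    p: ScalarMap
    q: ScalarMap
    q_mask: np.ndarray
    alpha_fdr: float

    @property
    def n_significant(self) -> int:
        return int(self.q_mask.sum())


def _stack(maps, space: SurfaceSpace | None) -> tuple[np.ndarray, SurfaceSpace | None]:
    """Stack ScalarMaps (or a bare subjects-by-elements array) to 2-D.

    Bare arrays may come without a space (e.g. per-pair asymmetry
    vectors); the result maps are then returned as plain arrays.
    """
    if isinstance(maps, np.ndarray):
        return np.asarray(maps, dtype=float), space
    arrs = [m.values for m in maps]
    space = maps[0].space
    return np.vstack(arrs), space


def _wrap(values: np.ndarray, space: SurfaceSpace | None, name: str):
    return ScalarMap(values, space, name=name) if space is not None else values


def two_sample_t_map(
    group_a,
    group_b,
    space: SurfaceSpace | None = None,
    alpha_fdr: float = 0.05,
    welch: bool = False,
    fdr_method: str = "bh",
) -> GroupContrastResult:
    """Vertexwise two-sample t (2-sided), group A minus group B.

    Accepts lists of :class:`ScalarMap` or bare (subjects x vertices)
    arrays with an explicit ``space``.  NaN subjects are dropped per
    vertex with a per-vertex df adjustment; vertices with zero variance in
    both groups (or fewer than 2 finite subjects per group) are NaN.
    """
    A, space = _stack(group_a, space)
    B, _ = _stack(group_b, space)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups live on different spaces")

    nA = np.isfinite(A).sum(axis=0).astype(float)
    nB = np.isfinite(B).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mA, mB = np.nanmean(A, axis=0), np.nanmean(B, axis=0)
        vA = np.nanvar(A, axis=0, ddof=1)
        vB = np.nanvar(B, axis=0, ddof=1)

    ok = (nA >= 2) & (nB >= 2)
    t = np.full(A.shape[1], np.nan)
    df = np.full(A.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        if welch:
            se2 = vA / nA + vB / nB
            df_w = se2**2 / (
                (vA / nA) ** 2 / (nA - 1) + (vB / nB) ** 2 / (nB - 1)
            )
            t_all = (mA - mB) / np.sqrt(se2)
            df_all = df_w
        else:
            sp2 = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
            t_all = (mA - mB) / np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
            df_all = nA + nB - 2
    valid = ok & np.isfinite(t_all)
    t[valid] = t_all[valid]
    df[valid] = df_all[valid]

    p = np.full_like(t, np.nan)
    fin = np.isfinite(t)
    p[fin] = 2.0 * sps.t.sf(np.abs(t[fin]), df[fin])
    q_mask, q = fdr_bh(p, alpha_fdr, method=fdr_method)
    return GroupContrastResult(
        t=_wrap(t, space, "t"),
        df=df,
        p=_wrap(p, space, "p"),
        q=_wrap(q, space, "q"),
        q_mask=q_mask,
        alpha_fdr=alpha_fdr,
    )


def one_sample_t_map(
    maps,
    space: SurfaceSpace | None = None,
    popmean: float = 0.0,
    alpha_fdr: float = 0.05,
    fdr_method: str = "bh",
) -> GroupContrastResult:
    """Vertexwise one-sample t against ``popmean`` (2-sided).

    A zero-variance vertex whose mean differs from ``popmean`` gets a
    large finite sentinel t (+-1e9) with a warning instead of infinity;
    zero variance with mean equal to ``popmean`` gives t = 0.
    """
    Y, space = _stack(maps, space)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    n = np.isfinite(Y).sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(Y, axis=0) - popmean
        s = np.nanstd(Y, axis=0, ddof=1)

    t = np.full(Y.shape[1], np.nan)
    df = np.where(n >= 2, n - 1, np.nan)
    ok = n >= 2
    zero_var = ok & (s == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t[ok] = m[ok] / (s[ok] / np.sqrt(n[ok]))
    t[zero_var & (m == 0)] = 0.0
    sentinel = zero_var & (m != 0)
    if sentinel.any():
        warnings.warn(
            f"{int(sentinel.sum())} zero-variance vertices with nonzero mean; "
            f"t set to +-{ZERO_VARIANCE_T_SENTINEL:.0e}",
            stacklevel=2,
        )
        t[sentinel] = np.sign(m[sentinel]) * ZERO_VARIANCE_T_SENTINEL

    p = np.full_like(t, np.nan)
    fin = np.isfinite(t) & np.isfinite(df)
    p[fin] = 2.0 * sps.t.sf(np.abs(t[fin]), df[fin])
    q_mask, q = fdr_bh(p, alpha_fdr, method=fdr_method)
    return GroupContrastResult(
        t=_wrap(t, space, "t"),
        df=df,
        p=_wrap(p, space, "p"),
        q=_wrap(q, space, "q"),
        q_mask=q_mask,
        alpha_fdr=alpha_fdr,
    )


def fdr_bh(
    p: np.ndarray, alpha: float = 0.05, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control (``method="by"`` for
    Benjamini-Yekutieli).

    NaN p-values are excluded from the test count m and stay NaN in the
    q-values; returns ``(reject_mask, q_values)`` aligned with ``p``.
    """
    p = np.asarray(p, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    q = np.full(p.shape, np.nan)
    fin = np.isfinite(p)
    m = int(fin.sum())
    if m == 0:
        return mask, q
    pf = p[fin]
    if (pf < 0).any() or (pf > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pf, kind="stable")
    ranked = pf[order]
    denom = np.arange(1, m + 1, dtype=float)
    c_m = np.sum(1.0 / denom) if method == "by" else 1.0
    if method not in ("bh", "by"):
        raise ValueError(f"unknown FDR method {method!r}")
    raw_q = ranked * m * c_m / denom
    qs = np.minimum.accumulate(raw_q[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    passing = np.flatnonzero(ranked <= denom * alpha / (m * c_m))
    rej = np.zeros(m, dtype=bool)
    if passing.size:
        rej[: passing[-1] + 1] = True
    out_rej = np.zeros(m, dtype=bool)
    out_q = np.empty(m)
    out_rej[order] = rej
    out_q[order] = qs
    mask[fin] = out_rej
    q[fin] = out_q
    return mask, q


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean(a) - mean(b)) / pooled SD, with the unbiased pooled variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 finite values per group")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else float("inf") * np.sign(a.mean() - b.mean())
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """2|A and B| / (|A| + |B|); two empty masks score 1.0 by convention."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a space")
    denom = a.sum() + b.sum()
    if denom == 0:
        logger.info("dice of two empty masks: returning 1.0 by convention")
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def roi_group_model(
    values: np.ndarray,
    cohort: pd.DataFrame,
    covariates: list[str],
    group_col: str = "group",
) -> dict:
    """Linear model of per-subject ROI means on group plus covariates.

    Group enters categorically; constant covariates are dropped (see
    :func:`handlat.preprocess.build_design`), and a rank-deficient design
    raises.  Returns the overall group F-test and all pairwise group
    contrasts (t, p, estimate); on a two-group design with no informative
    covariates this reduces to the pooled two-sample t exactly.
    """
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    if len(values) != len(cohort):
        raise ValueError("values and cohort must align")
    groups = cohort[group_col].astype(str).to_numpy()
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 group levels")

    # group dummies (drop first level) + covariate design
    gdum = pd.get_dummies(pd.Series(groups, name=group_col), prefix=group_col).astype(
        float
    )
    Xcov, cov_names = build_design(cohort[covariates], add_intercept=False)
    X = np.column_stack(
        [np.ones(len(values))]
        + [gdum[f"{group_col}_{lv}"].to_numpy() for lv in levels[1:]]
        + ([Xcov] if Xcov.shape[1] else [])
    )
    names = ["intercept"] + [f"{group_col}_{lv}" for lv in levels[1:]] + cov_names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        collinear = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                collinear.append(names[j])
            r = rj
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    model = sm.OLS(values, X)
    fit = model.fit()

    # overall group effect: F-test on the group dummy block
    k = len(levels) - 1
    R = np.zeros((k, X.shape[1]))
    for i in range(k):
        R[i, 1 + i] = 1.0
    ftest = fit.f_test(R)

    # pairwise contrasts between group levels
    rows = []
    coef = {lv: 0.0 for lv in levels}
    col_of = {lv: 1 + i for i, lv in enumerate(levels[1:])}
    for i, la in enumerate(levels):
        for lb in levels[i + 1 :]:
            c = np.zeros(X.shape[1])
            if la in col_of:
                c[col_of[la]] += 1.0
            if lb in col_of:
                c[col_of[lb]] -= 1.0
            tt = fit.t_test(c)
            rows.append(
                {
                    "contrast": f"{la}-{lb}",
                    "estimate": float(np.ravel(tt.effect)[0]),
                    "t": float(np.ravel(tt.tvalue)[0]),
                    "p": float(np.ravel(tt.pvalue)[0]),
                    "df": float(fit.df_resid),
                }
            )
    return {
        "group_F": float(ftest.fvalue),
        "group_p": float(ftest.pvalue),
        "df_num": int(k),
        "df_den": float(fit.df_resid),
        "pairwise": pd.DataFrame(rows),
        "covariates_used": cov_names,
        "fit": fit,
    }
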