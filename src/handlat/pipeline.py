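"""Study orchestration: run the full analysis on a synthetic cohort.

Stage order (recorded in provenance): generate -> band-pass filter ->
motion censoring -> per-subject thresholded-degree maps (all hemisphere
scopes and both edge signs) -> seed connectivity maps -> subject indices
-> group covariate removal -> vertexwise contrasts with FDR -> asymmetry
-> report.  A subject that fails motion QC is excluded with a logged
reason; the run aborts if more than half the cohort is excluded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fcd import FcdResult, Scope, Sign, compute_fcd_profile
from .indices import handedness_index, laterality_map, roi_delta
from .preprocess import (
    PROCESSING_ORDER,
    DenseTimeSeries,
    ExclusionFlag,
    PreprocessParams,
    bandpass,
    censor_high_motion,
    grand_mean_scale,
    residualize_matrix,
)
from .seedfc import seed_fc_map
from .space import ROI
from .stats import cohens_d, dice, one_sample_t_map, roi_group_model, two_sample_t_map
from .synth import GeneratedSpace, GeneratorParams, generate_cohort, generate_space, generate_subject_timeseries
from .indices import asymmetry_map

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "split_discovery_replication",
    "simulate_handedness_index",
    "calibrate_motor_effect",
]


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to (re)run a study deterministically."""

    n_per_group: int = 60
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    fcd_threshold: float = 0.6
    chunk_size: int = 256
    log_base: str = "natural"
    include_negative: bool = True
    alpha_fdr: float = 0.05
    split_fraction: float = 0.505
    covariates: tuple[str, ...] = (
        "mean_fd",
        "age_months",
        "sex",
        "race",
        "site",
        "scanner",
    )
    seed: int = 0
    laterality_on_z: bool = True  # apply the laterality ratio to Fisher z (else raw r)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = GeneratorParams(**d["generator"])
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessParams(**d["preprocess"])
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d


@dataclass
class StudyReport:
    cohort: pd.DataFrame
    records: pd.DataFrame
    group_maps: dict
    contrasts: dict
    index_ehis: pd.DataFrame
    roi_delta_records: pd.DataFrame
    roi_delta_stats: pd.DataFrame
    asymmetry: dict
    dice_table: pd.DataFrame
    exclusions: pd.DataFrame
    provenance: dict
    gspace: GeneratedSpace


def split_discovery_replication(
    cohort: pd.DataFrame, fraction: float = 0.505, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified (group x sex) split into disjoint Discovery/Replication.

    Within each handedness group the Discovery target is
    ``round(fraction * n_group)``, allocated across sex strata by largest
    remainder, so per-group counts deviate from the stratified target by
    at most 1.  Deterministic under ``seed``.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(17,)))
    disc_idx: list[int] = []
    for group, gdf in cohort.groupby("group", sort=True):
        if len(gdf) < 4:
            raise ValueError(f"need >= 4 subjects per group, {group} has {len(gdf)}")
        target = int(round(fraction * len(gdf)))
        strata = [(sex, sdf) for sex, sdf in gdf.groupby("sex", sort=True)]
        quotas = np.array([fraction * len(sdf) for _, sdf in strata])
        base = np.floor(quotas).astype(int)
        short = target - base.sum()
        order = np.argsort(-(quotas - base), kind="stable")
        for j in order[: max(short, 0)]:
            base[j] += 1
        for sidx, (_, sdf) in enumerate(strata):
            take = min(base[sidx], len(sdf))
            picked = rng.permutation(len(sdf))[:take]
            disc_idx.extend(sdf.index[picked])
    disc_mask = cohort.index.isin(disc_idx)
    return cohort[disc_mask].copy(), cohort[~disc_mask].copy()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return float("nan")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def _scaled_index(
    ml_vals: np.ndarray, mr_vals: np.ndarray, strata: np.ndarray
) -> np.ndarray:
    """Handedness index after per-stratum grand-mean scaling of both inputs.

    Falls back to unscaled values (with a log message) when any stratum
    mean is non-positive, which happens for near-empty edge-count scopes.
    """
    try:
        ml_s = grand_mean_scale(ml_vals, strata)
        mr_s = grand_mean_scale(mr_vals, strata)
    except ValueError as e:
        logger.info("grand-mean scaling skipped: %s", e)
        ml_s, mr_s = ml_vals, mr_vals
    denom = ml_s + mr_s
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(np.abs(denom) > 1e-9, (ml_s - mr_s) / denom, np.nan)
    return idx


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full study described by ``config``; optionally persist it."""
    params = replace(config.generator, seed=config.seed)
    gspace = generate_space(params)
    space = gspace.space
    cohort = generate_cohort(config.n_per_group, params)
    pp = config.preprocess

    scopes = [(Sign.POSITIVE, Scope.GLOBAL), (Sign.POSITIVE, Scope.IPSI), (Sign.POSITIVE, Scope.CONTRA)]
    if config.include_negative:
        scopes.append((Sign.NEGATIVE, Scope.GLOBAL))

    gfcd_stacks: dict[tuple[Sign, Scope], list[np.ndarray]] = {k: [] for k in scopes}
    delta_stack: list[np.ndarray] = []
    asym_stack: list[np.ndarray] = []
    rec_rows: list[dict] = []
    excl_rows: list[dict] = []
    included_idx: list[int] = []

    report_rois: list[tuple[str, np.ndarray]] = [
        ("periMl", gspace.ml_halo),
        ("periMr", gspace.mr_halo),
    ]
    seed_members = np.union1d(gspace.ml.members, gspace.mr.members)

    for i, row in cohort.iterrows():
        ts = generate_subject_timeseries(gspace, row, params)
        ts = bandpass(ts, pp.band_low, pp.band_high, order=pp.filter_order)
        res = censor_high_motion(ts, pp.fd_threshold, pp.min_retained_fraction)
        if isinstance(res, ExclusionFlag):
            logger.warning("excluding %s: %s", res.subject_id, res.reason)
            excl_rows.append(
                {
                    "subject_id": res.subject_id,
                    "retained_fraction": res.retained_fraction,
                    "reason": res.reason,
                }
            )
            continue
        ts = res

        profile = compute_fcd_profile(
            ts, space, threshold=config.fcd_threshold,
            chunk_size=config.chunk_size, log_base=config.log_base,
        )
        for key in scopes:
            gfcd_stacks[key].append(profile[key].gfcd.values)

        z_ml = seed_fc_map(ts, gspace.ml, space)
        z_mr = seed_fc_map(ts, gspace.mr, space)
        if config.laterality_on_z:
            lat = laterality_map(z_ml, z_mr)
            delta_stack.append(lat.delta.values)
        else:
            import copy

            r_ml = copy.deepcopy(z_ml)
            r_mr = copy.deepcopy(z_mr)
            r_ml.z.values = np.tanh(r_ml.z.values)
            r_mr.z.values = np.tanh(r_mr.z.values)
            lat = laterality_map(r_ml, r_mr)
            delta_stack.append(lat.delta.values)

        g_map = profile[(Sign.POSITIVE, Scope.GLOBAL)].gfcd
        asym_stack.append(asymmetry_map(g_map, gspace.pairing))

        rec = {
            "subject_id": row["subject_id"],
            "group": row["group"],
            "ehis_score": row["ehis_score"],
            "n_frames_retained": ts.n_retained,
        }
        for sign, scope in scopes:
            g = profile[(sign, scope)].gfcd.values
            rec[f"gfcd_ml_{sign.value}_{scope.value}"] = float(
                np.mean(g[gspace.ml.members])
            )
            rec[f"gfcd_mr_{sign.value}_{scope.value}"] = float(
                np.mean(g[gspace.mr.members])
            )
        for roi_name, members in report_rois:
            clean = np.setdiff1d(members, seed_members)
            roi_obj = _roi_like(roi_name, clean, gspace, space)
            rec[f"delta_{roi_name}"] = roi_delta(z_ml, z_mr, roi_obj)
            rec[f"z_ml_{roi_name}"] = float(np.nanmean(z_ml.z.values[clean]))
            rec[f"z_mr_{roi_name}"] = float(np.nanmean(z_mr.z.values[clean]))
        rec_rows.append(rec)
        included_idx.append(i)

    n_total = len(cohort)
    if len(excl_rows) > 0.5 * n_total:
        raise RuntimeError(
            f"{len(excl_rows)} of {n_total} subjects excluded for motion; aborting"
        )

    records = pd.DataFrame(rec_rows)
    sub_cohort = cohort.loc[included_idx].reset_index(drop=True)
    records = records.reset_index(drop=True)

    # -- subject indices (grand-mean scaled by sex x race strata) ----------
    strata = (sub_cohort["sex"].astype(str) + "|" + sub_cohort["race"].astype(str)).to_numpy()
    for sign, scope in scopes:
        tag = f"{sign.value}_{scope.value}"
        records[f"handedness_index_{tag}"] = _scaled_index(
            records[f"gfcd_ml_{tag}"].to_numpy(),
            records[f"gfcd_mr_{tag}"].to_numpy(),
            strata,
        )
    records["handedness_index"] = records["handedness_index_positive_global"]

    # -- discovery / replication split -------------------------------------
    disc, repl = split_discovery_replication(
        sub_cohort, fraction=config.split_fraction, seed=config.seed
    )
    split_label = np.where(sub_cohort.index.isin(disc.index), "discovery", "replication")
    records["split"] = split_label

    index_rows = []
    for split_name in ("discovery", "replication", "all"):
        sel = np.ones(len(records), bool) if split_name == "all" else (records["split"] == split_name).to_numpy()
        r = _pearson(
            records.loc[sel, "handedness_index"].to_numpy(),
            records.loc[sel, "ehis_score"].to_numpy(),
        )
        index_rows.append({"split": split_name, "r_index_ehis": r, "n": int(sel.sum())})
    index_ehis = pd.DataFrame(index_rows)

    # -- vertexwise contrasts (L vs R) on residualized maps -----------------
    cov_df = sub_cohort[list(config.covariates)]
    is_l = (records["group"] == "L").to_numpy()
    is_r = (records["group"] == "R").to_numpy()
    contrasts: dict[str, object] = {}
    group_maps: dict[str, np.ndarray] = {}
    for (sign, scope), stack in gfcd_stacks.items():
        Y = np.vstack(stack)
        tag = f"gfcd_{sign.value}_{scope.value}"
        for gname in ("L", "R", "M"):
            gsel = (records["group"] == gname).to_numpy()
            group_maps[f"{tag}_mean_{gname}"] = Y[gsel].mean(axis=0)
        Yr = residualize_matrix(Y, cov_df)
        contrasts[f"{tag}_LvsR"] = two_sample_t_map(
            Yr[is_l], Yr[is_r], space=space, alpha_fdr=config.alpha_fdr
        )
    D = np.vstack(delta_stack)
    Dr = residualize_matrix(D, cov_df)
    contrasts["delta_LvsR"] = two_sample_t_map(
        Dr[is_l], Dr[is_r], space=space, alpha_fdr=config.alpha_fdr
    )
    for gname in ("L", "R"):
        gsel = (records["group"] == gname).to_numpy()
        group_maps[f"delta_mean_{gname}"] = np.nanmean(D[gsel], axis=0)

    # -- ROI laterality models ---------------------------------------------
    roi_rows = []
    roi_stat_rows = []
    for roi_name, _ in report_rois:
        col = f"delta_{roi_name}"
        for _, rrow in records.iterrows():
            roi_rows.append(
                {
                    "roi": roi_name,
                    "subject_id": rrow["subject_id"],
                    "group": rrow["group"],
                    "split": rrow["split"],
                    "delta": rrow[col],
                }
            )
        for split_name in ("discovery", "replication", "all"):
            sel = (
                np.ones(len(records), bool)
                if split_name == "all"
                else (records["split"] == split_name).to_numpy()
            )
            vals = records.loc[sel, col].to_numpy()
            grp = sub_cohort.loc[sel]
            try:
                model = roi_group_model(vals, grp, list(config.covariates))
                pair = model["pairwise"].set_index("contrast")
                lr_t = float(pair.loc["L-R", "t"]) if "L-R" in pair.index else np.nan
                lr_p = float(pair.loc["L-R", "p"]) if "L-R" in pair.index else np.nan
            except ValueError:
                lr_t, lr_p = np.nan, np.nan
            means = {
                g: float(np.nanmean(vals[(grp["group"] == g).to_numpy()]))
                for g in ("L", "M", "R")
            }
            roi_stat_rows.append(
                {
                    "roi": roi_name,
                    "split": split_name,
                    "mean_L": means["L"],
                    "mean_M": means["M"],
                    "mean_R": means["R"],
                    "t_LvsR": lr_t,
                    "p_LvsR": lr_p,
                    "cohens_d_LvsR": cohens_d(
                        vals[(grp["group"] == "L").to_numpy()],
                        vals[(grp["group"] == "R").to_numpy()],
                    ),
                }
            )
    roi_delta_records = pd.DataFrame(roi_rows)
    roi_delta_stats = pd.DataFrame(roi_stat_rows)

    # -- asymmetry ----------------------------------------------------------
    A = np.vstack(asym_stack)  # subjects x pairs
    asym: dict[str, object] = {}
    masks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for gname in ("L", "R", "M"):
        gsel = (records["group"] == gname).to_numpy()
        if gsel.sum() >= 2:
            res = one_sample_t_map(A[gsel], alpha_fdr=config.alpha_fdr)
            asym[f"one_sample_{gname}"] = res
            masks[gname] = (res.q_mask & (res.t > 0), res.q_mask & (res.t < 0))
    Ar = residualize_matrix(A, cov_df)
    asym["two_sample_LvsR"] = two_sample_t_map(
        Ar[is_l], Ar[is_r], alpha_fdr=config.alpha_fdr
    )

    dice_rows = []
    for ga, gb in (("R", "L"), ("R", "M"), ("L", "M")):
        if ga in masks and gb in masks:
            dice_rows.append(
                {
                    "pair": f"{ga}-{gb}",
                    "dice_positive": dice(masks[ga][0], masks[gb][0]),
                    "dice_negative": dice(masks[ga][1], masks[gb][1]),
                }
            )
    dice_table = pd.DataFrame(dice_rows)

    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "processing_order": list(PROCESSING_ORDER),
        "n_subjects": n_total,
        "n_included": len(records),
        "n_excluded": len(excl_rows),
        "versions": _library_versions(),
    }

    report = StudyReport(
        cohort=cohort,
        records=records,
        group_maps=group_maps,
        contrasts=contrasts,
        index_ehis=index_ehis,
        roi_delta_records=roi_delta_records,
        roi_delta_stats=roi_delta_stats,
        asymmetry=asym,
        dice_table=dice_table,
        exclusions=pd.DataFrame(
            excl_rows, columns=["subject_id", "retained_fraction", "reason"]
        ),
        provenance=provenance,
        gspace=gspace,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _roi_like(name: str, members: np.ndarray, gspace: GeneratedSpace, space) -> ROI:
    """Wrap a bare member set as an ROI (center = member closest to centroid)."""
    centroid = space.coords[members].mean(axis=0)
    center = int(members[np.argmin(np.linalg.norm(space.coords[members] - centroid, axis=1))])
    hemi = int(space.hemisphere[center])
    radius = float(np.linalg.norm(space.coords[members] - space.coords[center], axis=1).max()) or 1.0
    return ROI(name=name, center_vertex=center, radius=radius, hemisphere=hemi, members=members)


def _library_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Persist the report as deterministic plain files (TSV + JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    report.cohort.to_csv(out / "cohort.tsv", sep="\t", index=False, float_format=fmt)
    report.records.to_csv(out / "subject_records.tsv", sep="\t", index=False, float_format=fmt)
    report.index_ehis.to_csv(out / "index_ehis_correlation.tsv", sep="\t", index=False, float_format=fmt)
    report.roi_delta_records.to_csv(out / "roi_delta_subjects.tsv", sep="\t", index=False, float_format=fmt)
    report.roi_delta_stats.to_csv(out / "roi_delta_stats.tsv", sep="\t", index=False, float_format=fmt)
    report.dice_table.to_csv(out / "dice_consistency.tsv", sep="\t", index=False, float_format=fmt)
    report.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False, float_format=fmt)

    contrast_cols = {}
    for name, res in report.contrasts.items():
        contrast_cols[f"{name}_t"] = np.asarray(res.t.values if hasattr(res.t, "values") else res.t)
        contrast_cols[f"{name}_q"] = np.asarray(res.q.values if hasattr(res.q, "values") else res.q)
        contrast_cols[f"{name}_sig"] = res.q_mask.astype(int)
    pd.DataFrame(contrast_cols).to_csv(
        out / "vertexwise_contrasts.tsv", sep="\t", index=False, float_format=fmt
    )
    pd.DataFrame(report.group_maps).to_csv(
        out / "group_maps.tsv", sep="\t", index=False, float_format=fmt
    )
    (out / "provenance.json").write_text(json.dumps(report.provenance, indent=2, sort_keys=True))

    from .io import write_pairing_tsv, write_space_tsv

    write_space_tsv(out / "space.tsv", report.gspace.space)
    write_pairing_tsv(out / "pairing.tsv", report.gspace.pairing)


# ---------------------------------------------------------------------------
# effect-size calibration helpers

def simulate_handedness_index(
    params: GeneratorParams,
    n_per_group: int,
    groups: tuple[str, ...] = ("L", "R"),
    preprocess: PreprocessParams | None = None,
    fcd_threshold: float = 0.6,
    gspace: GeneratedSpace | None = None,
) -> dict[str, np.ndarray]:
    """Per-group handedness-index samples from a minimal generator->index run.

    Runs only the stages the index needs (generate, filter, censor,
    thresholded-degree map, ROI means) without grand-mean scaling, so it
    is cheap enough for calibration loops.  Excluded subjects are skipped.
    ``gspace`` pins the geometry (the *design*); when given, the seed only
    varies the cohort draw and subject-level noise.
    """
    from .fcd import compute_fcd_profile
    from .indices import handedness_index

    pp = preprocess or PreprocessParams()
    if gspace is None:
        gspace = generate_space(params)
    cohort = generate_cohort(n_per_group, params)
    cohort = cohort[cohort["group"].isin(groups)]
    out: dict[str, list[float]] = {g: [] for g in groups}
    for _, row in cohort.iterrows():
        ts = generate_subject_timeseries(gspace, row, params)
        ts = bandpass(ts, pp.band_low, pp.band_high, order=pp.filter_order)
        ts = censor_high_motion(ts, pp.fd_threshold, pp.min_retained_fraction)
        if isinstance(ts, ExclusionFlag):
            continue
        profile = compute_fcd_profile(ts, gspace.space, threshold=fcd_threshold)
        gfcd = profile[(Sign.POSITIVE, Scope.GLOBAL)].gfcd
        rec = handedness_index(gfcd, gspace.ml, gspace.mr, row["subject_id"])
        out[row["group"]].append(rec.handedness_index)
    return {g: np.asarray(v) for g, v in out.items()}


def calibrate_motor_effect(
    target_d: float,
    params: GeneratorParams,
    n_pilot: int = 300,
    lo: float = 0.02,
    hi: float = 0.8,
    n_iter: int = 7,
    n_reps: int = 3,
) -> float:
    """Tune ``motor_asymmetry_effect`` so the R-vs-L Cohen's d of the
    handedness index matches ``target_d``.

    Bisection on the (monotone in expectation) effect -> d response,
    evaluated at a fixed pilot seed so the search sees a smooth function.
    The geometry is built once from ``params`` and held fixed: the design
    effect size belongs to a design, not to a particular geometry draw.
    Returns the calibrated effect value.
    """
    gspace = generate_space(params)

    def estimate(effect: float) -> float:
        # average replicate cohort draws to tame pilot sampling noise
        ds = []
        for rep in range(n_reps):
            p = replace(
                params, motor_asymmetry_effect=effect, seed=params.seed + 7919 * rep
            )
            res = simulate_handedness_index(p, n_pilot, gspace=gspace)
            ds.append(cohens_d(res["R"], res["L"]))
        return float(np.mean(ds))

    d_lo, d_hi = estimate(lo), estimate(hi)
    if d_hi < target_d:
        return hi
    if d_lo > target_d:
        return lo
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        d_mid = estimate(mid)
        if d_mid < target_d:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
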