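"""Synthetic cohort generator for end-to-end testing without any download.

The generator emulates, at configurable desk scale, the statistical
structure the analysis relies on:

* a mirror-symmetric pair of hemisphere-like vertex clouds with
  designated hand-motor patches (Ml on the left, Mr on the right) at
  mirrored locations and posterior connectivity hubs;
* BOLD-like per-subject signals from a latent-factor (low-rank + noise)
  model with homotopic coupling between mirror twins, a shared hub
  factor, and hand-motor factors whose intra-hemispheric coupling shifts
  with the subject's handedness score;
* framewise-displacement traces with censorable spikes;
* a cohort table with four-item handedness inventory scores and
  demographic covariates.

All randomness flows from a single master seed through named substreams
(space, cohort, subject i), so any subject can be regenerated in
isolation and two runs with the same seed are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .space import (
    LEFT,
    RIGHT,
    ROI,
    HomologousPairing,
    SurfaceSpace,
    roi_from_center,
)
from .preprocess import DenseTimeSeries

__all__ = [
    "GeneratorParams",
    "GeneratedSpace",
    "generate_space",
    "generate_subject_timeseries",
    "generate_cohort",
]

# substream labels
_STREAM_SPACE = 0
_STREAM_COHORT = 1
_STREAM_SUBJECT = 2

EHIS_ITEM_LEVELS = (100, 50, 0, -50, -100)

RACE_LEVELS = ("White", "Hispanic", "AfricanAmerican", "Asian", "Other")
RACE_PROBS = (0.535, 0.183, 0.180, 0.008, 0.094)
SCANNER_LEVELS = ("Siemens", "GE", "Philips")
SCANNER_PROBS = (0.65, 0.22, 0.13)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic study; defaults are desk-scale."""

    n_vertices_per_hemi: int = 200
    n_frames: int = 256
    tr: float = 0.8
    hub_fraction: float = 0.08
    homotopic_rho: float = 0.3
    motor_coupling_base: float = 1.3
    motor_asymmetry_effect: float = 0.0
    noise_sd: float = 1.0
    fd_spike_rate: float = 0.03
    seed: int = 0
    # geometry
    sphere_radius: float = 70.0
    mirror_jitter_sd: float = 0.0
    motor_patch_radius: float = 25.0
    motor_halo_radius_factor: float = 1.8
    motor_halo_weight: float = 0.4
    # weak coupling of each motor patch to the opposite hemisphere's motor
    # factor, so seed maps have a contralateral component and the laterality
    # ratio is responsive rather than saturated near +-1
    motor_contra_weight: float = 0.25
    hub_weight: float = 1.5
    fd_baseline_mean: float = 0.12
    fd_baseline_sd: float = 0.04

    def __post_init__(self) -> None:
        for name in ("hub_fraction", "homotopic_rho", "fd_spike_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_frames < 64:
            raise ValueError("n_frames must be >= 64")
        if self.n_vertices_per_hemi < 50:
            raise ValueError("need at least 50 vertices per hemisphere")
        if self.motor_asymmetry_effect < 0:
            raise ValueError("motor_asymmetry_effect must be non-negative")


@dataclass
class GeneratedSpace:
    """A synthetic space together with its generation ground truth."""

    space: SurfaceSpace
    pairing: HomologousPairing  # ground-truth mirror pairing
    ml: ROI
    mr: ROI
    hub_vertices: np.ndarray  # global vertex ids, both hemispheres
    ml_halo: np.ndarray  # same-hemisphere surround of Ml (excl. members)
    mr_halo: np.ndarray


def generate_space(params: GeneratorParams) -> GeneratedSpace:
    """Sample a mirror-symmetric two-hemisphere vertex cloud.

    Left-hemisphere vertices are sampled on a hemisphere-like shell of
    radius ``sphere_radius`` (x < 0); the right hemisphere is the exact
    x-mirror, plus optional Gaussian jitter of ``mirror_jitter_sd`` mm.
    Vertex ``i`` (left) and vertex ``n + i`` (right) are mirror twins, and
    that ground-truth pairing is returned.  Hand-motor patches are grown
    around a lateral-superior vertex and its mirror twin; hubs sit at the
    posterior end (most negative y) of each hemisphere.
    """
    rng = _rng(params.seed, _STREAM_SPACE)
    n = params.n_vertices_per_hemi

    dirs = rng.standard_normal((n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs[:, 0] = -np.abs(dirs[:, 0]) - 0.05  # strictly left of the midline
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radius = params.sphere_radius * (1.0 + 0.02 * rng.standard_normal(n))
    left = dirs * radius[:, None]

    right = left.copy()
    right[:, 0] = -right[:, 0]
    if params.mirror_jitter_sd > 0:
        right = right + params.mirror_jitter_sd * rng.standard_normal(right.shape)

    coords = np.vstack([left, right])
    hemi = np.concatenate([np.full(n, LEFT, np.int8), np.full(n, RIGHT, np.int8)])
    space = SurfaceSpace(coords=coords, hemisphere=hemi)

    pairs = np.column_stack([np.arange(n), np.arange(n) + n])
    mirrored = left.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    resid = np.linalg.norm(mirrored - right, axis=1)
    a, b = mirrored.ravel(), right.ravel()
    corr = float(np.corrcoef(a, b)[0, 1])
    pairing = HomologousPairing(
        pairs=pairs, match_residual=resid, coordinate_correlation=corr
    )

    # hand-motor patch: lateral and slightly superior-anterior on the left
    target = params.sphere_radius * np.array([-0.85, 0.25, 0.45])
    target /= np.linalg.norm(target) / params.sphere_radius
    ml_center = int(np.argmin(np.linalg.norm(left - target, axis=1)))
    mr_center = ml_center + n
    ml = roi_from_center(space, ml_center, params.motor_patch_radius, name="Ml")
    mr = roi_from_center(space, mr_center, params.motor_patch_radius, name="Mr")

    halo_r = params.motor_halo_radius_factor * params.motor_patch_radius
    ml_halo = np.setdiff1d(
        roi_from_center(space, ml_center, halo_r, name="_").members, ml.members
    )
    mr_halo = np.setdiff1d(
        roi_from_center(space, mr_center, halo_r, name="_").members, mr.members
    )

    # posterior hubs (most negative y), mirror-symmetric by construction
    k = max(1, round(params.hub_fraction * n))
    hub_left = np.argsort(left[:, 1], kind="stable")[:k]
    hub_vertices = np.concatenate([hub_left, hub_left + n])

    return GeneratedSpace(
        space=space,
        pairing=pairing,
        ml=ml,
        mr=mr,
        hub_vertices=np.sort(hub_vertices),
        ml_halo=ml_halo,
        mr_halo=mr_halo,
    )


def _motor_weights(params: GeneratorParams, ehis_score: float) -> tuple[float, float]:
    """Intra-hemispheric coupling of the Ml and Mr patches for one subject.

    The asymmetry shift is signed by the handedness score (positive score
    = right-handed direction: Ml up, Mr down) and scaled by |score|/100.
    """
    shift = params.motor_asymmetry_effect * ehis_score / 100.0
    w_ml = params.motor_coupling_base * (1.0 + shift)
    w_mr = params.motor_coupling_base * (1.0 - shift)
    return max(w_ml, 0.0), max(w_mr, 0.0)


def generate_subject_timeseries(
    gspace: GeneratedSpace,
    row: pd.Series | dict,
    params: GeneratorParams,
) -> DenseTimeSeries:
    """Latent-factor BOLD-like series for one cohort row.

    Per vertex: sqrt(rho) x homotopic pair factor + sqrt(1-rho) x private
    noise, plus a shared hub factor on hub vertices and a hand-motor
    factor on the Ml (resp. Mr) patch and, at reduced weight, its
    same-hemisphere halo.  The per-subject substream is keyed by the
    cohort row's ``subject_index``, so any subject regenerates in
    isolation.
    """
    idx = int(row["subject_index"])
    rng = _rng(params.seed, _STREAM_SUBJECT, idx)
    n = params.n_vertices_per_hemi
    N = 2 * n
    T = params.n_frames
    rho = params.homotopic_rho

    noise = rng.standard_normal((N, T))
    pair_factors = rng.standard_normal((n, T))
    hub_factor = rng.standard_normal(T)
    m_l = rng.standard_normal(T)
    m_r = rng.standard_normal(T)

    data = np.sqrt(1.0 - rho) * noise
    data[:n] += np.sqrt(rho) * pair_factors
    data[n:] += np.sqrt(rho) * pair_factors
    data[gspace.hub_vertices] += params.hub_weight * hub_factor

    w_ml, w_mr = _motor_weights(params, float(row["ehis_score"]))
    # patches load only their own factor (seed signals stay pure); the
    # surrounding halos couple to both motor factors, with the
    # contralateral arm fixed at base strength so that group membership
    # shifts intra-hemispheric coupling only
    c = params.motor_contra_weight * params.motor_coupling_base
    data[gspace.ml.members] += w_ml * m_l
    data[gspace.ml_halo] += params.motor_halo_weight * (w_ml * m_l + c * m_r)
    data[gspace.mr.members] += w_mr * m_r
    data[gspace.mr_halo] += params.motor_halo_weight * (w_mr * m_r + c * m_l)
    data *= params.noise_sd

    fd = np.abs(
        params.fd_baseline_mean + params.fd_baseline_sd * rng.standard_normal(T)
    )
    spikes = rng.random(T) < params.fd_spike_rate
    fd[spikes] = 0.55 + rng.exponential(0.25, size=int(spikes.sum()))

    return DenseTimeSeries(
        data=data,
        tr=params.tr,
        fd=fd,
        subject_id=str(row.get("subject_id", f"sub-{idx:04d}")),
    )


def _draw_ehis_items(rng: np.random.Generator, group: str) -> np.ndarray:
    """Four inventory items consistent with the group label."""
    if group == "R":
        return rng.choice([50, 100], size=4, p=[0.35, 0.65])
    if group == "L":
        return rng.choice([-100, -50], size=4, p=[0.65, 0.35])
    # mixed: resample until the mean lands near zero
    for _ in range(100):
        items = rng.choice([-50, 0, 50], size=4, p=[0.3, 0.4, 0.3])
        if abs(items.mean()) <= 25:
            return items
    return np.zeros(4, dtype=int)


def generate_cohort(n_per_group: int, params: GeneratorParams) -> pd.DataFrame:
    """Balanced L/R/M cohort table with inventory scores and covariates."""
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = _rng(params.seed, _STREAM_COHORT)
    rows = []
    idx = 0
    for group in ("L", "R", "M"):
        for _ in range(n_per_group):
            items = _draw_ehis_items(rng, group)
            rows.append(
                {
                    "subject_id": f"sub-{idx:04d}",
                    "subject_index": idx,
                    "group": group,
                    "ehis_item_1": int(items[0]),
                    "ehis_item_2": int(items[1]),
                    "ehis_item_3": int(items[2]),
                    "ehis_item_4": int(items[3]),
                    "ehis_score": float(items.mean()),
                    "age_months": int(rng.integers(107, 132)),
                    "sex": str(rng.choice(["F", "M"], p=[0.43, 0.57])),
                    "race": str(rng.choice(RACE_LEVELS, p=RACE_PROBS)),
                    "site": f"site{int(rng.integers(1, 22)):02d}",
                    "scanner": str(rng.choice(SCANNER_LEVELS, p=SCANNER_PROBS)),
                    "mean_fd": float(
                        np.abs(rng.normal(params.fd_baseline_mean, params.fd_baseline_sd))
                    ),
                    "brain_volume_ml": float(rng.normal(1215.0, 108.0)),
                }
            )
            idx += 1
    return pd.DataFrame(rows)
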