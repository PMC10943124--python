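# handlat

Hemispheric-laterality analysis of dense functional connectomes, with a
synthetic cohort generator so every stage can be exercised end-to-end on a
laptop, without restricted data.

The pipeline implements, as reusable and tested components:

- **`handlat.space`** — grayordinate data model: surface spaces (vertex
  coordinates + hemisphere labels), Euclidean spherical ROIs, and
  interhemispheric homologous vertex pairing by mirror-reflection and
  one-to-one nearest-neighbour matching.
- **`handlat.io`** — readers/writers for spaces (TSV), dense time series
  (HDF5 / TSV / CIFTI-2 dtseries via nibabel), scalar maps, and pairings.
- **`handlat.preprocess`** — zero-phase Butterworth band-pass (default
  0.01–0.10 Hz), framewise-displacement censoring (default FD > 0.5 mm,
  subjects excluded below 50 % retained frames), least-squares covariate
  residualization, and multiplicative grand-mean scaling by stratum.
- **`handlat.fcd`** — functional connectivity density: per-grayordinate
  counts of suprathreshold correlations (default |r| > 0.6), globally or
  restricted to the ipsilateral/contralateral hemisphere, for positive or
  negative edges, computed by memory-bounded chunking that is exactly
  equivalent to thresholding the full correlation matrix.
- **`handlat.seedfc`** — seed-based connectivity: ROI-mean signal,
  per-vertex Pearson r, Fisher z maps.
- **`handlat.indices`** — the handedness index
  `(gFCD(Ml) − gFCD(Mr)) / (gFCD(Ml) + gFCD(Mr))`, the laterality map
  `Δ = (z_Ml − z_Mr) / (|z_Ml| + |z_Mr|)`, right-minus-left asymmetry over
  homologous pairs, and the parcel functional-specialization index.
- **`handlat.stats`** — vertexwise pooled/Welch t-maps, Benjamini–Hochberg
  (or Benjamini–Yekutieli) FDR, Cohen's d, Dice overlap, and covariate-
  adjusted ROI group models (statsmodels OLS).
- **`handlat.synth`** — the synthetic cohort generator: mirror-symmetric
  hemisphere point clouds with hand-motor patches and posterior hubs,
  latent-factor BOLD-like subject time series with homotopic coupling and
  group-dependent motor-patch coupling, FD traces with censorable spikes,
  and handedness-inventory cohort tables.
- **`handlat.pipeline`** — orchestration: full study runs (including the
  stratified Discovery/Replication split), effect-size calibration
  helpers, and deterministic plain-file reports.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which implements the
acceptance criteria (edge-set conservation, chunked-vs-brute-force oracle
equivalence, mirror-correspondence bound, symmetry nulls, effect-direction
recovery, effect-size calibration, FDR calibration, and closed-form
checks). The calibration tests run seeded simulations and take a couple of
minutes on one CPU.

## CLI

```bash
# materialize a synthetic fixture study (space, cohort, per-subject HDF5)
handlat synth --out fixture/ --n-per-group 4 --vertices-per-hemi 200 --frames 256 --seed 1

# run the full pipeline from a config file (YAML or JSON)
handlat run --config study.yaml --out out/

# re-render the summary of a finished run
handlat report --study-dir out/

# quick invariant checks on a small instance
handlat validate --seed 0
```

A config file mirrors `handlat.pipeline.StudyConfig`; every field has a
default, so `handlat run --out out/` works without one. Example:

```yaml
n_per_group: 60
seed: 2024
alpha_fdr: 0.05
split_fraction: 0.505
covariates: [mean_fd, age_months, sex, race]
generator:
  n_vertices_per_hemi: 200
  n_frames: 256
  motor_asymmetry_effect: 0.35
```

The report directory contains deterministic TSV tables (subject records
with per-scope handedness indices, index–score correlations per split, ROI
laterality statistics, Dice consistency of asymmetry masks, vertexwise
contrast maps) plus `provenance.json` with the config, seeds, versions,
processing order, and exclusion log. Running the same config twice yields
byte-identical tables.

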