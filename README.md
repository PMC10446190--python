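# trophamp

Analysis pipeline for *trophic amplification* in gridded marine food-web
projections: how climate-driven changes in net primary production (NPP)
propagate — amplified, attenuated or inverted — into consumer biomass.

Given annual 1°-style lat-lon fields of NPP, sea-surface temperature and
total consumer biomass (per ensemble member), the package computes:

- **Change maps** between a reference window (default 1995–2014) and an
  end-of-century target window (default 2090–2099): per-cell ΔNPP%, ΔB%
  and ΔSST, plus global annual change series.
- **Six-type response classification** per cell (positive/negative ×
  amplification/attenuation/inversion) and the amplification ratio
  R = ΔB% / ΔNPP% (R > 1 amplification, 0 < R < 1 attenuation, R < 0
  inversion), with area fractions and trimmed per-type R statistics.
- **Ensemble agreement maps** by per-cell majority vote across members
  with an absolute threshold (e.g. 6 of 7).
- **Warming-response curves**: R binned by ΔSST, split by NPP direction,
  with the ±1% NPP exclusion and 2.5/97.5 percentile trimming, plus
  Pearson/Shapiro diagnostics.
- **Size-class disaggregation** of the signal along the food web,
  including a biomass-conserving trophic-level → weight-class conversion.

Real forcing archives are not required: the `synthetic` module generates
seeded pseudo-ensembles (land/ocean mask, zonal warming and NPP trends,
members with configurable temperature sensitivity of trophic transfer)
whose expected behaviour is known in closed form, so every downstream
stage can be validated against analytic ground truth.

## CLI

The pipeline is config-driven. A minimal YAML config:

```yaml
synthetic:
  seed: 9
  grid_shape: [45, 90]
  year_range: [1950, 2099]
  noise_sd: 0.05
analysis:
  agreement_threshold: 4
output_dir: scratch/demo
```

Run everything (or individual stages, which compose through the files
they read/write under the output directory):

```sh
trophamp run-all -c config.yaml -o scratch/demo
trophamp generate -c config.yaml -o scratch/demo   # or stage by stage:
trophamp changes  -c config.yaml -o scratch/demo
trophamp classify -c config.yaml -o scratch/demo
trophamp agree    -c config.yaml -o scratch/demo
trophamp warming  -c config.yaml -o scratch/demo
trophamp sizeclasses -c config.yaml -o scratch/demo
```

Outputs are one-variable CF-style NetCDF files (dims `time, lat, lon`)
plus flat CSV summaries, and `manifest.json` records the config hash and
data checksums — two runs of the same config are bit-identical.

## Package layout

| module | role |
| --- | --- |
| `trophamp.grid_io` | grid/field data model, NetCDF I/O, area weighting |
| `trophamp.synthetic` | seeded pseudo-ensemble generator + closed-form ground truth |
| `trophamp.changes` | window climatologies, change maps, global series |
| `trophamp.classification` | six-type classifier, R ratio, per-type statistics |
| `trophamp.agreement` | multi-member majority voting, agreement areas |
| `trophamp.warming` | ΔSST-binned R curves and correlation tests |
| `trophamp.sizeclass` | per-class changes, TL→weight conversion, profiles |
| `trophamp.config` / `pipeline` / `cli` | YAML config, staged execution, CLI |
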