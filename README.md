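# pampipe

A desk-scale passive-acoustic-monitoring (PAM) pipeline for a rare vocal
primate: synthetic soundscapes → convolutional call detector → verified
detection histories → landscape occurrence statistics. Every stage runs on
synthetic data with known ground truth, so the full workflow is testable
without any field recordings.

## Stages / modules

| Module | What it does |
| --- | --- |
| `pampipe.audio.synth` | Whinny-like FM calls, rainforest-style background beds, scheduled recordings (05:00–09:30, 14:00–18:30, 21:00–03:00 = 15 h/day), labelled clip sets with hard negatives |
| `pampipe.audio.frontend` | Log-Mel spectrograms and sliding analysis windows |
| `pampipe.detector` | CNN detector — conv blocks with squeeze-and-excitation recalibration and multi-head attention pooling — built on a small numpy autodiff engine; site-independent splits, Adam/BCE training, thresholded inference, UAR/precision/F1 evaluation, positives CSV + clip export |
| `pampipe.review` | Review bookkeeping (every detection gets a verdict), 7-day detection histories, site occurrence, naive occupancy |
| `pampipe.landscape.synth` | Stratified site networks (≥500 m spacing), land-cover raster + road/building vector layers, spatially autocorrelated occurrence with known truth (forest-cover threshold, road exclusion, Gaussian random field, daily detection probability) |
| `pampipe.landscape.metrics` | Buffer covariates: % forest cover, road density (km), building area (km²) at a grid of radii |
| `pampipe.stats.scale` | Scale-of-effect profiles (per-radius logistic fits, McFadden/Tjur pseudo-R²) |
| `pampipe.stats.glm` | Logistic regression by IRLS with explicit separation detection, Firth bias-reduced fits, Bonferroni pairwise contrasts, delta-method prediction bands, empirical tipping points |
| `pampipe.stats.spatial` | Moran's I (expectation −1/(n−1), normal-approximation p), inverse-distance weights, distance-weighted autocovariate (210 m minimum neighbour distance), empirical variogram |
| `pampipe.stats.occupancy` | Constant-ψ/constant-p null occupancy MLE on 7-day histories |
| `pampipe.stats.partition` | Hierarchical (all-subsets) variance partitioning into independent/joint contributions |
| `pampipe.cli` | `pampipe` command with per-stage subcommands and an end-to-end `pipeline` runner |

The detector is implemented in pure numpy (a compact reverse-mode autodiff in
`pampipe.detector.autodiff`) so it trains on one CPU in seconds at desk scale;
no deep-learning framework is required.

## CLI

Each subcommand accepts `--seed` and `--out`; runs are deterministic per seed.

```bash
# audio side
pampipe synth-audio --n-pos 60 --n-neg 60 --n-sites 6 --out clips/
pampipe train --clips clips/ --epochs 8 --out model.npz
pampipe detect --model model.npz --audio recordings/ --threshold 0.5 --out detections/
pampipe review --detections detections/positives.csv --manifest recordings/manifest.csv --out decisions.csv
pampipe histories --detections detections/positives.csv --decisions decisions.csv --out histories.csv

# landscape / statistics side
pampipe synth-landscape --n-sites 341 --region-km 33 --out land/
pampipe scale --covariates land/covariates_geom.csv --histories land/histories.csv --out scale.csv
pampipe fit --covariates land/covariates_geom.csv --histories land/histories.csv --method firth --out fit.csv
pampipe spatial --sites land/sites.csv --histories land/histories.csv --out spatial/
pampipe partition --covariates land/covariates_geom.csv --histories land/histories.csv --out partition.csv
pampipe occupancy --histories land/histories.csv --out occupancy.csv

# everything from one YAML config
pampipe pipeline --config demo.yaml --seed 0 --out run/
```

A minimal `demo.yaml`:

```yaml
audio:
  enabled: true
  n_pos: 40
  n_neg: 40
  epochs: 5
landscape:
  n_sites: 120
  region_km: 15
  psi: 0.3
  field_sd: 1.0
```

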