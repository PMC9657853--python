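# spectroleaf

Hyperspectral reflectance modelling of leaf nutrient status for hydroponic
lettuce. The package implements a complete, testable pipeline:

- **ENVI cube I/O** (`spectroleaf.hsi_io`) — narrow, explicit dialect (BIL/BIP,
  float32, wavelength list in nm), ROI mean-spectrum extraction, NIR-threshold
  leaf masking, and validated sample tables (nutrients, SPAD, pH, Brix,
  weights).
- **Preprocessing** (`spectroleaf.preprocess`) — 13-point moving-average
  smoothing, min-max spectral normalization (NDS), first-order derivative of
  reflectance (FDR, 1/nm) on the actual wavelength grid, and detection of
  dynamic waveband regions by thresholded |FDR| runs.
- **Models** (`spectroleaf.models`) — NIPALS PLS1 and joint [Y X] PCA, both
  reduced to linear regression coefficients; component-count selection from
  the cumulative response-variance curve.
- **Waveband selection** (`spectroleaf.selection`) — three strategies sharing
  one output shape: FDR-region representatives, top local maxima of |β| from
  a full-spectrum model, and VIP scores above 1 (mean squared VIP is 1 by
  construction).
- **Evaluation** (`spectroleaf.evaluation`) — RMSE, R², blue–green
  band-windowed Pearson correlation between leaf and nutrient-solution
  spectra, and the per-(cultivar × response × method) accuracy report.
- **Synthetic data** (`spectroleaf.synthetic_data`) — lettuce-like reflectance
  (blue plateau, green peak, red edge, NIR plateau) whose feature amplitudes
  are linear in a latent nutrient state, with full ground truth
  (informative bands, true coefficients) for recovery tests.
- **Pipeline + CLI** (`spectroleaf.pipeline`, `spectroleaf` command) — staged,
  deterministic, plain-text artifacts.

## CLI

```sh
# full run on synthetic data into ./out
spectroleaf run --out out --seed 1

# with a config file; stages can also be run one at a time
spectroleaf run --config examples/tub.yaml --out out
spectroleaf simulate  --out out
spectroleaf preprocess --out out
spectroleaf select    --out out
spectroleaf fit       --out out
spectroleaf evaluate  --out out
spectroleaf report    --out out
```

A YAML config may set any `RunConfig` field, e.g.

```yaml
profile: tub          # or nft
seed: 1
window: 13            # smoothing window (odd)
methods: [FDR, COEF, VIP]
k: 6                  # bands per selection
h: 6                  # PLS components for fitting
synthetic:
  noise_sd: 0.01
  n_replicates: 4
```

Artifacts written to the run directory: `spectra.csv`, `smoothed.csv`,
`table.csv`, `ground_truth.json`, `fdr.csv`, `regions.csv`, `selections.csv`,
`models/*.json`, `predictions.csv`, `report.csv`, `correlations.csv`,
`manifest.json`. Identical config + seed reproduces every file byte for byte.

## Library example

```python
import numpy as np
from spectroleaf import SyntheticConfig, generate_study
from spectroleaf.models import PredictorMatrix, ResponseVector, fit_plsr, extract_regression
from spectroleaf.preprocess import smooth_moving_average

study = generate_study(SyntheticConfig.tub_default(seed=0))
X = np.vstack([smooth_moving_average(s, 13).values for s in study.spectra])
info = study.ground_truth.informative_band_indices
pm = PredictorMatrix(X[:, info], study.config.grid.wavelengths_nm[info])
y = ResponseVector(study.samples["NO3_ppm"].to_numpy(), "NO3_ppm")
coeffs = extract_regression(fit_plsr(pm, y, h=6))
```
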