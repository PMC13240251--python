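# spadspec

Leaf-level hyperspectral calibration of SPAD (relative chlorophyll) for
maize, built for plant-phenotyping and chemometrics work where a
SPAD-502-style meter provides the reference trait and a field
spectroradiometer provides 325–1075 nm reflectance at 1 nm.

The package implements the full calibration workflow:

- **Paired outlier screening** — K-means/Euclidean distance on SPAD
  values (flag if distance to the assigned centre exceeds
  mean + 2·SD) and Monte-Carlo PLSR residual analysis on spectra
  (component count by 10-fold CV capped at 20; 1000 random 80%
  calibration subsets; flag if a sample's mean |residual| exceeds
  mean + 3·SD). Samples flagged on either side are excluded as pairs.
- **Preprocessing chains** — Savitzky–Golay smoothing (window 15,
  order 2) followed by SNV, SNV + detrend, or MSC, the standard
  treatments for multiplicative gain and additive baseline scatter.
- **21 vegetation indices** on the nominal bands R450, R550, R670,
  R720, R800 (NDVI, RVI, NDRE, CIrededge, SAVI, TGI, …), in their
  published variants.
- **Correlation screening** — per-(stage, leaf position) Pearson r of
  every chain × index with SPAD; |r| ≤ 0.3 none, ≤ 0.5 weak, ≤ 0.8
  significant, > 0.8 highly significant; argmax |r| selects the
  optimal combination per group.
- **SPAD prediction** — single-index regressions (linear, quadratic,
  exponential a·e^{bx}, power a·x^b) and a random-forest regression
  ŷ = (1/T) Σₜ fₜ(x) over all 21 indices, tuned over T ∈ [5, 1000]
  and mtry ∈ [1, ⌊2p/3⌋], on a deterministic SPXY 4:1 train/test
  partition (farthest-point sweep on d = dX/max dX + dY/max dY).
- **Evaluation** — R² (squared Pearson correlation of predicted vs.
  actual), RMSE (n denominator), and RPD = SD/RMSE with the standard
  capability classes (> 2.5 excellent, 1.8–2.0 good, 1.4–1.8
  acceptable, …).
- **Synthetic data** — a generator producing paired
  (spectrum, SPAD, metadata) datasets with the structure the analysis
  assumes: per-group truncated-normal SPAD (nine stage × leaf-position
  groups, CV < 10%), Beer–Lambert reflectance with saturated visible
  troughs and a responsive red edge, per-leaf gain/offset scatter,
  sensor noise, and ground-truth-flagged planted anomalies for
  recovery benchmarks.

## Worked example

```python
import spadspec as sp
from spadspec.indices import compute_index_table
from spadspec.models import fit_rf, spxy_split

cfg = sp.GeneratorConfig(groups=(sp.GroupSpec("V12", "apical", 120, 50.6, 4.3),), seed=1)
samples, _ = sp.generate_dataset(cfg)
processed = sp.apply_chain(samples, "SG-MSC")
table = compute_index_table(processed)
split = spxy_split(table.values.to_numpy(), processed.spad, 0.2,
                   ids=list(table.values.index))
rf = fit_rf(table, processed.spad, split,
            n_trees_grid=(50, 200, 500), mtry_values=[4, 8, 14], seed=1)
print(rf.test_metrics)
```

Running `python examples/04_spad_prediction_models.py` (which wraps the
code above plus the single-index fits) prints:

```
strongest index under SG-MSC: CIrededge (r = 0.977)

single-index fits (in-sample):
  linear       R2 = 0.955  RMSE = 0.87 SPAD
  quadratic    R2 = 0.955  RMSE = 0.87 SPAD
  exponential  R2 = 0.954  RMSE = 0.88 SPAD
  power        R2 = 0.955  RMSE = 0.87 SPAD

random forest on all 21 indices (SPXY 96:24 split, 200 trees, mtry 8):
  train  R2 = 0.99  RMSE = 0.47  RPD = 9.27
  test   R2 = 0.96  RMSE = 0.63  RPD = 4.43 (Excellent)
```

The red-edge chlorophyll index CIrededge (R800/R720 − 1) dominates the
screening because the 450/670 nm absorption troughs are optically
saturated at field-typical chlorophyll, so the red-edge shoulder
carries most of the SPAD information; the RPD of 4.4 places the
multi-index forest in the top capability class on this synthetic group.
The other `examples/` scripts walk through simulation and I/O, outlier
screening, preprocessing + correlation screening, and the one-call
pipeline.

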