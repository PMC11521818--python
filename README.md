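# chlorospec

Leaf-level hyperspectral estimation of maize chlorophyll content: spectral
indices, chlorophyll-sensitive band selection, minimum-redundancy
maximum-relevance (MRMR) feature ranking, and six regression model families
evaluated with a common statistics bundle.

## The problem

Total leaf chlorophyll (a+b, µg/g fresh weight) is the workhorse indicator
of crop nitrogen status and stress, but wet-lab determination — acetone
extraction followed by spectrophotometry,

```
chl = (20.2·A644 + 8.02·A663) · V / w
```

— is destructive and slow. Leaf reflectance in the 400–1000 nm range
carries the same information non-destructively: chlorophyll absorbs near
430 and 660 nm, the green peak near 550 nm sinks as pigment accumulates,
and the *red edge* — the sharp reflectance rise between ~680 and 750 nm —
shifts to longer wavelengths with increasing chlorophyll.

`chlorospec` implements a complete calibration workflow over such spectra:

1. **Indices** — eleven chlorophyll-related variables per spectrum: NDVI,
   REP (red-edge position by four-band linear interpolation,
   `700 + 40·(((ρ₆₇₀+ρ₇₈₀)/2 − ρ₇₀₀)/(ρ₇₄₀ − ρ₇₀₀))`), NDVI705, mSR705,
   mNDVI705, PRI, MCARI, VREI2, and three chlorophyll indices built from
   the 516/551/763 nm bands:
   `CHLI1 = (ρ₅₅₁+ρ₇₆₃)/(ρ₇₆₃−ρ₅₅₁)`, `CHLI2 = (ρ₇₆₃−ρ₅₁₆)/ρ₅₅₁`,
   `CHLI3 = (ρ₅₁₆+ρ₅₅₁)/ρ₇₆₃`.
2. **Band selection** — PCA with Kaiser-normalized Varimax rotation plus
   relative-SD profiling locate the chlorophyll-sensitive wavelengths;
   a tolerance/VIF screen (VIF > 5 or tolerance < 0.1) flags collinear
   indices.
3. **MRMR** — greedy feature ranking from first principles: equal-frequency
   discretization, plug-in mutual information in bits (Miller–Madow
   corrected), quotient scoring `I(x;y) / mean I(x;x_selected)`, and a
   permutation-test relevance screen that assigns exactly zero importance
   to chlorophyll-blind features.
4. **Models** — Huber robust linear regression (IRLS), stepwise linear
   regression with pairwise interactions (partial-F entry/removal),
   ε-SVR with quadratic and fine-Gaussian (kernel scale 0.83) kernels,
   exact Gaussian-process regression with an isotropic Matérn 5/2 kernel
   `k(r) = σ(1 + √5·r/l + 5r²/(3l²))·e^(−√5·r/l)`, and a trilayered
   (3 × 20 ReLU) neural network.
5. **Evaluation** — R², RMSE, MAE, MBD and MSPE per model and stage, an
   every-third-record deterministic validation split for single-index
   calibrations, and a seeded random split for the learned models.

Because the original 540-sample field dataset is not public, the package
ships a first-class synthetic-data generator that reproduces the study
conditions: left-skewed chlorophyll (mean 2479.8, SD 632.5 µg/g, range
321.1–3713.1), a chlorophyll-dependent red edge, green-region reflectance
of 20–31% for pigment-rich and 45–48% for pigment-poor leaves, carotenoid
co-variation, leaf-to-leaf structural variability and gain-like sensor
noise on a 400–1000 nm grid with 0.6 nm step.

## Worked example

```python
from chlorospec import GeneratorConfig, simulate_spectrum
from chlorospec.indices import compute_index
from chlorospec.evaluation import run_pipeline

rec = simulate_spectrum(2500.0, config=GeneratorConfig(noise_sd=0.0))
for name in ("CHLI1", "CHLI2", "CHLI3", "REP", "NDVI705"):
    print(f"{name:8s} {compute_index(rec, name):8.3f}")

report = run_pipeline({"seed": 1, "models": ["robust_linear", "gpr_matern52"]})
print(report.metrics_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints

```
CHLI1       4.008
CHLI2       0.866
CHLI3       1.081
REP       718.510
NDVI705     0.633

        model    stage    r2   rmse    mae    mbd     mspe
robust_linear training 0.982 77.481 62.491 -0.347 6003.314
robust_linear  testing 0.974 98.908 63.880  2.091 9782.792
 gpr_matern52 training 0.988 63.829 47.917 -0.002 4074.136
 gpr_matern52  testing 0.983 80.265 55.074 -4.727 6442.394
```

For a 2500 µg/g leaf the red edge sits at 718.5 nm, near its saturating
position; the Matérn 5/2 GPR generalizes best (testing R² 0.983, RMSE
80 µg/g on this synthetic run), with the robust linear fit close behind —
the same qualitative ordering the index/model comparison is designed to
expose. MRMR ranking on the same conditions places the photochemical
reflectance index (PRI) last with importance exactly 0: it tracks
short-term photosynthetic regulation, not pigment content, and the
permutation screen recognizes it as chlorophyll-blind.

A `chlorospec` command-line tool wraps each stage
(`simulate`, `indices`, `select`, `rank`, `collinearity`, `train`,
`evaluate`, `run`); see `chlorospec --help`.

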