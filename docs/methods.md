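# Methods

This note documents the models and numerical choices behind `chlorospec`,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the workflow left genuine freedom.

## Chlorophyll determination

Total chlorophyll (a+b) in µg/g fresh weight is computed from acetone-extract
absorbances as `(20.2·A644 + 8.02·A663)·V/w`, with extract volume V (ml) and
fresh weight w (g). The function is linear in each absorbance and in V/w,
which the tests assert as exact algebraic properties. A470 is carried through
the data model as a carotenoid-related reading but enters no formula: no
carotenoid quantification is provided, deliberately.

## Synthetic leaf spectra

The generator is phenomenological, not radiative. A spectrum is assembled
from a visible-region envelope (a monotone-shape-preserving PCHIP curve
through anchor points expressing the blue chlorophyll/carotenoid absorptions,
the green peak and the red absorption), a logistic red edge, and a
near-infrared plateau with a water feature at 960 nm. Every downstream
consumer sees the spectra only through band ratios, so feature *geometry* is
what matters; a PROSPECT-class radiative-transfer model would add physical
fidelity the workflow cannot observe.

Pigment-to-reflectance coupling uses exponential saturation curves:

* green level `g(chl) = 0.20 + 0.455·exp(−chl/1480)` — calibrated so the
  520–580 nm window averages ≈ 0.46 at 800 µg/g and ≈ 0.26 at 3000 µg/g,
  matching the reported reflectance ranges for pigment-poor and pigment-rich
  maize leaves;
* red (670 nm) level `r(chl) = 0.012 + 0.215·exp(−chl/900)`, and an analogous
  blue level — the deep red absorption makes the relative-SD profile of a
  wide chlorophyll group peak near 662–670 nm, the band the SD-profiling
  narrative identifies;
* red-edge inflection `λ_e(chl) = 688 + 40·chl/(chl+1200)` nm — monotone in
  chlorophyll, spanning ≈ 697–718 nm over the observed chlorophyll range and
  giving four-band REP values in the low 700s to low 720s.

Chlorophyll labels are drawn from a moment-matched skew-normal (mean 2479.8,
SD 632.5 µg/g, skewness −1.0, the full-set descriptives) truncated by
rejection to [321.1, 3713.1]. The skew-normal family caps |skewness| below
0.9953, so the target of −1.0 is clamped to −0.99; the fitted moments are
otherwise exact before truncation. A narrower observed range (796.6–3257.0)
is also quoted in the source narrative; the full-set bounds are used because
they are the descriptives of the complete sample, and the bounds are plain
configuration for anyone who prefers the narrower reading.

Carotenoid level is a relative covariate (mean 1, SD 0.15) correlated 0.6
with the chlorophyll z-score, clipped to [0.6, 1.4]; it modulates the
460–515 nm shoulder only.

Three stochastic components act per leaf, all seeded:

1. **Structural variability** (`structural_sd`, default 0.04): independent
   multiplicative jitters of the green/blue/red levels, standing in for
   leaf-structure and water-status variation that real leaves show beyond
   pigment content. Without it every index is a nearly deterministic
   function of chlorophyll and all six models saturate at R² ≈ 1, which no
   field calibration does.
2. **Red-edge jitter** (`edge_jitter_sd`, default 1.0 nm): positional noise
   of the inflection, the main scatter source for red-edge indices.
3. **Measurement noise** (`noise_sd`, default 0.005): gain-like, i.e.
   *relative* fluctuations proportional to the local reflectance, with a
   white and a smooth low-frequency component. Proportional (rather than
   additive) noise is the natural model for a dual-reference (white/dark
   calibrated) reflectance instrument, and it has a structural consequence
   the test-suite relies on: a band ratio of two wavelengths whose
   noise-free reflectances share the same pigment scaling — PRI's 531 and
   570 nm bands both ride on the green level — is *exactly* independent of
   chlorophyll. Additive noise would leak a heteroscedastic chlorophyll
   signature into PRI through the noise-to-signal ratio.

The green-peak anchors between 520 and 585 nm are all proportional to the
green level for the same reason: PRI must be chlorophyll-blind by
construction, mirroring its observed role as the one index the feature
ranking discards.

What the generator does **not** emulate: canopy and soil background, view
and illumination geometry, sensor spectral response and stray light,
multi-scattering between leaves, seasonal drift, and any chlorophyll-a/b
split. Passing tests therefore certify the *workflow* — formulas, selection
logic, model fitting, statistics — on data with the right geometry and
noise structure, not the field performance of any index on real maize.

## Band selection

PCA runs on per-wavelength z-scored reflectance (the scaling convention is a
package choice; correlation-matrix PCA keeps dark and bright bands
comparable). Retention defaults to the Kaiser criterion (eigenvalue > 1),
with an integer override to force a fixed component count — useful because
Kaiser is known to over-retain when wavelengths outnumber samples. Varimax
rotation is Kaiser-row-normalized, tolerance 1e-6, at most 500 sweeps
(delegated to `statsmodels`' rotation routines); orthogonality preserves
per-wavelength communalities and total explained variance to 1e-8, which is
asserted. Components are re-ordered by post-rotation explained variance and
signed so the dominant loading is positive.

`pick_wavelengths` takes interior strict local extrema of the first rotated
component's |loadings|: the largest `n_max` maxima and smallest `n_min`
minima, ties toward the shorter wavelength. The SD profile is reported
alongside as corroborating evidence but does not enter the automatic pick —
how the two evidence streams were combined originally is not specified, so
the package keeps the deterministic, auditable rule and leaves the judgment
to the analyst.

VIF for feature j is `1/(1−R²_j)` from an intercept-included least-squares
regression on the remaining features; tolerance is its reciprocal; flags use
VIF > 5 or tolerance < 0.1. Perfect collinearity yields an infinite VIF with
a flag rather than an error, since a screening report should survive a
degenerate column.

## MRMR

Features and target are discretized to 10 equal-frequency bins (robust to
the left-skewed chlorophyll distribution); ties share the bin of their mean
rank so an exact duplicate feature discretizes identically. Dependence is
plug-in mutual information in bits from the joint contingency table, with
cell contributions summed in sorted order so the estimate is exactly
symmetric. The ranking uses the Miller–Madow bias-corrected estimate
(clamped at zero) because the raw plug-in MI of two independent variables
is biased upward by ≈ (r−1)(c−1)/(2N·ln2) bits — about 0.1 bits at N = 540
with 10×10 bins, enough to scramble the tail of a ranking.

Relevance screening: a feature enters the greedy selection only if a
permutation test (399 permutations of the target, fixed internal seed,
α = 0.01) rejects independence; otherwise its relevance and importance are
exactly 0 and it is appended after all selected features, in input order.
The permutation null is exact by construction — a chi-square approximation
to the G statistic proved anti-conservative at the expected cell counts
here (≈ 5 per cell) and produced false positives well above nominal.

Greedy scoring is the quotient scheme, `I(x_j;y) / mean_{k∈S} I(x_j;x_k)`,
with a 1e-12-bit floor on the denominator; the first feature's importance
is its relevance. The difference scheme (`relevance − redundancy`, floored
at zero) is available via `scheme="difference"`. The quotient default
matches the convention of the interactive toolboxes this kind of analysis
is usually run in.

## Models

All presets standardize features (stored with the model and re-applied at
prediction); the network also standardizes the response internally for
conditioning and inverts the scaling at prediction time.

* **Robust linear**: Huber loss (`r²/2` for |r| ≤ δ, `δ(|r|−δ/2)` beyond)
  minimized by IRLS. δ defaults to 1.345 × a median-absolute-deviation
  scale estimate, re-estimated each iteration — the classical 95%-efficiency
  tuning — with an absolute override. Convergence: max coefficient change
  below 1e-8, at most 100 sweeps. Cross-checked against `statsmodels` RLM.
* **Stepwise linear**: candidate terms are the linear effects plus all
  pairwise interactions; entry/removal by partial-F p-values (0.05 enter,
  0.10 remove), bidirectional by default from a linear-terms start
  (forward starts empty), at most 1000 steps.
* **SVR**: ε-insensitive regression; quadratic-polynomial (coef0 = 1,
  scale-heuristic γ) or Gaussian kernel with fixed kernel scale 0.83 on
  standardized features, `K = exp(−‖x−y‖²/(2σ²))`. "Automatic" box
  constraint is iqr(y)/1.349 — a robust response-scale estimate — and ε is
  a tenth of it, the convention of the toolchain such models are commonly
  fitted with.
* **GPR**: exact inference, constant basis (implemented by response
  normalization, so far-from-data predictions revert to the training mean),
  isotropic Matérn 5/2 kernel times a variance scale plus a Gaussian noise
  term, all optimized by quasi-Newton maximization of the log marginal
  likelihood with 2 restarts and a jitter ladder 1e-10 → 1e-6 for Cholesky
  stability. `noise="zero"` pins the noise to jitter only, giving exact
  interpolation of noise-free data (asserted to 1e-6).
* **Trilayered network**: 3 hidden layers × 20 ReLU units, linear output,
  L2 strength 0, full-batch L-BFGS with an iteration limit of 1000 — chosen
  over stochastic optimizers so a fixed seed gives bit-reproducible weights.

Model persistence is provided for the coefficient-based families through the
run report (coefficients and selected terms are part of the fitted state);
kernel and network models are cheap to refit from a seeded config, which is
the package's reproducibility mechanism rather than binary checkpoints.

## Evaluation

The five statistics are computed exactly as defined: R² = 1 − SSE/SST
against the reference mean, RMSE, MAE, MBD = mean(y − ŷ) (positive =
under-prediction), and MSPE = mean squared error, so MSPE ≡ RMSE² and
RMSE ≥ MAE ≥ |MBD| hold identically and are fuzz-tested. If the reference
values have zero variance, R² is undefined and the error carries the four
remaining statistics.

Splits: the single-index calibrations use the deterministic every-third
rule (records 3, 6, 9, … to validation; 540 → 180), the learned models a
seeded shuffle at a 2:1 ratio; both are overridable in the pipeline config.
The full pipeline — generate/load → indices → collinearity → MRMR →
calibrations → fits → statistics — is a pure function of its config and
seed, and two runs produce byte-identical JSON reports.

## Problem sizes used in the checks

The shipped test-suite and acceptance script run the complete workflow on
the default 540-sample, 0.6 nm-grid conditions (single pipeline runs and a
ten-seed model-ordering comparison on a two-model subset), 200-sample
feature tables for the ranking-oracle comparison, and 50–100 small seeded
regressions for the robustness and selection-behaviour checks. These sizes
keep each property statistically meaningful for the estimators involved
while the whole suite completes in about a minute.

## Known limitations

* The generator's realism is geometric, not physical (see above); absolute
  model accuracies on it do not transfer to field data.
* Kaiser retention over-counts components when wavelengths outnumber
  samples; force a component count for full-grid PCA.
* The stepwise search is greedy and inherits the usual selection-inference
  caveats; its p-values are entry/exit criteria, not honest hypothesis
  tests.
* MRMR importances depend on the discretization; 10 equal-frequency bins is
  a robust default, not an estimate of the continuous mutual information.
* The permutation relevance screen is exact only marginally per feature; no
  multiplicity adjustment is applied across the eleven indices.
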