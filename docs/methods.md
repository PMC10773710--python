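# Methods

## The vertical profile model

Maize leaf chlorophyll, proxied by unitless SPAD-meter readings, follows a
bell-shaped curve over leaf position `n` (ordinal, counted from the stem
base). The package models it with the Lorentz (Cauchy-type) peak function

```
SPAD(n) = SPAD_m / [1 + ((n − n_m)/b)²]
```

with three interpretable parameters: `SPAD_m` the peak SPAD value (SPAD
units, > 0), `n_m` the leaf position of the peak (leaf-position units), and
`b` a width/slope coefficient (leaf-position units, > 0; at
`|n − n_m| = b` the curve is at half peak). The model is even in `b`; the
fitter always reports the positive representative, which changes nothing in
the objective. `n_m` is fitted as a continuous parameter — a bell peak need
not sit exactly on an integer leaf — and the campaign table reports it both
raw and rounded to the nearest integer leaf position.

Assumptions worth stating: the profile is unimodal and symmetric about
`n_m` on the measured range (real canopies are mildly asymmetric; the
Lorentz form absorbs this into `b` at some cost in fit quality at the
tails), and leaf positions are comparable across plots within a stage
(senesced bottom leaves at R1/R2 are handled by starting the measured range
at leaf 6, not by re-indexing).

## Fitting

`fit_lorentz` minimizes the sum of squared SPAD residuals with SciPy's
bounded trust-region least squares. Initialization: `SPAD_m` at the maximum
observed SPAD, `n_m` at its position, `b` at half the observed position
range; bounds `SPAD_m ∈ (0, 2·max]`, `n_m ∈ [min−2, max+2]`,
`b ∈ (0.1, 3·range]`. Because short noisy profiles (4–8 points) can strand
a single local start in a side minimum, a vectorized coarse presearch
(16 × 24 × 24 grid over the same box, geometric spacing on `b` so narrow
peaks are represented) supplies up to three additional starts, and the
lowest-SSE refinement wins. Convergence: `ftol = 1e-12` on the objective,
at most 2000 residual evaluations per start. On noiseless profiles the
round trip recovers generating parameters to ≲1e-9 relative error; the
test suite checks ≤1e-6 against all 28 reference triples and checks the
fitted SSE against a dense 50³ brute-force grid on random short profiles.

Degenerate inputs: fewer than three distinct positions raises an
insufficient-data error (the model has three parameters); an exactly
constant profile raises a degenerate-profile error; optimizer
non-convergence is reported via `converged=False`, never an exception.

Campaign tables (`fit_campaign`) fit the **leaf-position-wise mean profile**
per (treatment, stage) group by default — the protocol that corresponds to
one curve drawn through per-position group means with error bars. Pooling
all observations of a group is available via `mode="pooled"`; on noiseless
data the two coincide. Validation (`validate_fit`) pools predicted versus
observed SPAD per stage across all validation plots and reports R²/RMSE of
the 1:1 comparison, excluding (and reporting) treatments without
parameters.

## Evaluation metrics

R² = 1 − SS_res/SS_tot (not clamped; negative for predictors worse than the
mean), RMSE = √(Σ(yᵢ−Pᵢ)²/n), nRMSE = RMSE/(y_max − y_min), and Pearson r
with a two-sided p-value from the exact t-transform
t = r·√((n−2)/(1−r²)), n−2 df — the standard test for a correlation
coefficient. Screening (per leaf position, per index) is at raw p < 0.05
with no multiplicity correction, matching the per-stratum screening
protocol this pipeline implements; `holm_adjust` is provided for users who
want family-wise control. All sums run in double precision; tests require
1e-12 agreement with direct-summation oracles.

## Vegetation indices

Seventeen broad-band indices are computed from fractional reflectance in
five bands (475/560/668/717/842 nm) exactly as the broad-band definitions
are written — the triangular and absorption indices (TVI, mTVI, TCARI,
MCARI, EVI, DVI) operate on fractional reflectance with no percent
rescaling, so their magnitudes are in the fractional-reflectance
convention. mNDblue is `(Rblue − Rre)/(Rblue + Rnir)`; other denominators
circulate in the literature, and this package deliberately uses the
broad-band form above. CCCI is the min–max rescaling of NDRE over all
plots of one flight date/stage — the only normalization population
consistent with computing CCCI per stage — so it is a campaign-level
quantity: undefined for a single plot (carried as NaN with a warning), and
invariant to increasing affine transforms of the NDRE set. Zero
denominators yield NaN markers that propagate with logged counts, never
±inf.

## Imagery

Plot reflectance is the arithmetic mean over a rectangular ROI
(0-based, row-major, top-left origin; half-open window
`[row, row+h) × [col, col+w)`, conventionally 100×100 px). Nodata pixels
(NaN, or a user-declared marker mapped to NaN on read) are excluded;
an ROI entirely nodata in any band flags the plot missing rather than
producing a value. Rasters are held in float64 in memory (so noiseless
fixture → extraction round trips are exact) and exchanged as float32
multiband TIFFs, band order blue/green/red/red_edge/nir; geo-referencing
and co-registration are assumed done upstream and are out of scope.

## The synthetic campaign generator

The generator emulates a split-plot nitrogen trial: nitrogen level is the
main plot (N0–N6 = 0–400 kg N ha⁻¹), hybrid varieties randomized within it,
with replicates; stages V6/V9/R1/R2 carry leaf ranges 1–6, 1–9, 6–20, 6–19
(bottom leaves senesce by the reproductive stages). The default parameter
bank is the 28-triple reference set in `canopyspad.reference`; default
sensitive leaves are 6/4/12/12 for V6/V9/R1/R2.

Per plot × stage, SPAD at each integer leaf position is the Lorentz value
plus additive Gaussian noise, truncated below at zero (truncation, not
resampling: at the default sd the truncation probability is negligible, so
the induced bias is too). The default SPAD noise sd is 2.0 SPAD units — a
realistic repeatability figure for per-leaf means of handheld SPAD readings
averaged over several plants and leaf segments; no within-plot variance is
prescribed by the trial design itself, so this is a package choice exposed
in `CampaignConfig`.

Reflectance is generated *through NDRE* rather than a radiative-transfer
model: the latent contrast `c = a0 + a1·SPAD(sensitive leaf) + ε`,
`ε ~ N(0, 0.03)`, becomes the plot NDRE after clamping to [0.01, 0.99]
(clamping more than 10 % of plots logs a warning); NIR is fixed at 0.45 and
the red edge solved from NDRE, so the generated NDRE is exact; blue, green
and red are uniform nuisance draws (0.03–0.06, 0.06–0.12, 0.04–0.10)
independent of SPAD. Defaults `a0 = −0.05`, `a1 = 0.011` map SPAD 20–60
onto NDRE ≈ 0.17–0.61, a realistic maize canopy span. The rationale for
this minimal structure: the headline index (CCCI) is a pure function of
NDRE, so tying NDRE to the sensitive leaf is exactly the structure the
downstream screening and inversion stages are supposed to detect, with all
other bands acting as distractors.

What the generator does **not** emulate: leaf-angle/LAI confounds, soil and
shadow background, bidirectional reflectance effects, between-variety
parameter variation within a treatment, and spatially correlated field
trends. Passing tests therefore demonstrate that the algorithms recover a
known generative structure under measurement-style noise — not that any
particular field dataset satisfies that structure.

Reproducibility: one campaign seed; each plot × stage draws from a stream
keyed by (seed, namespace, stage index, plot index), so a plot's values
never depend on generation order or on which subset of stages is run.

## Sensitivity and inversion

`rank_vis` correlates each index with canopy-mean SPAD (mean over all
measured leaves of a plot) and sorts by descending r, ties broken
alphabetically. `find_sensitive_leaf` maximizes the *signed* r across leaf
positions (all expected correlations are positive under the generative
link; `use_abs=True` switches to |r|), ties to the lower position;
positions with constant SPAD or fewer than three pairwise-complete plots
are excluded and flagged. Inversion models are OLS fits
SPAD = intercept + slope·VI, trained and evaluated on explicit, disjoint
plot-id splits (or an independent dataset, e.g. another season); with no
split given the model is evaluated on its training plots and flagged
resubstitution. `compare_models` reports
(R²_sens − R²_canopy)/R²_canopy as an integer percent — the relative-gain
arithmetic that makes (0.59, 0.44) → +34 % and (0.67, 0.65) → +3 %.

## Problem sizes in the shipped checks

The test suite runs campaigns of 70 plots (7 treatments × 10 varieties × 1
replicate — the single-season trial size) and repeats stochastic
properties over 100 seeded replicates (sensitive-leaf recovery,
sensitive-vs-canopy R² ordering, red-edge ranking); Monte-Carlo mean checks
use 1000 plots. These sizes make every statistical assertion sharp at
desk scale while the full suite stays in the tens of seconds.

## Known limitations

* The Lorentz form is symmetric; strongly asymmetric senescence profiles
  will push error into `b` and the tails.
* CCCI depends on the normalization population: values are comparable only
  within one flight date, and a campaign with near-constant NDRE has an
  ill-conditioned CCCI.
* The linear inversion is per stage and per index by design; no
  multi-index or nonlinear regressors are provided.
* Fitted parameters are not linked to nitrogen rate or thermal time by any
  quantitative model; the parameter tables are descriptive.
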