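# Methods

This note records the models, conventions and design choices behind
`airexposure`, in the order the pipeline runs them.

## Synthetic worlds

The generator produces daily multi-pollutant fields with a fully known
parametric structure:

    C(g,t,p) = B_p · exp(r_p · y(t)) · (1 + A_p · cos(2π(doy(t) − φ_p)/365.25)) · exp(ε(g,t,p))

- `B_p` — baseline level (µg/m³).  Defaults are long-term continental
  population-weighted means characteristic of 2003–2019 Europe:
  14.34 (PM₂.₅), 22.01 (PM₁₀), 13.46 (NO₂), 74.51 (MDA8 O₃).
- `r_p` — log-linear annual trend (fraction/year); `y(t)` counts
  fractional years since the series start (days/365.25).  Defaults
  −1.72 %, −2.72 %, −2.45 %, +0.58 % per year mirror the declining
  particulate/NO₂ and slowly rising O₃ regime of that period.
- `A_p`, `φ_p` — seasonal relative amplitude and peak day-of-year.
  Particulates and NO₂ peak in mid-January (φ = 15) and O₃ in mid-July
  (φ = 196), so cold-season compound days involve PM/NO₂ and warm-season
  ones involve O₃.  Amplitudes default to 0.30 (0.25 for O₃) — a
  noticeable but not dominating cycle.
- `ε` — mean-zero Gaussian log-noise, σ = 0.40 by default (daily
  cell-level concentrations commonly fluctuate by tens of per cent).
  Spatial correlation is imposed by Gaussian-kernel smoothing of white
  noise with kernel width `spatial_corr_length` (default 3 cells); the
  smoothed field is rescaled to unit variance using the exact sum of
  squared kernel weights, so `noise_sd` is the marginal log-sd regardless
  of the correlation length.  The correlation length is a free parameter
  of the generator, not an estimate of any real residual field.
  Cross-pollutant dependence is imposed by multiplying the per-pollutant
  noise vector with a PSD matrix square root of the configured
  correlation matrix (default: PM₂.₅–PM₁₀ 0.8, PM₂.₅–NO₂ 0.6,
  PM₁₀–NO₂ 0.5, O₃ weakly coupled 0.05–0.2), which keeps the marginals
  lognormal and the fields strictly positive.
- Calendar: Gregorian with leap days; the seasonal argument divides by
  365.25 so multi-year series need no special-casing.

The population surface is a Gaussian-bump mixture plus a small uniform
background, allocated by a single multinomial draw — counts are integers
and conserve the configured total exactly.  Regions are a rectangular
block partition with stable row-major ids.  Station sampling draws cells
without replacement, with probability proportional to population by
default (monitoring networks are urban-biased); observations are the cell
truth plus Gaussian noise clipped at zero (truncation bias is negligible
at the configured noise levels and avoids resampling loops), with
station-days dropped independently at the configured missingness rate.

What the generator does *not* emulate: atmospheric chemistry and
transport, real geography and emission patterns, instrument-specific
error structure, within-year population change, and spatially varying
trends.  Passing tests therefore demonstrate the correctness of the
*accounting and estimation machinery* under known ground truth, not the
accuracy of any real-world exposure estimate.

## Grid conventions

Coordinates are cell centers on a regular geographic grid; a cell is the
half-open box `[center − Δ/2, center + Δ/2)` per axis, which makes area
intersection for buffers and region masks unambiguous.  All buffers and
distances are in geographic degrees; no projection or CRS transformation
is performed (inputs must be lat-lon).

- Bilinear resampling interpolates the four surrounding source centers;
  target centers outside source coverage become missing.  Resampling to
  the same grid is the identity; planes are reproduced exactly.
- Nearest-neighbour (categorical) resampling breaks exact midpoint ties
  toward the lower-index source cell.
- Station extraction uses a square buffer of ±0.05° by default:
  overlap-area-weighted mean for continuous data, modal category by
  overlap area for categorical data (ties toward the lower category id).
- Region membership is cell-center-in-polygon by default, with an
  optional fractional-weights mode for border cells; both are provided
  because real workflows differ on whether border cells are split.
- PW aggregation excludes missing cells from numerator and denominator
  per day (per-day renormalization) and warns when more than 25 % of a
  region's population sits under missing cells; zero-population regions
  yield missing values with a warning.

## Guideline machinery

Default limits are the WHO 2021 air-quality guideline values — 24-h
PM₂.₅ 15, PM₁₀ 45, NO₂ 25, MDA8 O₃ 100 µg/m³; annual PM₂.₅ 5, PM₁₀ 15,
NO₂ 10; O₃ peak-season 60 µg/m³ with interim target 2 (70 µg/m³)
available and used by the pipeline default, since almost nowhere meets
60.  All limits are user-overridable through the YAML guideline file.

Boundary conventions, chosen to match the guideline wording and all
documented in the code: daily exceedance is strict (`C > L`; a value
exactly at the limit complies), the short-term clean threshold is strict
(`E < (1−0.99)·N_days`, so 3 exceedance days in a 365-day year are clean
and 4 are not; leap years use 366, threshold 3.66), and long-term "not
exceeded" is non-strict (`metric ≤ L` is clean).  The short-term
threshold is rounded at the ninth decimal so binary representation of
`1 − 0.99` cannot flip the strict comparison.

MDA8 forms the running 8-hour means starting each clock hour; only
windows fully contained in the series' span count, a window is valid
with ≥ 6 of its 8 hours present (mean over present hours), and a day is
valid when ≥ 75 % of its in-span windows are valid — 18 of 24 for a day
followed by another day.  These availability fractions follow common
regulatory practice.  When the O₃ input is already a daily MDA8 field
(the pipeline's normal case) this operation is bypassed.

The peak-season mean is the maximum over the twelve windows of six
consecutive calendar months, wrapping the year boundary, and requires
data in at least six distinct months.

Missing data in one pollutant on a cell-day counts as *non-exceedance*
(with the overall coverage fraction reported on the compound field)
rather than invalidating the day; full-coverage inputs are unaffected
and sparse synthetic tests stay well-defined.

Compound categories are exact sets, serialized as "+"-joined sorted
codes (`NO2+PM25`).  This makes the per-category decomposition a true
partition: category exposure times sum to the any-compound exposure time
for every region-year, an identity asserted in the tests.  Note that a
category's exposure time is bounded by each member pollutant's
single-pollutant exposure time, but the *any-compound* time is not
bounded by the minimum of the members.

The "population with at least one compound day" statistic is provided in
two modes — per grid cell (population of cells with ≥ min_days compound
days) and per region (population of regions whose population-weighted
compound exposure reaches min_days) — because either definition is
defensible; the pipeline defaults to the cell mode.

## Trends

Theil–Sen slopes are the median of all pairwise slopes, skipping pairs
with identical times; annual percentage change is `100·slope/mean` of the
annual series (trends are computed on annual means, matching an "annual
rate of change").  Mann–Kendall uses the tie-corrected variance and a
continuity-corrected two-sided normal approximation; for n ≤ 10 with no
ties an exact p-value by dynamic-programming enumeration of the null
distribution of S is available, and an all-tied series returns S = 0,
p = 1 by convention.  No autocorrelation pre-whitening is applied — a
known limitation for strongly autocorrelated annual series.  Designated
outlier years can be excluded from both the slope and the mean (the
usual treatment of exceptional O₃ years).

## Model harness

- Distance weights: `d_i` is the mean degree distance to the k = 10
  nearest distinct-location stations (k is configurable; coincident
  stations draw on the remaining neighbours); weights `d_i/mean(d)` are
  clipped to [0.2, 5] to bound the influence of extreme isolation, then
  renormalized to mean 1.  Regularly spaced networks get exactly uniform
  weights.
- The weighted pinball loss is normalized by the weight sum, so weight
  rescaling is a no-op; the gradient contract returns
  `−w_i(τ − 1[u_i<0])` with unit pseudo-curvature `w_i`, the convention
  boosting libraries expect for piecewise-linear objectives.  τ = 0.5
  (the median) is the point-estimate default.
- Spatial CV partitions *stations* into five near-equal folds (all rows
  of a station share its fold); temporal CV tiles the year span with
  blocks of three consecutive years plus trailing two-year blocks so the
  span is covered exactly (17 years → 3+3+3+3+3+2, six subperiods).
- The shadow-feature screen appends one shuffled copy of every feature
  per iteration, scores a hit when a real feature's importance beats the
  best shadow, and decides by one-sided binomial tests against p = 0.5
  at the configured α; undecided features stay tentative.
- NRMSE is normalized by the observed range (max − min); NMB by the
  observation sum.  Mean-normalization of RMSE produces values an order
  of magnitude larger on typical concentration scales, which is
  inconsistent with the few-per-cent NRMSE magnitudes conventionally
  reported for models of this type, so range-normalization was adopted;
  the normalizer is a documented, deliberate choice.
- The nested-CV loop flags failing folds and continues; every row
  receives exactly one out-of-sample prediction, and the leakage audit
  (no prediction from a model that saw the station in training) is
  asserted by tests.

## Problem sizes and determinism

Tests and the acceptance script use deliberately small worlds —
5×5 to 24×24 cells, 2–10 years, 50-seed ensembles for parameter
recovery and 500 replicates for the Mann–Kendall null size — sized so
the whole suite completes in well under a minute apart from the
recovery ensemble (~30 s).  All randomness flows through explicit
`numpy` generator seeds; identical seeds give bit-identical fields,
tables and CSV outputs (asserted byte-for-byte in the tests).

## Known limitations

- Degree-space distances and buffers ignore the latitude dependence of
  longitudinal distance; acceptable at the regional scales targeted,
  wrong near the poles.
- No CRS handling beyond rejecting non-geographic GeoJSON.
- The significance flag ignores serial correlation of annual series.
- The synthetic generator's spatial covariance is a single isotropic
  correlation length; real residual fields are anisotropic and
  heterogeneous.
- Exposure assumes a static within-year population.
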