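# Methods

## Problem and model

`ecodist` quantifies the separation between ecoregions — geographic and
ecological — and relates it to the error of machine-learning models
transferred across ecoregion boundaries. An *ecoregion* is a unit of
generally similar ecosystems; plots inside it carry fractional-cover
indicators in percent (line-point-intercept "any hit" covers, canopy-gap
fractions) and predictor features, and its landscape carries seasonal
raster variables observable without field work.

### Harmonic seasonal descriptors

Each (pixel, variable) series is modelled by OLS in the basis
{1, t, cos(ωⱼt), sin(ωⱼt)}, t in fractional years, J = 2 harmonics. The
default frequency convention is ωⱼ = 2πj yr⁻¹ — the j-th harmonic completes
j cycles per year, which is the standard land-surface-phenology reading
(the second harmonic captures bimodal greenness such as double cropping). A
`literal-reciprocal` mode (ωⱼ = 2π/j yr⁻¹, multi-year periods) is kept
behind a flag for completeness because the two conventions coincide at
j = 1 and diverge only in how the second term is interpreted. A third
harmonic adds little in practice and is not a default.

Amplitude is √(β₂² + β₃²); phase uses the two-argument arctangent so the
quadrant is unambiguous on (−π, π], with (0, 0) mapped to phase 0. The
solver is QR-based least squares with an explicit rank check: sampling
times that alias a harmonic (e.g. exact half-year spacing aliasing the
second harmonic into the intercept) raise an error naming the collinear
design column rather than returning an arbitrary solution.

Per-pixel values are averaged to ecoregion level arithmetically; a circular
phase mean (mean resultant direction) is available via configuration for
phase distributions that straddle ±π. Amplitudes are then min–max scaled to
[0, 1] per variable across ecoregion-level descriptors, pooling both
harmonics of a variable (a per-(variable, harmonic) mode exists); a
degenerate range maps to 0.

### Separation measures

- **geoDist**: equirectangular distance with R = 6371.0088 km and the
  longitude difference scaled by cos(mean latitude). A planar
  `degrees-euclidean` mode (Euclidean in degrees × 111.195 km/deg) is
  provided. Note the equirectangular variant is not a true metric: because
  each pair uses its own mean-latitude cosine, triangle-inequality
  violations of order 0.1 % are possible over a continental extent; the
  planar mode is exactly Euclidean. This is a projection artifact, not an
  implementation error.
- **ecoDisIS**: indicators are z-scored over all plots of qualifying
  ecoregions pooled (≥ `min_plots` plots, default 100), zero-variance
  indicators dropped with a warning; the index is the Euclidean distance
  between per-ecoregion mean z-vectors. A `centroids` z-scoring mode
  (z across per-ecoregion means) is available.
- **ecoDisRS**: with ΔA the mean absolute scaled-amplitude difference and
  ΔP the mean circular phase difference divided by π (both in [0, 1]),
  ecoDisRS = (1 + ΔA)(sin(ΔP − π/2) + 2) = (1 + ΔA)(2 − cos ΔP). The +1 and
  +2 offsets keep either component from zeroing the product, and the −π/2
  shift makes the sine term strictly increasing over the whole ΔP range.
  The normalized ΔP is used directly as the sine argument (radian-equivalent
  units), giving the analytic range [1, 2(2 − cos 1)] ≈ [1, 2.919] with the
  minimum attained exactly at self-comparison. Dividing the circular
  difference by π is the one normalization under which the index is both
  bounded and strictly increasing in ΔP; the raw circular mean in [0, π]
  would push the sine past its maximum.
- **ecoDisINT**: for a target ecoregion, the first interquartile mean — the
  mean of the k = ⌈0.25·n⌉ smallest values, ties broken by ecoregion id —
  of its pairwise dissimilarities to the n reference ecoregions with
  in-situ data (self excluded). It summarizes distance to the *most
  relevant* potential training pool rather than to any single ecoregion.

Pairwise values are stratified into quartiles Q1..Q4 by the 25/50/75th
linear-interpolation percentiles of the pooled pairwise set; bins are
right-open except the last, so a value equal to a cut point joins the upper
quartile.

### Transfer evaluation

One random forest per (training ecoregion, indicator) — reused against
every test ecoregion, which is mathematically identical to per-pair
training since the training set never depends on the test side — yields
K(K−1) MAE records for K qualifying ecoregions. Defaults: 100 trees, one
third of predictors tried per split, unlimited depth, deterministic
per-model seeds derived from the master seed. MAE summaries across test
ecoregions are unweighted means; per-record sample sizes are retained so
weighted summaries remain recomputable.

- **Test 1A** trains, for each test ecoregion, on all other qualifying
  ecoregions after excluding {}, {Q1}, {Q1,Q2}, {Q1,Q2,Q3} of a chosen
  separation measure (quartile of each training ecoregion taken relative to
  the test ecoregion, with globally pooled boundaries).
- **Test 1B** trains on exactly one quartile at a time.
- **Test 2** reports Spearman and Pearson correlations between the bulk
  in-situ and remote-sensing dissimilarities across ecoregions, plus the
  mean/median bulk IS value per RS quartile.
- The slope analysis fits MAE ~ geoDist by OLS within each quartile of a
  dissimilarity measure.

An empty training pool (e.g. excluding all four quartiles) produces an
explicit record with a NaN MAE and an `empty_pool` flag — never a silent
skip or imputation.

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, not any real
landscape. Every ecoregion draws a latent coordinate zₑ ~ N(0, I_d)
(d = 3 by default) in an abstract ecological space, and all observables
derive from it:

- **Indicators**: ecoregion means are 50 + 8·(Q zₑ) percent with Q an
  orthonormal loading, plot values add N(0, 5²) noise and clip to [0, 100].
  The scale-8 / sd-5 choice keeps between-ecoregion spread comparable to
  within-ecoregion scatter while making clipping rare, so clipping (chosen
  over a logistic transform for transparency) almost never distorts the
  geometry.
- **Seasonal series**: per (variable, harmonic), amplitude and phase are
  affine in zₑ (amplitude floored at 0.05, phase wrapped); pixel series are
  the ecoregion curve plus N(0, 0.1²) noise at a 16-day revisit over
  3 years. Ecoregions far apart in latent space therefore differ in both
  magnitude and timing of their seasonal cycles, which is what ecoDisRS
  measures.
- **Predictors**: plot predictors are a linear map of the (centred, scaled)
  indicators whose coefficients drift linearly with latent position at rate
  `nonstationarity` (default 1.0). With drift zero the predictor-indicator
  relation is spatially constant and transfer is nearly free; with positive
  drift a model fitted in one ecoregion systematically mis-maps another in
  proportion to latent distance — the single knob that creates a transfer
  penalty growing with ecological dissimilarity.
- **Geography**: centroids are geo_coupling·(a fixed-scale projection of
  the first two latent coordinates onto a lat/lon plane) +
  (1 − geo_coupling)·(an independent uniform layout over a western-US-like
  box). The default 0.7 encodes strong but partial spatial structuring of
  ecology — neighbouring ecoregions tend to be similar, yet geography alone
  does not determine ecology — which is the regime in which dissimilarity
  quartiles, not raw distance, carry the transfer signal; it was fixed
  during generator design after verifying the mechanism reproduces the
  expected quartile-slope contrast.
- **Climate**: five daily weather variables (daylength, precipitation,
  radiation, max/min temperature) as annual sinusoids with realistic bases
  and day-level noise, generated per plot over a 120-day lookback window
  ending at the plot's collection date (collection dates uniform within one
  calendar year). The window covers the 30- and 90-day min/max
  aggregations (5 × 2 × 2 = 20 derived predictors) while keeping long-form
  CSVs tractable at thousands of plots; a campaign-wide multi-year daily
  archive would add nothing the aggregation windows can see.

All randomness flows from one master seed through named substreams
(ecoregions, geography, plots, series, predictors, climate), so enabling or
disabling one stage never changes another stage's draws, and identical
configuration + seed reproduces byte-identical CSVs.

**What passing tests do and do not show.** The generator's world is
Gaussian, linear-in-latent and stationary within ecoregions; real cover
data are zero-inflated and skewed, real seasonal series have gaps, QA
masking and disturbance events, and real predictor relations drift
nonlinearly. Passing the qualitative suites shows the *pipeline* correctly
detects a transfer penalty structured by ecological dissimilarity when one
exists; it does not certify the empirical magnitudes of any real landscape.

## Numerical choices and edge cases

- OLS via `numpy.linalg.lstsq` after an explicit QR rank check
  (tolerance max-dimension · machine-epsilon · max|R_ii|, floored at
  1e−10 relative).
- Phase (0, 0) → 0; −π normalized to +π.
- Min–max scaling with max = min maps to 0.
- Interquartile mean: k = ⌈0.25·n⌉, stable sort, id tie-break.
- Quartile labels: right-open bins, last bin closed.
- z-scores use population (ddof = 0) standard deviations.
- Per-model forest seeds are derived deterministically from the master seed
  and the (ecoregion, condition, indicator) keys, so adding an experiment
  never reshuffles another's randomness.

## Problem sizes used by the shipped checks

The structural-count check runs the full 71-ecoregion, 100-plot cross
matrix (4970 records) with default forests. The behavioural ensembles use
20 replicate seeds of 24 ecoregions × 40 plots with 40-tree forests — sizes
chosen so each replicate is seconds-scale while leaving the quartile
contrasts statistically clear; the exclusion-ladder trend is assessed with
a one-sided sign test across replicates, the slope and correlation
properties as replicate success rates.

## Known limitations

- Arithmetic phase averaging can be misleading for phase distributions
  straddling ±π; the circular option exists but is not the default.
- ecoDisRS is not a metric (no triangle inequality is claimed) and its
  quartile boundaries depend on the pooled pair set, so adding ecoregions
  relabels quartiles.
- The equirectangular geoDist is metrically imperfect over continental
  extents (see above).
- Bulk ecoDisINT for truly unsampled regions requires only their seasonal
  descriptors, but this package's pipeline demonstrates it on regions that
  also have synthetic in-situ data; the IS column is simply absent in the
  unsampled case.
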