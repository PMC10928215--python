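# Methods

This note documents the models, conventions and design choices behind
`agbmap`, and what the synthetic scenes do and do not emulate.

## Allometry

Tree biomass is `W = 0.1355 (D²H)^0.817` kg, applied uniformly to all
stems (no species- or wood-density-specific variants; DBH ≥ 5 cm, the
census threshold, is enforced at the type level). Plot AGB density is the
summed tree biomass over the plot area (default 0.05 ha, a 12.5 m-radius
circle). Lorey's height is the basal-area-weighted mean height; only
basal-area *ratios* enter, so it is invariant to uniform DBH rescaling.

Regional height-biomass allometries `AGB = a·L^b` are fitted by nonlinear
least squares on the original Mg ha⁻¹ scale, initialised from a log–log
OLS fit. Original-scale fitting was chosen because the model's quality is
reported as an RMSE in Mg ha⁻¹, which is the quantity original-scale least
squares minimises; log-scale fitting would minimise relative error
instead. Reference coefficient pairs for the northern (0.5014, 1.8762) and
southern (0.1237, 2.3281) regions are exposed as constants and used as the
generating truth in synthesis. The north/south boundary is an explicit
label carried on plots and footprints; the synthetic scene assigns the
northern half of the frame to "north". The (a, b) estimators are strongly
negatively correlated and heavy-tailed at n ≈ 26 plots with 20 % scatter;
recovery tests therefore assert against wide marginal intervals frozen
from a 1000-replicate Monte-Carlo of the generator itself.

## Covariate preprocessing

* **L-band**: digital numbers calibrate to γ⁰ via `10 log₁₀(DN²) + CF`
  (CF = −83.0 dB). Speckle smoothing uses a circular 150 m focal mean
  applied in the **linear power** domain before converting to dB —
  averaging dB values biases backscatter low. Non-positive DN propagates
  as nodata rather than raising, because nodata is a normal pixel state.
  The HV−HH dB difference (the linear-power ratio) is carried as a band
  because the ratio saturates later than either polarisation.
* **C-band**: HH and VV acquisitions are pooled into one per-pixel sample;
  mean, sample (n−1) standard deviation and minimum are computed where at
  least 2 observations exist, else the pixel is flagged as a gap. The
  (n−1) estimator was chosen because per-pixel counts are small. The
  minimum band is computed and included in the default feature list
  (configurable).
* **Optical**: observations flagged cloudy in the QA layer are excluded
  per pixel; band temporal means and NDVI max/min/difference are computed
  on the unsmoothed reflectances. "Fluctuation" of any annual series is
  defined throughout as max − min over the series.
* **Terrain**: Horn's 3×3 finite-difference slope in degrees, replicated
  borders.
* **Forest mask**: baseline canopy cover strictly > 10 % and no loss
  flagged in 2001..2007.
* **Resampling** between aligned grids supports integer aggregation
  (NaN-aware block averaging; nearest neighbour for masks) and integer
  refinement; the synthetic frame is planar, so no geodesic machinery is
  involved.

## Footprints to training cells

Footprint QC drops slope > 15°, and slope in (12°, 15°] with AGB ≤ 40
Mg ha⁻¹ (relief comparable to tree height makes low-biomass retrievals
unreliable); each dropped footprint carries the flag explaining it, so
filtering is auditable, idempotent and order-independent. Heights are
capped at 25 m at the *footprint* level before conversion (the cap could
also be read as applying to cell means; both are implemented, footprint
level is the default single-pass choice). Because the allometry is
nonlinear, the default aggregation converts each footprint and averages
AGB within cells; averaging heights first and converting the cell mean is
available behind `cell_average="height"`. Cells need ≥ 2 footprints;
slope at a footprint is read from the slope band at its centre pixel
(footprint-scale slope is not available). The 60/40 train/validation
split is a seeded uniform permutation.

Cells default to 8 pixels (400 m at 50 m pixels) in the default 200×200
scene so that several hundred populated cells exist — scale-faithful to
aggregating ~0.01° cells on a much larger real grid, where the default
would be ~20 pixels. Cell size is configuration, not behaviour.

## Stratified extrapolation

Forest pixels partition into flat (slope ≤ 10°), rugged (> 10°) and
no-C-band (gap) strata; the gap takes precedence. One regression forest
per stratum: 500 trees, per-split candidate count ⌈p/3⌉, fixed seed —
conventional regression-forest defaults recorded in the model manifest.
Importances are mean decrease in impurity (node purity); pruning drops
the 10 lowest-importance variables (stable input-order tie-break for
determinism) and refits. The flat and rugged models train on their own
stratum's cells; the no-C-band model trains on *all* training cells with
the C-band features removed, because the gap stratum alone rarely
contains enough cells for a stable fit. The canonical feature list is
every band the covariate module produces plus the coordinate bands
(which let the forest absorb broad geographic gradients). The scale
mismatch — trained on cell means, predicted on 50 m pixels — is inherent
to the design and documented rather than corrected. Predictions are
clipped at zero; pixels with missing covariates stay nodata, and
stitching errors only if a forest pixel belongs to no stratum.

Accuracy is assessed cell-wise: pixel predictions averaged over each
held-out cell's forest pixels against the cell's LiDAR-derived AGB. R² is
the squared Pearson correlation (matching scatter-plot usage; the
1 − SSE/SST variant is available via configuration).

## Bias correction

Validation pairs are binned by the reference axis in 10 Mg ha⁻¹
intervals; empty bins are skipped. The zero-intercept slope over bin
means, `s = Σx̄ᵢȳᵢ / Σx̄ᵢ²`, rescales the map by `1/s`. The global rescale
(rather than per-bin inversion) is the unique monotone linear map that
makes the refitted bin regression coincide exactly with the 1:1 line; it
is idempotent and order-preserving, and when the forest compresses the
range (s < 1) it widens the corrected maximum. Pre/post R², RMSE and
extremes are computed on the same validation cells used to fit the
corrector.

## Validation and comparison

Site screening: forest fraction of the 100 m buffer ≥ 0.5 (pass at
exactly 0.5); NDVI fluctuation of the buffer-mean annual series strictly
< 0.15; both SAR polarisation fluctuations strictly < 2 dB; buffer
sd / field AGB ≤ 0.25 (pass at exactly 0.25) — a literal reading of the
stated criteria. Sites with zero field AGB have an undefined
heterogeneity ratio and are excluded with a distinct audit code, as are
sites outside the raster extent. Histograms use right-closed 10 Mg ha⁻¹
bins labelled by upper edge (bin "10" is (0, 10]). Carbon conversion
multiplies AGB by 0.47. Distribution statistics near sites pool forest
pixels of the 1 km cell containing each site; quartiles use linear
interpolation.

## Synthetic scenes

The latent AGB surface is Gaussian-smoothed white noise whose marginal is
rank-flattened to a uniform distribution over the configured range
(default 0–250 Mg ha⁻¹) — a monotone transform of the random field that
preserves spatial structure while spanning the whole range the way a
national-scale AGB population does, instead of clustering mid-range. At
the default correlation length of 10 px the lag-10 autocorrelation is
0.75 ± 0.05 (50-seed Monte-Carlo). Sensor responses follow
`y = c0 + c1(1 − exp(−AGB/k))`: HV saturates near 70 Mg ha⁻¹, HH 45,
C-band 80, NDVI 60. L-band carries multiplicative gamma speckle in linear
power; C-band has Poisson observation counts (mean 5) plus a contiguous
low-count gap disc (5 % of the scene); optical observations are cloudy
with probability 0.1 and flagged in QA. The DEM is a smooth surface with
100 m amplitude, giving ≈ 65 % flat, 27 % rugged and 5 % above the 15°
filter at 50 m pixels. Footprint heights invert the regional allometry
from true AGB plus Gaussian noise (default sd 5.9 m, floored at zero).
Field plots are built from identical stems whose diameter solves the tree
biomass equation for the target plot total, so plot Lorey's height and
density are exact and recoverable; scatter is multiplicative lognormal.
Validation sites are placed on disjoint fully-forested homogeneous
buffers and then deliberately broken per criterion (an NDVI or SAR
excursion year, or a field AGB chosen to violate the heterogeneity
ratio), with ground-truth pass/fail labels carried on the site table.

What the generator does **not** emulate: orbit geometry, waveform
physics, sensor point-spread functions, geolocation error beyond pixel
snapping, seasonal phenology, or real land-cover class structure. Passing
tests therefore demonstrate the pipeline's correctness and statistical
health under the assumed noise model, not the accuracy of any real-data
map.

## Problem sizes and numerical choices

The default scene is 200×200 pixels with ~5000 footprints and ~550
populated cells, sized so a full pipeline run takes a few seconds and the
ten-seed health check stays under a minute. Power-law fits start from the
log–log OLS solution and use `scipy.optimize.curve_fit` with up to 2·10⁴
evaluations; degenerate predictors (all heights equal) raise. dB↔linear
round trips are exact to 1e-10. All randomness flows from
`numpy.random.default_rng` seeded per component via deterministic
sub-seeds of the master seed, so every generator and the whole pipeline
are bit-reproducible for a fixed seed.

## Known limitations

* The no-C-band stratum shares training cells with the other strata (see
  above); with a much larger gap region a dedicated gap-only training set
  would be preferable.
* The bias corrector is a single global rescale; it restores range but
  cannot fix bin-specific nonlinearity.
* Synthetic validation-site field AGB for heterogeneous sites is set from
  the buffer statistics (to make the filter ground truth exact), so those
  sites are label constructions, not plausible field measurements.
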