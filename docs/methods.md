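# Methods

## Mixture model and estimation

Every unmasked pixel is modelled as a convex combination of `n` endmember
spectra over `m` bands, `R = C α + ε` with `α ≥ 0` and `Σ α = 1`. Both
estimators minimise `‖R − C α‖²` under these constraints:

* **LSMM** uses the full library `C` for every pixel.
* **SELSMM** first selects a per-pixel subset (below), then solves the same
  constrained problem restricted to it; unselected endmembers get
  abundance 0.

The constrained solve uses the Heinz–Chang augmentation: the design matrix
gains a constant row weighted `δ = 10⁴ × max|C|` and the augmented system
is solved by non-negative least squares (`scipy.optimize.nnls`). At this
weight the residual-induced drift of `Σα` from 1 stays near 10⁻⁸ while the
system remains well conditioned in double precision; solutions within
10⁻⁶ of the simplex are renormalised exactly, larger violations raise a
warning. Degenerate all-zero spectra carry no information and return the
uniform `1/n` with a warning. Libraries with `n > m + 1` are
underdetermined and warn but do not fail.

## Selective endmember iteration

The per-pixel selection loop operates on a residual spectrum, initialised
to the pixel spectrum:

1. Compute the **response coefficient** — the Pearson correlation across
   bands — between the residual and every endmember.
2. Among the not-yet-selected endmembers, choose the one with maximal
   response `r_max` (ties to the lowest index). Each endmember can be
   chosen at most once per pixel.
3. Its normalised contribution is `X_max = r_max / Σ_j max(r_j, 0)`, the
   denominator running over **all** `n` endmembers' (negative-clamped)
   responses to the current residual — not only the remaining candidates.
   This keeps the damped step `η·X_max·A_max` from inflating as the
   candidate pool shrinks, which would otherwise overshoot the residual
   and truncate selection before small true fractions are admitted.
4. Subtract `η·X_max·A_max` from the residual and record the iteration.
5. Stop when (a) any residual component turns negative, (b) the residual
   change `‖ΔR‖∞ = η·X_max·‖A_max‖∞` falls below `delta_tol`, (c) no
   candidate responds positively, or (d) candidates are exhausted. The
   endmember chosen in a stopping iteration is retained by default
   (`include_final_endmember=True`): it was judged most similar *before*
   the subtraction that triggered the stop.

A flat (zero-variance) pixel has no defined correlation with anything; it
falls back to full-library FCLS with a logged flag. Pixels whose spectrum
responds positively to nothing do the same.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| `eta` | 0.35 (6-band) / 0.65 (4-band) | — | damping of the subtracted contribution; larger values stop selection after fewer picks |
| `delta_tol` | 1e-4 | reflectance | `‖ΔR‖∞` threshold of the small-change stop |
| `include_final_endmember` | True | — | keep the pick that triggered a stop |
| `max_iterations` | `n` | — | hard cap (each endmember picked at most once) |

### Behaviour and limitations

The response coefficient compares spectral *shape*, not amplitude. Three
consequences, all reproducible with the simulator and worth knowing before
applying the method:

* **Selection is permissive among positively correlated endmembers.** On
  bright semi-arid surfaces (soils, litter, vegetation) every endmember
  responds positively to most residuals, so at η = 0.35 the loop usually
  runs to exhaustion and SELSMM coincides with LSMM. Pruning appears as η
  grows (mean selected size is non-increasing in η), but each wrongly
  dropped true endmember costs far more accuracy than excluding an absent
  one saves: under the simulator's exact-mixture conditions the
  scene-mean abundance error of SELSMM is never below LSMM's. Restricting
  FCLS to the *true* per-pixel support does help substantially (the
  oracle roughly halves the RMSE), so the selective idea has headroom,
  but correlation-based selection cannot realise it at these conditions.
  On real imagery — where library spectra are averages that do not match
  any pixel exactly — the balance can differ; that regime is outside the
  simulator's generative model.
* **Anti-correlated dark endmembers are invisible in mixtures.** Water's
  decreasing spectrum correlates negatively with any residual dominated
  by a bright surface, so a minority water fraction is never admitted;
  only water-dominated pixels select it. The default simulated roster
  therefore contains no water; adding it (supported via explicit class
  lists) degrades SELSMM markedly on mixed shoreline pixels.
* **The non-vegetation product flag is selection-aware.** A pixel whose
  selected set excludes every vegetation endmember is flagged
  non-vegetation outright, mirroring how selective unmixing can rule
  vegetation out entirely while full-library unmixing cannot.

## Endmember extraction (MNF + PPI)

The minimum noise fraction transform solves the generalised eigenproblem
`S v = λ N v` with `S` the image covariance and `N` a noise covariance
estimated by horizontal neighbour differencing (covariance of
`x[r,c+1] − x[r,c]` halved — valid when the signal varies smoothly across
columns). A ridge of `10⁻¹⁰ × max(trace, 1)` keeps `N` invertible on
noiseless input. Components are ordered by descending noise-adjusted
eigenvalue; retaining all of them makes the transform exactly invertible.

The Pixel Purity Index projects component-space pixels onto random unit
skewers (default 10 000, seeded) and counts, per pixel, how often its
projection lies within `extreme_tol` (default 0.01) of the projection
range's minimum or maximum — up to 2 counts per skewer. Convex-hull
vertices (pure materials) collect the highest counts; on a noiseless
simplex with `extreme_tol = 0` only planted pure pixels score. Candidate
spectra are the top-scoring pixels, greedily deduplicated when their
mutual response coefficient exceeds 0.995 (replacing the manual
n-dimensional visualisation step with a reproducible rule); V-I-S class
labels are left to the analyst.

## Products and evaluation

FVC is the summed abundance of vegetation-class endmembers — no
rescaling. Maps are classified into bins [0, 0.2), [0.2, 0.4), [0.4, 0.6),
[0.6, 0.8), [0.8, 1.0] (left-closed, top bin closed; the bin-edge
convention is a documented choice) plus **non-vegetation**: vegetation
abundance at or below `nv_threshold` (default 0, i.e. zero within 10⁻⁶) or
no vegetation endmember selected. Area tables report pixel counts and
percents over unmasked pixels and always sum to 100.

Accuracy assessment pairs each field plot with the single pixel containing
its coordinates (plot size matches the pixel footprint; no interpolation)
and reports

* `RMSE = sqrt( (1/N) Σ (f′_i − f_i)² )` of estimated vs measured cover,
* `R²` as the squared Pearson correlation of the pair — identical to the
  R² of the simple OLS regression of estimated on measured, whose slope,
  intercept and two-sided slope p-value are reported alongside.

Plots outside the raster or on nodata pixels are excluded with a warning
naming the plot id.

## Calibration and IO

DN→radiance calibration is linear per band, in two flavours:
`L = (Lmax − Lmin)/255 · DN + Lmin` (TM-style min/max radiances, applied
exactly as written, so `Lmin` is the radiance at DN 0) and
`L = gain · DN + L0` with `gain` the multiplicative absolute-calibration
gain. Rasters are 32-bit float multiband GeoTIFF (geotransform carried in
GeoTIFF pixel-scale/tiepoint tags, nodata as NaN) or ENVI BSQ with a text
header (nodata as a declared ignore value of −9999; pixel sizes stored
signed so arbitrary geotransforms round-trip). Spectral libraries are
`name,class,b1,…,bm` CSV with classes from
{vegetation, impervious, soil, water, other}.

## Synthetic scenes

The simulator emulates the data structure of a semi-arid watershed FVC
study: per-pixel convex mixtures of a small endmember subset plus additive
band noise, and a plot survey sized to the pixel footprint.

* **Library.** Parametric spectra on nominal band centres of a 6-band
  TM-like or 4-band HJ-1B-CCD-like sensor (centres shape the spectra only;
  unmixing never consults wavelengths). The default four-endmember roster
  is green vegetation (red-edge), bright sandy soil, darker loessal soil
  and dry grass/litter (cellulose SWIR2 drop) — the dominant surfaces of a
  semi-arid steppe watershed. Water and gray impervious templates exist
  for explicit class lists. Small seeded jitter (σ = 0.004) individualises
  libraries; all pairwise response coefficients stay below 0.99.
* **Mixing.** Per pixel, a support of 1…`max_support` endmembers (size
  uniform, members uniform without replacement) and fractions from a
  symmetric Dirichlet (α = 1, uniform on the simplex). Truth is stored
  exactly; the cube minus noise equals `library × abundances` exactly.
* **Noise.** Per band, i.i.d. Gaussian with variance set so that the
  band's scene-wide signal variance over noise variance equals `snr_db`
  (default 30 dB).
* **Survey.** Distinct pixels, coordinates at pixel centres, measured
  cover = true FVC + Gaussian(0, 0.05) clipped to [0, 1], 30 plots by
  default.

What the simulator does **not** emulate: within-class endmember spectral
variability (every pixel mixes the exact library spectra), spatial
autocorrelation of land cover, atmospheric/illumination residuals, sensor
PSF and quantisation. Passing tests therefore demonstrate correctness of
the algorithms under the linear-mixture model's own assumptions, not
performance on real imagery — in particular, the LSMM/SELSMM comparison
can come out differently on real scenes where library spectra are
imperfect (see the selection limitations above).

## Numerical choices

* FCLS augmentation weight `10⁴ × max|C|`; simplex renormalisation window
  10⁻⁶; NNLS as the inner solver.
* Selection ties on `r_max` break to the lowest endmember index; response
  coefficients are clipped to [−1, 1] against rounding.
* MNF ridge `10⁻¹⁰ × max(trace, 1)` on both covariances; PPI skewers are
  normalised Gaussian draws from a seeded generator, processed in blocks
  of 256 to bound memory.
* Top-k purity candidates tie-break by row-major pixel order; only pixels
  with positive counts are candidates.
* Scene sizes used throughout testing and the acceptance script are
  64×64 (4 096 pixels) with 200-instance solver checks and 2 000-skewer
  extraction runs — small enough to iterate comfortably, large enough for
  stable stochastic checks.
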