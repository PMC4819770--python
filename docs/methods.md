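# Methods

`nanofish` measures the distance between two differently colored RNA-FISH
transcription foci to nanometer accuracy on a conventional widefield
microscope, by single-molecule-style localization of each focus, chromatic
registration with fiducial beads, and propagation of all error terms into
the reported separation. This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic tests do and
do not demonstrate.

## Image model

A diffraction-limited spot is modeled as an elliptical 2D Gaussian on a
constant background:

    F(x, y) = z0 + A * exp(-[((x - x0)/sx)^2 + ((y - y0)/sy)^2] / 2)

with the theoretical PSF standard deviation

    s = 0.21 * lambda / NA

used to initialize `sx = sy` (for a 1.45-NA objective and 650-nm emission,
s ≈ 94 nm). Predicted pixel counts are the *integral* of `F` over each
pixel (error-function differences), not a point sample at the pixel
center. At the reference geometry the pixel (200 nm) is *larger* than the
PSF standard deviation, so point sampling would bias the fitted width by
~17%; the integrated model removes that bias and makes the synthetic
generator and the fitters exact inverses of each other, which is what the
noiseless recovery oracles rely on. Under this parameterization the total
signal above background is `2*pi*A*sx*sy / a^2` counts.

Coordinates: 0-based pixel indices, the center of pixel `(i, j)` at
`((j + 0.5)a, (i + 0.5)a)` nm, x along columns, y along rows. All
positions are reported in nm.

## Camera and noise model

Expected photons per pixel = background `b` + emitter photons distributed
by the integrated Gaussian. The camera applies, in order: Poisson shot
noise, multiplication by `gain` (counts/photon), additive Gaussian read
noise, rounding, clipping at zero. The synthetic generator can disable the
stochastic stages (`shot_noise=False`) and then returns the exact expected
image, which serves as the zero-noise oracle. Defaults mirror the
acquisition the package emulates: a = 200 nm pixels, NA = 1.45, two
emission channels around 615 and 684 nm, gain 1, no read noise. Photon
budgets are free parameters of the simulation (the acquisition they mimic
used 10–60 s exposures, so several thousand photons per focus is the
realistic regime; benchmark conditions use 5000 unless stated).

## Fitting

* **Least squares (default).** Levenberg–Marquardt on the six parameters
  `(z0, A, x0, y0, sx, sy)` with a forward-difference Jacobian. The two
  widths adjust independently — real spots are never exactly symmetric.
  Initialization follows the classical recipe: `z0` = mean of the ROI
  perimeter pixels, `A` = brightest pixel − z0 (row-major first on ties),
  `(x0, y0)` = center of the brightest pixel, `sx = sy = s`, rotation 0.
  Convergence is declared when the relative change of the residual sum of
  squares between accepted steps falls below 1e-4 (“0.01%”); a
  parameter-step criterion is available via `convergence="step"`. At
  moderate SNR (N = 5000, b = 10) the median fit converges in ~6
  iterations. Non-converged fits and fits whose center leaves the ROI are
  flagged and excluded downstream.
* **Rotation.** The initial parameter list includes a rotation angle but
  the default model is axis-aligned; a rotated-Gaussian mode (pixel-center
  sampled) exists for diagnostics.
* **Maximum likelihood.** Counts are converted to photons by the gain and
  the Poisson deviance `2*sum(mu - c + c*log(c/mu))` is minimized with
  L-BFGS-B. The deviance has the same optimum as the Poisson
  log-likelihood but is bounded below by zero, so the same relative-change
  stopping rule is meaningful. MLE is the most accurate estimator at low
  photon counts, at a ~10x compute cost.
* **Centroid.** Background-subtracted (perimeter mean), negative residuals
  clipped, intensity-weighted mean. Fast, adequate at high SNR, and
  degrades rapidly with noise — the Monte-Carlo ordering test shows its
  error growing >2x between peak/background ≈ 100 and ≈ 2.

## Localization precision

    sigma^2 = s^2/N + a^2/(12 N) + 8*pi*s^4*b^2 / (a^2 * N^2)

per axis, with `N` the detected signal photons (total counts minus fitted
background, divided by gain; a model-based estimate `2*pi*A*sx*sy/(a^2 g)`
is reported as a cross-check) and `b` the background *noise* in
photons/pixel, estimated as the standard deviation of the ROI perimeter
pixels. Note the distinction: the generator's background parameter is a
mean level; for Poisson background of mean `m` the corresponding noise is
`sqrt(m)`. Monte-Carlo calibration over N ∈ {500 … 20000} and background
means {0, 5, 20} puts the observed per-axis RMSE at 1.08–1.25x this
formula — the formula is a first-order result and mildly optimistic, which
is why measured uncertainties, not formula values, drive the significance
rule. For elliptical fits `s = sqrt(sx*sy)`.

## Spot QC

A candidate focus must look like an isolated diffraction-limited spot:

* `snr` = brightest pixel / perimeter mean ≥ 3 (foci at least 3x brighter
  than background),
* `gaussian_likeness` = Pearson correlation between the ROI and its
  best-fit Gaussian ≥ 0.7,
* `local_contrast` = (peak − perimeter mean) / perimeter std ≥ 5.

The 3x rule is the only quantified threshold in the source protocol; the
other two defaults are this package's choices, configurable and echoed
into output tables. Automatic candidate search (local maxima above median
+ 5·MAD, greedy non-maximum suppression at max(2s, 1.5 px)) replaces the
manual spot picking of the original workflow; a list of manually chosen
pixel coordinates is accepted wherever the detector would run. On
background-only frames the full gate yields <0.1 false candidates per
128×128 frame.

## Chromatic registration

Multi-spectral beads imaged in both channels give matched position pairs
(mutual nearest neighbors after subtracting the median displacement). The
correction from channel B into the channel-A frame is a local weighted
mean of second-order polynomial maps: around each control bead a quadratic
map is fitted by weighted least squares to its `k` nearest control pairs
(Gaussian weights scaled to the k-th neighbor distance, coordinates
centered and scaled for conditioning), and a query point takes the
Gaussian-distance-weighted blend of nearby local maps. The field is
evaluated on an 8-pixel grid and bilinearly interpolated; a direct
evaluator exists for validation and for queries outside the grid (counted
as extrapolation warnings).

**Neighborhood size.** At least 12 matched fiducials are required
throughout, but the default neighborhood per local fit is `k = 20`
(clamped to the number of pairs). A quadratic map has 6 coefficients; fit
to exactly 12 noisy bead positions it near-interpolates each center bead's
localization error (measured prediction-variance factor ≈ 0.37 per axis),
and the held-out residual lands ~1.3x above the localization noise floor.
With 20 neighbors the local fits smooth instead of memorize and the
residual tracks `sqrt(sigma_A^2 + sigma_B^2)` to within ~15%. Order-2
local fits reproduce any global warp of polynomial order ≤ 2 exactly:
noiseless quadratic warps of 50-nm amplitude correct to <2 nm on held-out
beads (the remaining error is dominated by the bilinear grid
interpolation, ~0.2 nm at the default pitch).

The residual misalignment `r` is the RMS distance between corrected
channel-B and channel-A positions over *held-out* bead pairs, never the
control pairs. It is stored with the model and is a mandatory input to
every separation record. One model per acquisition batch; the CLI ties
model files to image batches by explicit argument.

## Separation measurement

Foci are paired across channels by mutual nearest neighbors within a gate
(default 200 nm, the diffraction limit). For each pair,
`d = |pos_A − T(pos_B)|` and

    u = sqrt(sigma_A^2 + sigma_B^2 + r^2)

`d` is *significant* only when `d > u`. With the 15-nm per-peak precision
of the emulated experiment and a bead-limited `r ≈ 21 nm`, `u ≈ 30 nm` —
the combined separation precision quoted for this class of measurement.
All distances are 2D; unknown axial offsets are absorbed into the error
budget rather than modeled.

A population of separations is summarized as a fixed-width histogram
(default 30-nm bins, half-open `[kw, (k+1)w)`), with a least-squares
Gaussian through the binned counts; fitted curves are rescaled to a common
analytic area `A*sd*sqrt(2*pi)` so conditions with different n can be
overlaid. A Gaussian on distance magnitudes is wrong near zero (the true
zero-separation distribution is Rayleigh-like); it is kept as the primary
summary for comparability with the established presentation of such data,
and fitting the raw (unbinned) separations is available as an alternative.
With fewer than three nonzero bins the fit is degenerate and the empirical
mean is reported, flagged as such. `chance_colocalization` quantifies why
overlap implies same-allele origin: for foci scattered uniformly over a
nucleus, `p = 1 − (1 − n_A·4·spot_area/nuclear_area)^n_B`, well under 1e-2
for diffraction-sized spots in a 10×10 µm nucleus.

**Precision conventions.** The per-axis/radial ambiguity of a quoted
"15-nm precision" is resolved as follows: `sigma` from the formula is
per-axis; a quoted per-peak precision of 15 nm is taken as the 2D RMS
error (per-axis 15/√2). This keeps the arithmetic
`sqrt(15^2 + 15^2 + 21^2) ≈ 30 nm` self-consistent.

## Synthetic data: what it does and does not emulate

The generator produces isolated Gaussian spots, uniform Poisson
background, camera gain/read noise, bead fields and paired two-color
scenes under smooth chromatic warps (translation + rotation + quadratic
terms, amplitude bounded). It does **not** emulate: structured cellular
autofluorescence, channel bleed-through, fluorophore blinking/bleaching,
3D defocus, overlapping foci, or non-polynomial distortion. Passing tests
therefore demonstrate that the estimators, the registration and the error
propagation are correct and internally calibrated under the stated model —
not that real micrographs meet the model's assumptions; on real data the
QC gate exists precisely to reject foci that do not.

## Benchmark problem sizes

The shipped checks use 500 spots for convergence statistics, 500 per cell
for the precision calibration grid, 1000 paired spots for the estimator
ordering, 60-bead fields, 300 pairs for the colocalization control, and
~72 pairs per separation group (0/68/150/300 nm) for end-to-end recovery;
end-to-end scenes use bright (20000-photon) foci so that the recovery test
probes the registration and pairing chain rather than pure photon noise.
These sizes give stable medians and RMS values at desk scale.

## Known limitations

* Strictly 2D; no z-localization or drift correction.
* The LWM transform is not idempotent and extrapolates poorly outside the
  fiducial hull (flagged, not fixed).
* The precision formula is first-order; at background means ≳ 100
  photons/pixel with few signal photons it is substantially optimistic.
* The probe screens are exact-match combinatorics (GC window, k-mer
  uniqueness, spacing, span); no thermodynamics or secondary structure.
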