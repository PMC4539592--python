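# Methods

## Model and quantities

A spectral (lambda) stack assigns every image pixel an emission spectrum
`I_λ` sampled on a uniform channel grid. Channel `k` of an axis
`(start, width, n)` is identified with its center wavelength
`start + width·(k + 1/2)`; the canonical axis used throughout the
defaults is 32 channels of 8.9 nm from 415 nm (centers 419.45–695.35 nm).

Generalized polarization is computed per pixel as

    GP = (I_B − I_R) / (I_B + I_R),

with `I_B` read at the blue reference `λ_Lo` and `I_R` at the red
reference `λ_Ld` of the probe preset (C-Laurdan 440/490 nm,
Di-4-ANEPPDHQ 565/605 nm). Both intensities are divided by 255 before
the ratio; this mirrors the original plug-in convention and is exactly
value-neutral (the factor cancels), which a test asserts. A pixel with
`I_B + I_R = 0` has undefined GP and is stored as NaN — never 0, which
is a legal GP value.

`I_B`/`I_R` come from one of three methods:

* **direct** — the channel whose center is nearest the reference
  wavelength (ties break toward the lower wavelength; deterministic, no
  physical preference exists). Note this reads 437.25/490.65 nm on the
  canonical axis, not 440/490 nm: direct sampling estimates the GP *of
  the sampled grid*, and validation against ground truth uses exactly
  that quantity (`analytic_gp_sampled`), while fitted methods are held
  to the continuous analytic GP.
* **gaussian** — per-pixel least-squares fit of
  `I(λ) = A·exp(−(λ−μ)²/2σ²)` (no additive offset), evaluated
  continuously at `λ_Lo`/`λ_Ld`.
* **gamma_variate** — per-pixel fit of the peak-normalized gamma-variate
  line shape

      I(λ) = A·((λ−λ0)/(αβ))^α · exp(α − (λ−λ0)/β)   for λ > λ0, else 0,

  which peaks with height `A` at `λ0 + αβ`, is right-skewed for small
  shape `α`, and tends to a Gaussian of width `√α·β` as `α → ∞` — so it
  nests the symmetric case and is the better model for the skewed
  spectra seen in ordered membrane phases.

## Pipeline

`compute_gp_map` runs: optional per-channel sensitivity correction →
Z-projection (pixelwise channel sum) → linear min–max rescale to 0–255 →
threshold mask (strictly greater than the 8-bit threshold, default 15) →
optional background subtraction → per-pixel readout → GP.

Background is a per-slice scalar estimated from the dark area, defined
as the complement of the mask (all below-threshold pixels, rather than a
hand-picked dark region — deterministic and maximal sample size). The
statistic is the mean by default, median optionally for heavy-tailed
backgrounds. Subtraction applies only inside the mask and clips at zero;
masked-out pixels are returned bitwise unchanged.

For the fitting methods, each masked pixel's fit is scored with
`R² = 1 − SS_res/SS_tot` computed at the channel centers (matching what
was fitted); pixels with `R²` below the tolerance (default 0.8) or with
failed fits are excluded (NaN) and failures are counted, never raised.

## Numerical choices

* **Optimizer.** `scipy.optimize.least_squares` (bounded
  trust-region-reflective), tolerances 1e-8, evaluation budget of five
  function evaluations per nominal iteration (default cap 200
  iterations). Amplitudes and widths are bounded positive; the Gaussian
  center is confined to the detection window ± its span.
* **Spectrum normalization.** Each spectrum is divided by its maximum
  before fitting and the fitted amplitude rescaled afterwards. This
  makes the fit exactly scale-equivariant (fitting `c·I` returns `c·A`
  with identical shape parameters and R²) and gives all pixels the same
  conditioning regardless of detector units.
* **Gamma Variate parametrization.** Reported parameters are
  `(A, λ0, α, β)`, but the optimizer works in `(A, peak, effective
  width √α·β, log α)`. In the raw coordinates the near-symmetric limit
  is a curved ridge (`λ0 → −∞`, `α → ∞` jointly) on which bounded least
  squares stalls far from the optimum; in the internal coordinates that
  limit is the single direction `log α → ∞` and fits of symmetric
  spectra converge in a few dozen evaluations with GP errors of a few
  1e-4. `log α` is bounded to [ln 1e-3, ln 1e9].
* **Onset bound.** The emission onset `λ0` is constrained below the
  first channel center − 1 nm (the probe's emission rises blue of the
  detection window). If the internally parametrized optimum violates
  the bound — possible only for strongly skewed spectra — the fit is
  redone in raw coordinates with the bound active.
* **Initial guesses.** Gaussian: amplitude = max intensity, center =
  intensity-weighted mean wavelength, σ = intensity-weighted SD floored
  at half a channel width. Gamma Variate: onset pinned one channel blue
  of the window, then shape and scale by method of moments (the curve is
  proportional to a gamma density of shape `α+1`, scale `β`, so
  `α + 1 = (m−λ0)²/s²`, `β = s²/(m−λ0)` from the weighted mean `m` and
  SD `s`).
* **Degenerate inputs.** All-zero spectra are non-converged results
  (NaN R², excluded downstream). A constant nonzero spectrum has zero
  variance to explain, so R² is undefined (NaN) and the pixel is
  excluded. A constant Z-projection rescales to all-zero 8-bit, giving
  an empty mask — fail-safe. Negative intensities on load are clipped to
  zero with a warning (detector offsets).
* **8-bit rescale.** Linear min→0/max→255 with round-half-to-even; the
  mask inequality is strict (`> threshold`).
* **Histogram.** Uniform bins over [−1, 1], default width 0.02 (fine
  enough to resolve phase separations of ΔGP ≥ 0.3 with many bins
  between modes); SD is the population SD; `median_positive`/`_negative`
  are medians over GP > 0 / < 0, NaN for empty subsets; mode is the
  center of the fullest bin, lowest bin on ties.

## Synthetic scenes

The generator emulates equatorial-plane vesicle images: a circular ring
(membrane cross-section) of given radius and thickness over a flat (or
per-channel) background, partitioned into angular sectors that each
carry one spectral model. Defaults are the canonical two-phase
conditions: Gaussian sector spectra peaked at 440 nm (ordered) and
490 nm (disordered), σ = 25 nm, on the 32-channel axis; 128×128 image,
ring radius 42 px, thickness 8 px (a vesicle filling about two thirds of
the field, with ≈1000 pixels per phase); background 2 counts per
channel. Noise is Poisson (shot noise on expected counts) or additive
Gaussian clipped at zero, from a seeded `numpy` generator; rendering is
bitwise deterministic given (scene, noise model, seed). Peak SNR is peak
expected signal over its SD: amplitude = SNR² under Poisson noise.
Right-skewed scenes use gamma-variate sector spectra with the onset one
channel blue of the window and the scale chosen to keep the requested
peak positions.

Ground truth carries the per-pixel sector label and the analytic GP of
each sector's continuous model at the preset (plus, for validating
direct sampling, the channel-sampled variant).

What the scenes do **not** emulate: optics (no point-spread blur),
photophysics (bleaching, detector afterpulsing), 3-D geometry,
polarization/photoselection effects, spatially structured backgrounds,
or sub-pixel ring edges (membership is binary). Passing tests therefore
demonstrate the correctness of the estimator pipeline under known
single-peak spectra and ideal segmentation geometry, not performance on
real microscope data, where mask quality, spectral mixing at phase
boundaries and detector artifacts add further error sources.

## Design decisions

* Carrier format is plain multi-page TIFF/OME-TIFF; the wavelength axis
  comes from explicit configuration (which always wins) or from file
  metadata (a JSON payload this package embeds on write, or OME
  `EmissionWavelength` attributes on a uniform grid). Mismatches are
  errors, never silently resolved.
* The Di-4-ANEPPDHQ preset is 565 nm (blue, `λ_Lo`) / 605 nm (red,
  `λ_Ld`), consistent with the probe's emission maxima in ordered
  (565 nm) and disordered (610 nm) reference membranes.
* The colored GP rendering uses matplotlib's `RdYlBu_r` over [−1, 1]
  with excluded pixels black; the colormap is a documented convention,
  not a fidelity target.
* `AnalysisConfig` lives in its own module so both the pipeline and the
  CLI import it without cycles; the CLI commands (`gp-map`,
  `gp-compare`, `gp-hist`, `gp-simulate`) are thin `click` wrappers that
  serialize the effective configuration into each output directory's
  `manifest.json`.

## Problem sizes

Test and acceptance runs use 64×64 scenes (≈540 ring pixels) for
noiseless recovery and fit-quality comparisons, the full 128×128
default (≈2100 ring pixels) for the SNR-10 de-noising check, 256×256
(>10⁴ ring pixels) for the law-of-large-numbers check on the noise
model, and 1000 Monte-Carlo replicates for the fitted-peak bias check.
These sizes give sub-percent standard errors on every reported mean
while keeping a full suite run around a minute.

## Known limitations

* Per-pixel fitting is a Python loop over `least_squares` calls
  (~2–10 ms per pixel); megapixel stacks would want batching or
  vectorized fitting.
* Single 2-D plane per analysis; no time series or z-stacks.
* Single-peak models only: no spectral unmixing, multi-component fits,
  or dipolar-relaxation modeling.
* Mask construction is a plain global threshold; no morphological
  cleanup or spatially varying background model (the background is one
  scalar per slice).
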