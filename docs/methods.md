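# Methods

`specklequant` is a fully synthetic re-implementation of a fiber-specklegram
biosensing workflow for quantifying the tumor biomarker CEACAM5
(carcinoembryonic antigen) in the 1–1000 ng/mL range.  The physical
instrument it emulates is a tapered multimode fiber whose evanescent field
samples the medium at the taper waist: antigen binding to the
antibody-functionalised surface shifts the local refractive index, which
re-phases and re-couples the guided modes and therefore reshapes the output
speckle pattern recorded by a camera.  The package simulates that chain,
demodulates it with zero-mean normalized cross-correlation (ZNCC), calibrates
the dose-response, and decodes concentration with a convolutional network.

## Forward model (speckle_sim)

**Mode superposition.**  The output field is
`A(x,y) = Σ_m a_m ψ_m(x,y) exp(j φ_m)` over `M` guided modes and the camera
records `I(x,y) = |A(x,y)|²`, equivalently the double sum
`Σ_m Σ_n a_m a_n ψ_m ψ_n exp(j(φ_m − φ_n))`.  Both forms are implemented and
tested against each other.  True guided-mode profiles of a tapered fiber
would require an electromagnetic solver, which is out of scope; the
simulator substitutes **surrogate mode profiles**: seeded Gaussian random
fields low-pass filtered to a correlation length of ~1/40 of the grid side,
then QR-orthonormalised so the discrete Gram matrix is the identity to
1e-8 (a 2D cosine-product basis is available as an option).  This preserves
what the downstream analysis actually consumes — fully developed,
mode-count-limited interference statistics — without modelling fiber
geometry.

**Mode coupling.**  An external perturbation exchanges power between modes:
`ΔP_m = gain · Σ_{n≠m} h_mn (p_n − p_m)` with a symmetric, zero-diagonal,
non-negative coupling matrix `h` (entries i.i.d. uniform on `[0, h_scale]`,
`h_scale = 0.05`, seeded).  The default sign convention ("relax") moves
power toward equipartition; the opposite sign, which amplifies imbalance,
is selectable (`coupling.convention: printed`).  Under either convention
`Σ_m ΔP_m = 0` exactly, because `h` is symmetric and `(p_m − p_n)` is
antisymmetric; powers are clipped at zero and re-normalised after each
step.

**Dose response.**  Concentration enters through a Hill-form response
`r(c) = response_max · c^h / (K^h + c^h)` (defaults `K = 100 ng/mL`,
`h = 1`), chosen because the sensor's correlation readout saturates
logistically over the three-decade panel.  `r(c)` drives per-mode phase
shifts `φ_m ← φ_m + β_m r(c)` and one coupling step with gain
`coupling_scale · r(c)` (`coupling_scale = 0.2`).  `r(0) = 0`, so the
baseline state is exactly the 0 ng/mL sensor.  The per-mode sensitivities
`β_m` are a stratified draw from `U(0.25, 1.75)` (one value per
equal-probability stratum, assigned to modes in seeded random order).

**Per-fiber response calibration.**  A phase shift common to all modes
leaves `|A|²` unchanged, so the speckle decorrelation is governed by the
power-weighted dispersion of `β` and by fourth moments of the drawn basis —
i.e. each simulated fiber, like each fabricated taper, has its own
intrinsic responsivity.  The generator therefore calibrates each fiber the
way the physical sensor is calibrated: `β` is rescaled to unit
power-weighted dispersion, a noise-free small-signal probe measures the
fiber's ZNCC decorrelation per unit squared response,
`d = (1 − ZNCC(I(φ), I(φ + εβ)))/ε²` with `ε = 0.05`, and `response_max`
is solved from the small-signal model `z(c) ≈ 1 − d·(response_max·x(c))²`,
`x(c) = c^h/(K^h + c^h)`, so that the OLS slope of mean ZNCC vs
concentration over the 1–50 ng/mL sub-panel equals the target surface
sensitivity of 0.0012 (ng/mL)⁻¹.  Measured end to end (with noise), the
realised sensitivity sits within ±9% of the target across 20 independent
fiber seeds.  Setting `dose.response_max` explicitly bypasses the
self-calibration (used by the calibration sweep in
`analysis/03_calibrate_dose_response.py`).

**Replicates and camera.**  Frames within a concentration class share the
fiber and differ by a per-frame phase jitter (Gaussian, σ = 0.01 rad,
emulating frame-to-frame drift) and by camera noise: scaled-Poisson shot
noise (4 photons per count), additive Gaussian read noise (σ = 30 counts),
clipping and 16-bit quantisation.  The baseline intensity is scaled so its
mean sits at 8000 counts (~12% of full scale), keeping bright speckle
grains below saturation for all but ~0.3% of pixels.  Acquisition metadata
(5.3 µm pixel pitch, 6 ms exposure, 5 mm tip-to-camera distance, 7.46 µm
taper waist) is carried for provenance only; free-space propagation from
tip to camera is not modelled and the speckle is rendered at the output
plane directly.

**Dataset protocol.**  The default panel is 1, 5, 10, 20, 30, 50, 100,
500, 1000 ng/mL with 100 frames per class (900 total), split 50/25/25 into
train/validation/test, stratified exactly within each class.  By default
the speckle is rendered directly on the 320×256 analysis raster; rendering
at the native 1280×1024 camera raster followed by ×4 block-mean
downsampling is a config change (`grid: {width: 1280, height: 1024}`,
`preprocess: {factor: 4}`) and is exercised in tests at reduced size.
Identical (config, seed) regenerates the dataset bit for bit.

## Preprocessing (preprocess)

Grayscale reduction (3-channel inputs by unweighted channel mean),
normalisation to [0,1] (default: division by the sensor full scale, which
preserves relative brightness between frames; per-image min–max by
option), then non-overlapping block-mean downsampling, which preserves the
global mean exactly and rejects pixel noise.  The chain order is
grayscale → normalise → downsample.  No registration, denoising or
cropping is performed.

## ZNCC demodulation (zncc)

`ZNCC = Σ(I₀−Ī₀)(I−Ī) / √(Σ(I₀−Ī₀)² · Σ(I−Ī)²)` over all pixels — the
standard form with the two centered energies as separate sums under the
root, which is the form that carries the invariance to positive affine
brightness changes (an alternative reading that collapses both squares
under a single integral does not, and is not used).  Zero-variance inputs
raise rather than silently returning 0.  The reference frame is the
0 ng/mL baseline render of the same fiber.  Correlation curves are
per-concentration means ± sd of ZNCC against that reference, computed on
the preprocessed (downsampled) frames.

## Dose-response calibration (calibration)

The nine-point curve is fitted with a four-parameter logistic on a log10
concentration axis (the panel spans three decades), initialised from data
quantiles with a few slope-factor restarts; degenerate (flat) curves and
<4-point curves raise.  The 1–50 ng/mL sub-range is fitted by ordinary
least squares on the per-concentration means (unweighted, since replicate
counts are equal by construction; inverse-variance weighting is a
documented option not enabled by default), and the **surface sensitivity**
is |slope| in (ng/mL)⁻¹ — ZNCC is dimensionless.  Both fits invert in
closed form; estimates outside the fitted span clamp to the fit-range
boundary and set an extrapolation flag.  Noise-free round trips recover
concentrations to 1e-9 and 4PL parameters to 1e-6 (tested).

## CNN quantifier (cnn)

No deep-learning framework is used: the network is implemented in NumPy
(im2col convolutions backed by BLAS matrix products, analytic
backpropagation gradient-checked against central differences, Adam).
Architecture: three conv blocks (16/32/64 filters, 3×3 kernels, ReLU,
2×2 max-pool), a 256-unit dense ReLU layer, and a 9-way softmax; He
initialisation, cross-entropy loss.  All randomness is seeded; training
is exactly reproducible.

The model input is the preprocessed frame block-mean downsampled ×4 to
80×64 (desk scale; the full 320×256 input is a config change) and then
**standardised against the train split** (subtract the train-mean image,
divide each pixel by its train standard deviation, floored at 10% of the
mean deviation).  Standardisation matters here: concentration classes
differ by ~0.1% of full scale around a common speckle carrier, and
centering removes that carrier so the class signal is O(1) for the
optimiser.

**Optimisation schedule.**  Expected-value decoding demands near-one-hot
probabilities — a stray probability of 1e-3 on the 5 ng/mL class already
produces a 0.4% relative error on a 1 ng/mL frame — so the trainer is
built to converge deep within the 30-epoch budget.  The first two thirds
of the budget run plain mini-batch Adam (step 3e-3, batch 16); the
remainder anneals with one epoch per fresh-Adam restart at a third of
the step size.  Resetting the optimiser moments reliably drops the
cross-entropy by several further orders of magnitude (plain Adam stalls
near 1e-5; the annealed phase typically reaches 1e-7–1e-9), and the
occasional post-restart spike is harmless because the deployed weights
are the best-validation-loss snapshot over all epochs.  A candidate is
accepted once that snapshot's validation cross-entropy reaches 1e-6 —
empirically the regime in which even the least favourable test frames
decode to well under 0.1% error — otherwise training restarts from a
fresh seeded initialisation (at most twice) and the best-validation
model over all attempts is kept.  Selection uses the validation split
only.  Smaller steps, larger batches or a single continuous Adam run
were measured to stall at cross-entropies (1e-3–1e-5) whose decoded
errors are one to two orders of magnitude worse; those measurements
motivated these defaults.

**Decoding.**  The continuous estimate is the expectation of the panel
under the class probabilities, `ĉ = Σ_k P_k c_k`, with the argmax class
reported alongside.  With equal-count classes and a classifier trained to
high confidence this yields sub-percent continuous errors; the evaluation
reports per-image relative errors `|ĉ − c|/c × 100%`, their maximum, the
OLS line of decoded vs true concentration, per-class accuracy and the
confusion table.  `ĉ` is bounded by the panel extremes by construction.

## Pipeline, seeds and provenance (config, manifest, pipeline, cli)

A single global seed is fanned out to stage seeds (modes, coupling, dose,
dataset, CNN) by SHA-256 hashing of `(seed, stage-tag)`, so stages can be
rerun in isolation and still agree with a full run.  Configs are strict
(unknown keys rejected by name), YAML-round-trippable, and hashed for
provenance; every persisted artifact is written next to the resolved
config.  The `specklequant` CLI exposes the stages
(`simulate`, `preprocess`, `curve`, `calibrate`, `invert`, `train`,
`evaluate`, `reproduce`); the numbered scripts under `analysis/` are
narrative drivers over the same library.

## Problem sizes

Defaults were chosen so the full pipeline runs on one CPU core in a few
minutes: direct 320×256 rendering (the analysis raster), 30 modes, 900
images, 80×64 CNN input, ≤30 epochs.  The surface-sensitivity measurement
uses 10 frames per concentration at 1, 5, 10, 20, 30, 50 ng/mL per fiber
seed.  Unit tests run on 64×64 grids with ≤12 modes.

## What the generator does and does not emulate

It emulates: mode-interference speckle statistics with a finite mode
count, a saturating dose-response with the target low-range surface
sensitivity, frame-to-frame drift, shot/read noise and quantisation, and
the exact dataset protocol (panel, counts, split).  It does not emulate:
electromagnetic mode structure or fiber geometry, free-space diffraction
between fiber tip and camera, functionalisation chemistry or binding
kinetics (the dose-response abstraction stands in for them), temperature
or mechanical drift beyond the phase-jitter term, or inter-fiber
fabrication variability of the dose-response *shape* (only the amplitude
is fiber-specific).  Passing tests therefore demonstrate that the analysis
chain — demodulation, calibration, decoding — recovers what the forward
model encodes; they do not certify performance on real acquisitions,
where drift, speckle contrast and class separability can be less
favourable.

## Numerical choices and degenerate inputs

QR orthonormalisation signs are fixed deterministically (LAPACK sign
ambiguity); ZNCC raises on zero-variance images; min–max normalisation
raises on constant images; block-mean downsampling requires exact
divisibility (no implicit padding); the 4PL fit raises on flat or
under-determined curves and bounds its restarts; logits are computed in
float32 and softmax/losses in float64; probability vectors are validated
to sum to 1 within 1e-6 before decoding; split ratios must divide the
per-class count exactly.

## Known limitations

* The surrogate basis reproduces interference statistics, not modal
  physics; mode-resolved quantities (e.g. which modes carry the response)
  are not physically meaningful.
* Expected-value decoding is bounded by the panel extremes, so true
  concentrations outside [1, 1000] ng/mL cannot be estimated.
* The decorrelation-vs-concentration sign is fixed (ZNCC decreases with
  concentration) as the shipped default; the opposite sign is a config
  change and the calibration handles either.
* With 9 classes the classifier sees large inter-class gaps on the log
  axis; real continuous-concentration samples between panel points would
  decode to panel-bracketed interpolations whose accuracy is untested
  here.
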