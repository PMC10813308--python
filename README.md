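# specklequant

Synthetic end-to-end analysis of a **fiber-specklegram biosensor** for the
tumor biomarker **CEACAM5** (carcinoembryonic antigen).  A tapered
multimode fiber's evanescent field senses antigen binding as a surface
refractive-index change; that perturbs the phases and powers of the guided
modes, reshaping the speckle pattern `I(x,y) = |Σ_m a_m ψ_m e^{jφ_m}|²`
recorded by a camera.  This package simulates that chain and quantifies
concentration two ways:

1. **ZNCC demodulation + dose-response calibration** — the zero-mean
   normalized cross-correlation between each frame and the 0 ng/mL
   baseline,
   `ZNCC = Σ(I₀−Ī₀)(I−Ī) / √(Σ(I₀−Ī₀)² Σ(I−Ī)²)`,
   falls monotonically with concentration; a four-parameter logistic fits
   the full 1–1000 ng/mL panel and an OLS line over 1–50 ng/mL gives the
   **surface sensitivity** |slope| ≈ 0.0012 (ng/mL)⁻¹, invertible to a
   concentration estimate.
2. **CNN decoding** — a small convolutional classifier (NumPy
   implementation; conv–pool blocks, softmax over the 9-concentration
   panel) decodes each frame to `ĉ = Σ_k P_k c_k`, the expectation of the
   panel under the class probabilities, achieving sub-0.1% maximum
   relative error on the held-out test split.

The forward model, both decoders, the dataset protocol (900 frames, 9
concentrations, 450/225/225 split) and all seeds live in the library
under `src/specklequant/`; the numbered scripts under `analysis/` are the
narrative drivers.  Everything is seeded: one (config, seed) pair
regenerates the dataset bit for bit.  See `docs/methods.md` for the model,
its assumptions and its limitations.

## Worked example

```sh
python analysis/01_generate_dataset.py
python analysis/02_correlation_curve.py
python analysis/03_calibrate_dose_response.py
python analysis/04_train_quantifier.py
```

`01` renders the dataset (16-bit PNGs + CSV manifest under
`results/dataset/`):

```
wrote 900 specklegrams (9 concentrations) to results/dataset/images
split: train=450 validation=225 test=225
fiber response_max (auto-calibrated): 0.6219
```

`02` demodulates it against the 0 ng/mL baseline and fits the
dose-response:

```
 concentration_ng_per_ml  mean_zncc  sd_zncc   n
                     1.0   0.999748 0.000049 100
                     5.0   0.998660 0.000157 100
                    10.0   0.995577 0.000293 100
                    20.0   0.985546 0.000504 100
                    30.0   0.972458 0.000685 100
                    50.0   0.943981 0.001034 100
                   100.0   0.882255 0.001454 100
                   500.0   0.730113 0.001690 100
                  1000.0   0.694681 0.001593 100

surface sensitivity |slope| over 1-50 ng/mL: 0.00116 (ng/mL)^-1 (r^2=0.9785)
logistic midpoint 151.9 ng/mL, r^2=0.99973
```

The correlation falls logistic-like over three decades; the 1–50 ng/mL
slope magnitude is the sensor's surface sensitivity.  `03` shows why it
lands on target: each simulated fiber is self-calibrated from a
small-signal probe (sensitivity scales with the squared response
amplitude; across five independent fiber seeds the realised sensitivity
stays within 3.6% of the 0.0012 (ng/mL)⁻¹ target).  `04` trains the CNN
quantifier at desk scale (80×64 input) and evaluates the test split:

```
max relative decoding error on the 225 test images: 0.015%
decoded-vs-true slope: 1.00000
```

i.e. expected-value decoding over the class probabilities tracks the true
concentration essentially perfectly once training converges deep (the
trainer anneals with fresh-optimiser restarts and accepts only candidates
whose validation cross-entropy reaches 1e-6).

The same stages are exposed as a CLI (`specklequant simulate|preprocess|
curve|calibrate|invert|train|evaluate|reproduce --help`).

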