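# spectralgp

Generalized polarization (GP) mapping from spectral (lambda) fluorescence
image stacks, with per-pixel emission-spectrum curve fitting.

## The problem

The lateral packing of membrane lipids — tight and ordered (Lo) versus
loose and disordered (Ld) — can be read out with polarity-sensitive
probes such as **C-Laurdan** or **Di-4-ANEPPDHQ**, whose emission
spectrum red-shifts as the membrane becomes more disordered. The standard
quantity is the generalized polarization

```
GP = (I_B − I_R) / (I_B + I_R)
```

where `I_B` and `I_R` are the emission intensities at a blue-shifted
reference wavelength `λ_Lo` (emission maximum in an ordered membrane) and
a red-shifted reference `λ_Ld` (maximum in a disordered membrane). GP lies
in [−1, 1]; higher GP means tighter lipid packing. For C-Laurdan
`λ_Lo = 440 nm`, `λ_Ld = 490 nm`; for Di-4-ANEPPDHQ `λ_Lo = 565 nm`,
`λ_Ld = 605 nm`.

On a spectral confocal microscope, every image pixel carries a full
emission spectrum (e.g. 32 detection channels of 8.9 nm covering
415–700 nm). `spectralgp` turns such multi-page TIFF stacks into GP maps
two ways:

1. **Direct sampling** — read the channels whose centers are nearest
   `λ_Lo` and `λ_Ld`;
2. **Whole-spectrum curve fitting** — fit each pixel's spectrum with a
   Gaussian (no offset) or a right-skew-capable **Gamma Variate** line
   shape, score it with R², and evaluate the fitted curve exactly at
   `λ_Lo`/`λ_Ld`. Fitting de-noises the map and removes the channel-grid
   quantization of direct sampling.

The pipeline mirrors established spectral-GP practice: Z-projection of
the stack, 8-bit threshold mask, per-slice background subtraction from
the dark area, optional per-channel sensitivity correction, per-pixel
R² filtering of fits, and histogram/statistics reporting (including
separate medians of the positive and negative GP sub-populations).

A fully parametric synthetic-scene generator (vesicle rings with
per-sector spectra, Poisson or Gaussian noise) provides ground truth so
every stage is testable without microscope data.

## Worked example

Render a phase-separated vesicle (ordered sector peaked at 440 nm,
disordered at 490 nm, σ = 25 nm, Poisson noise at peak SNR 20) and
compare all three analysis methods:

```python
import spectralgp as sg

scene = sg.make_two_phase_vesicle(amplitude=sg.amplitude_for_peak_snr(20, "poisson"))
stack, truth = sg.render_stack(scene, noise="poisson", seed=7)
result = sg.compare_methods(stack, sg.AnalysisConfig(), phase_labels=truth.phase_label)
print(result.summary[["method", "mean_gp", "sd_gp", "mean_r2",
                      "phase0_mean_gp", "phase1_mean_gp"]].round(4).to_string(index=False))
```

prints

```
       method  mean_gp  sd_gp  mean_r2  phase0_mean_gp  phase1_mean_gp
       direct  -0.0179 0.7879      NaN          0.7694         -0.8052
     gaussian  -0.0009 0.7614   0.9967          0.7602         -0.7620
gamma_variate  -0.0079 0.7621   0.9968          0.7539         -0.7697
```

Reading the numbers: the analytic GP of the ordered sector's spectrum at
(440, 490) nm is tanh(1) ≈ 0.7616 and the disordered sector's is
−0.7616; both fitting methods land on them. Direct sampling reports
±0.77/−0.81 instead because it reads the nearest channel centers
(437.25 and 490.65 nm) rather than 440/490 nm exactly — a systematic
offset of the method, not noise. The whole-map `mean_gp` is near zero
because the two phases are equally large.

## Command line

```sh
gp-simulate --preset two-phase --size 128 --snr 20 --noise poisson --seed 7 -o scene/
gp-map scene/stack.tif --method gamma --probe c-laurdan -o out/
gp-compare scene/stack.tif -o cmp/
gp-hist out/gp.tif --bin-width 0.02 -o hist/
```

`gp-map` writes the GP map (32-bit float TIFF, excluded pixels NaN), a
color rendering (PNG, diverging map over [−1, 1]), the mask (8-bit
TIFF), the per-pixel R² image (float TIFF, fitting methods), the GP
histogram and summary statistics (CSV), and a `manifest.json` recording
the effective configuration. All flags can come from a YAML file via
`--config`; explicit flags win.

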