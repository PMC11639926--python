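# siribruise

Early, slight subsurface bruises in soft fruit (the motivating case is the
yellow peach) are nearly invisible under uniform illumination: the peel is
intact and the damaged flesh sits below it. **Structured-illumination
reflectance imaging (SIRI)** makes them visible by projecting a sinusoidal
light pattern of spatial frequency *f* (cycle/mm) onto the fruit and
demodulating three phase-shifted pattern images *I₁, I₂, I₃* (phases
−2π/3, 0, 2π/3) into

```
I_AC = (√2/3) · √[(I₁−I₂)² + (I₁−I₃)² + (I₂−I₃)²]        I_DC = (I₁+I₂+I₃)/3
```

The DC image is equivalent to uniform illumination; the AC image is the
local modulation amplitude, whose effective photon penetration depth is
set by *f*, so subsurface damage shows up as an AC-contrast defect.

`siribruise` implements the full analysis chain for this technique, aimed
at researchers in optical non-destructive testing of produce:

* **calibration** — flat-field / dark-frame correction
  `R = (R₀ − B)/(W − B)` against white/black reference frames;
* **demodulation** — the three-phase AC/DC decomposition above, plus the
  fruit-foreground mask (fixed DC threshold of 15 on the 8-bit scale);
* **enhancement** — histogram equalization of the AC image, the ratio
  image `RT = I_AC / I_DC` (cancels multiplicative shading such as
  curvature vignetting while retaining bruise contrast), and a 10×10
  sliding-window median filter against dark-spot speckle;
* **segmentation** — global fixed thresholding, Otsu's method
  (maximize `p₀p₁(μ₀−μ₁)²`), and an **improved Otsu** objective

  ```
  argmax_T  p₀p₁(μ₀−μ₁)² + (μ₀−μ)² + (μ₁−μ)²,   μ = p₀μ₀ + p₁μ₁
  ```

  that weighs each class mean's distance from the global mean and is more
  robust to dark-spot noise (surface pits, stems, sutures); followed by
  connected-component area filtering and the sample-level rule *bruised ⇔
  any pixels survive*;
* **parameter selection** — peak-to-valley contrast of line profiles
  through the bruise, ranked over a (spatial frequency, wavelength) grid;
* **phantom simulator** — seeded synthetic fruit discs with ground-truth
  bruise masks, frequency/wavelength-dependent modulation decay, pits,
  vignetting, sensor noise and matching reference frames, for validating
  every stage without access to a fruit imaging rig.

## Worked example

```python
import siribruise as sb

# a synthetic bruised peach imaged at 0.10 cycle/mm and 700 nm
spec = sb.PhantomSpec(seed=42, bruise=sb.BruiseSpec(center=(60, 70), semi_axes=(17, 21)))
sample = sb.render_phantom(spec, 0.10, 700.0)

result = sb.run_pipeline(sample)   # improved Otsu on the ratio image
print(result.classification.label, result.segmentation.threshold,
      result.classification.surviving_pixels)
```

prints

```
bruised 138 1089
```

the sample is called bruised: the selected threshold (level 138 of the
rescaled ratio image) leaves 1089 connected bruise pixels after cleanup,
against 1113 ground-truth bruise pixels (Dice overlap 0.97). A bruise-free
phantom (`sb.PhantomSpec(seed=7)`) comes back `normal` with 0 surviving
pixels.

A full detection study — render seeded cohorts of 50 normal and
100 bruised phantoms, run the pipeline, tabulate per-class accuracies:

```python
report = sb.bruise_detection_study(n_normal=50, n_bruised=100, n_sets=2, seed=1)
print(report.total_accuracy_pct)        # 96.3
print(report.class_accuracy_pct)        # {'bruised': 100.0, 'normal': 89.0}
```

The same chain is scriptable from the shell:

```bash
siribruise simulate --n-normal 5 --n-bruised 10 --seed 1 --out-dir data/
siribruise run --manifest data/manifest.csv --method iotsu --image-style rt --out-json report.json
```

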