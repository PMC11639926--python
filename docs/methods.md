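# Methods

## Signal model

Structured-illumination reflectance imaging projects a sinusoid of spatial
frequency *f* (cycle/mm) onto the sample and records three pattern images
at phase offsets −2π/3, 0, 2π/3. For an ideal scene,
`I_k = I_DC + I_AC·cos(φ + θ_k)`, and the demodulation formulas

```
I_AC = (√2/3)·√[(I₁−I₂)² + (I₁−I₃)² + (I₂−I₃)²]      I_DC = (I₁+I₂+I₃)/3
```

recover amplitude and offset exactly for any global phase φ (the identity
is exercised to machine precision in the tests). Pattern images are first
calibrated as `R = (R₀ − B)/(W − B)` against a white diffuse plate
(reflectivity 0.98) and a capped-lens dark frame; pixels where `W ≤ B`
carry no calibration information and are zeroed and counted rather than
propagated as infinities.

All images are real-valued in [0, 1] internally. Conversion to the 8-bit
scale (×255, round-half-up) happens only at file I/O and where the
method fixes 8-bit constants: the fruit-foreground mask is `DC > 15`
(strict; the choice of strict vs. inclusive is a convention, documented
here) and threshold selection operates on 256-level histograms.

## Enhancement

The AC image carries the bruise contrast but also the multiplicative
shading of a curved fruit (bright center, dark rim). The ratio image
`RT = I_AC / I_DC` cancels any gain field common to both components —
exactly, as a property test verifies — while a bruise, which suppresses
modulation much more than mean reflectance, stays dark. Division is
guarded at `DC ≤ 1/255` (below one 8-bit quantum the DC image carries no
signal); guarded pixels are zeroed and counted.

Histogram equalization is the classic 256-level integer mapping
`(cdf(v) − cdf_min)/(n − cdf_min)`, computed over foreground pixels only;
it is monotone (rank-preserving) and leaves a constant region unchanged.

The median filter default is a 10×10 sliding window. An even window has
no center pixel; the output pixel is anchored at position ⌈s/2⌉ (1-based)
along each axis, edges use symmetric (reflect) padding, and a 9×9 odd
window is available by configuration. Inside the pipeline the filter is
mask-aware: background pixels are excluded from every window, because a
zero background would otherwise bleed a dark rim into the fruit edge and
create spurious dark components.

Ratio images have no fixed range and are min-max rescaled to [0, 1] over
the foreground before quantization. Rescaling happens *after* median
filtering so that single-pixel outliers (noisy RT values where DC is
small near the mask boundary) cannot set the range.

## Threshold selection

Candidate thresholds split the 256-level histogram into class 0 (levels
≤ T) and class 1 (levels > T); candidates leaving a class empty are
excluded, and ties resolve to the smallest maximizing level for
determinism. Otsu's method maximizes the between-class variance
`p₀p₁(μ₀−μ₁)²`, equivalent to minimizing the within-class variance (both
formulations are brute-force-checked against each other in the tests).
The improved objective adds the squared distances of each class mean from
the global mean:

```
p₀p₁(μ₀−μ₁)² + (μ₀−μ)² + (μ₁−μ)²  =  (μ₀−μ₁)²·(1 − p₀p₁)
```

(the closed form follows from μ = p₀μ₀ + p₁μ₁ and is verified to 1e−9).
Relative to Otsu it tolerates very unbalanced splits with large mean
separation, so a compact dark tail — pits, stems, a bruise — is cut off
where it ends instead of dragging the threshold into the body of the
sound-tissue mode. That is the mechanism behind its robustness to
dark-spot noise.

**Histogram domain.** By default the selection histogram is built over
the *background-removed image including its zero background* (the
`histogram_domain='image'` setting), which is exactly the image the
thresholding stage sees after the mask multiplication. The background
mass anchors class 0 at level 0, and the selected threshold falls between
the dark (background + bruise) and sound-tissue modes. Restricting the
histogram to foreground pixels (`'foreground'`) is available but fragile:
the closed form above is then maximized by the extreme darkest-level cut
unless the bruise mode is implausibly deep (below roughly a tenth of the
sound-tissue mean after rescaling), the selected class degenerates to a
few pixels, and the min-area cleanup erases true bruises. Both behaviors
were confirmed on phantom suites; the image-domain default detects 100%
of phantom bruises where the foreground-only variant missed about half.

The bruise class is levels ≤ T (`polarity='below'`): bruises and
dark-spot noise are low-intensity in AC and RT images. Components smaller
than `min_area` (default 50 px at the default phantom resolution; a
components-equal-to-min-area boundary is retained) are removed with
8-connectivity, and the sample is *bruised* iff any pixels survive.

**Dynamic-range floor.** Automatic thresholding is only attempted if the
enhanced image spans at least `min_dynamic_range` (default 0.05 in unit
intensity) over the foreground after filtering. A featureless image —
residual sensor noise flattened by the median filter — would otherwise be
stretched to full range by the rescaling and split into meaningless
classes; below the floor the sample is classified normal. The default is
roughly ten times the post-median noise floor of the phantom and half the
shallowest programmed defect contrast.

## Parameter selection

Bruise separability at each (f, λ) is measured as the peak-to-valley
contrast of a pixel-intensity profile through the bruise:
`max(normal window) − min(bruise window)`, floored at 0, with the windows
supplied explicitly (from ground truth, in phantom studies). Profiles use
Bresenham nearest-pixel sampling. The (f, λ) pair with maximal contrast
wins; ties break toward lower frequency, then lower wavelength.

## The phantom simulator

The generator renders what the rig would record for a fruit on a dark
stage, with image formation

```
raw_k = dark + gain(x,y)·(R_dc + R_ac·cos(2πf·x_mm + θ_k)) + N(0, σ)
```

quantized to 8 bits, where `gain` is radial curvature shading
(1 − v·(r/R)², clipped at 0.1; *not* removable by flat-field calibration,
since the white plate is flat), `R_dc` the local mean reflectance, and
`R_ac = R_dc · depth(f, λ)`. The modulation depth of sound tissue is a
phenomenological single exponential, `depth = d₀·g(λ)·exp(−f·c)` — a
deliberate simplification of diffusion-theory attenuation, keeping only
its defining feature that higher spatial frequencies are damped faster.

Defaults (frozen as the package's study conditions): 128×128 px at
0.5 mm/px; disc radius 45 px (a ~45 mm fruit face); `R_dc` 0.60;
vignette 0.35; `d₀` 0.60 with decay 3.0 mm/cycle and wavelength gains
{700: 1.0, 750: 0.85, 800: 0.70} (photon efficiency and reflectivity drop
toward the NIR); sensor noise σ = 0.004 with dark level 0.02; white plate
0.98. The bruise is an ellipse (default semi-axes ~17×21 px, ~9–11 mm)
with DC contrast 0.05 and AC contrast 0.55 scaled by a band-pass
frequency response `(f/f₀)²·exp(2(1−f/f₀))` peaking at f₀ = 0.10
cycle/mm: uniform illumination probes past a subsurface defect and very
high frequencies never reach it. With the wavelength gains above, the
programmed contrast optimum of the default configuration is
(0.10 cycle/mm, 700 nm). Surface pits are small discs (radius 2–5.5 px)
with reflectance drop 0.30 and an extra 0.25 modulation drop, so they are
nearly as dark as bruises in AC images but distinctly shallower in RT.
An optional stem/suture streak is available. Dataset generation
randomizes bruise geometry and location, pit count/size/placement, and
mild per-fruit reflectance and shading variation; every sample's
generator derives deterministically from one seed.

What the phantom does *not* emulate: real diffusion-theory photon
transport, 3-D fruit geometry and specular reflection, spatially
correlated surface texture, and biological variability beyond the mild
parameter jitter above. Passing phantom suites therefore demonstrates
that the chain is implemented correctly and behaves as designed under its
own model of the data — not field performance on real fruit.

## Phantom study results

On seeded cohorts of 50 normal / 100 bruised phantoms at (0.10, 700),
the default pipeline (calibrate → demodulate → mask → RT → 10×10 masked
median → improved Otsu → min-area 50 → classify) reaches 95–98% total
accuracy across seeds: bruised recall is 100% and normal-class accuracy
86–93%, the errors being large pits whose post-median cores just clear
the min-area floor — the same normal-class error mode the technique shows
on real fruit. On bruise-free phantoms with pits, improved Otsu on RT
produces far fewer false bruise calls than plain Otsu on the equalized AC
image, whose mid-histogram split latches onto the vignetted rim.
`scripts/acceptance.py` recomputes these numbers; problem sizes there
(300-sample studies, 100-phantom noise suites, 12-point contrast grids)
are the package's standard desk-scale study sizes.

## Known limitations

* The even 10×10 median window is an unusual convention; the anchor
  choice above is arbitrary by half a pixel (a 9×9 window avoids it).
* Whether thresholds should be computed on 8-bit or rescaled-float images
  is a convention; this package quantizes to 256 levels after min-max
  rescaling and documents every rounding rule.
* The order of histogram equalization relative to the ratio image is not
  fixed by the method; the default feeds raw demodulated AC into RT, with
  `rt_from_equalized` available.
* Phantom optical parameters are self-consistent defaults, not calibrated
  to any real fruit tissue.
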