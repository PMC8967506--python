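# echoseg

Endocardial (chamber-boundary) segmentation for B-mode cardiac ultrasound.
In a B-mode echocardiogram the blood-filled chamber cavity is dark and the
surrounding myocardium bright, but speckle noise and the fan-shaped imaging
sector make the boundary hard to delineate. `echoseg` implements a classic
two-stage approach, aimed at researchers prototyping chamber-quantification
pipelines:

1. **Maximum-entropy (Kapur) thresholding.** With 256-bin histogram counts
   g(i) renormalized within each class, the gray level t* maximizes

   D(t) = H₁(t) + H₂(t),  Hc = −Σᵢ kᵢ ln kᵢ,  kᵢ = g(i) / Σ_class g(j),

   where class 1 is [0, t] and class 2 is [t+1, 255]. An exponentially
   smoothed histogram Y(a) = (1−β)·Y(a−1) + β·H(a) is available for robust
   peak location.

2. **Level-set refinement.** The thresholded cavity mask is embedded as a
   signed-distance function φ (negative inside) and its zero level set
   evolved by φₜ = −F·|∇φ| with outward normal speed F = β − w·κ,
   κ = div(∇φ/|∇φ|): a constant term β and a curvature term w that smooths
   the speckle-ragged boundary (a circle shrinks as r(t) = √(r₀² − 2wt)
   under pure curvature flow). First-order upwind differences, explicit
   Euler under the CFL bound dt ≤ 0.45/(|β| + 4w), narrow-band updates and
   periodic exact signed-distance reinitialization.

The final mask yields the chamber readout (area, mean gray value,
equivalent diameter) offered as a basis for clinical judgment.

Because no public dataset accompanies this class of method, the package
ships a seeded **speckle phantom generator**: a dark elliptical cavity in
bright myocardium inside a 75° imaging sector, corrupted by unit-mean
multiplicative gamma speckle and PSF blur, with the exact cavity ellipse as
ground truth.

## Worked example

```sh
python examples/03_segment_phantom.py
```

prints (exactly reproducible — everything is seeded):

```
threshold used:        158
level-set iterations:  45 (converged=False)
Dice vs ground truth:  0.9665
chamber area:          1026 px
chamber mean gray:     31.22 (configured cavity mean 30)
equivalent diameter:   36.14 px
```

The maximum-entropy threshold (158) falls between the configured cavity
(30) and myocardium (180) means; the refined mask overlaps the generating
ellipse with Dice 0.97 and recovers the blood-pool intensity to ~1 gray
level. `examples/01_threshold_histogram.py` and
`examples/02_levelset_circle_flows.py` demonstrate the thresholding and the
level-set solver (validated against analytic shrinking/growing circles)
in isolation.

The same pipeline is available from the shell:

```sh
echoseg phantom -n 1 --seed 7 --out ph
echoseg segment ph/phantom_000.png --roi ph/phantom_000_sector.png --out seg
echoseg evaluate seg/cavity_mask.png ph/phantom_000_mask.png
```

Exit codes: 0 success, 2 bad input, 3 no chamber found. Pipeline and
phantom parameters can be overridden with `--config <yaml>`; the keys are
the fields of `PipelineConfig` and `PhantomConfig` (see
`docs/methods.md`).

## Limitations

The phantoms emulate contrast, speckle and sector geometry — not
anatomy-specific wall structure, shadowing, or temporal motion; see
`docs/methods.md` for what passing these checks does and does not imply
for clinical images.
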