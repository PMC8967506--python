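"""Full endocardial segmentation of a synthetic frame, scored against truth.

Generates a speckled phantom, runs the complete pipeline (Gaussian smooth,
maximum-entropy threshold, component selection, level-set refinement),
and reports the Dice overlap with the known cavity mask plus the chamber
gray-value readout a clinician would use.

The command-line equivalent is:
    echoseg phantom -n 1 --seed 7 --out ph
    echoseg segment ph/phantom_000.png --roi ph/phantom_000_sector.png --out seg
    echoseg evaluate seg/cavity_mask.png ph/phantom_000_mask.png
"""

from echoseg import (
    PhantomConfig,
    chamber_metrics,
    dice,
    generate_phantom,
    segment_endocardium,
)

sample = generate_phantom(PhantomConfig(seed=7))
result = segment_endocardium(sample.image, roi=sample.sector)
metrics = chamber_metrics(result, sample.image)

print(f"threshold used:        {result.threshold_used}")
print(f"level-set iterations:  {result.iterations} (converged={result.converged})")
print(f"Dice vs ground truth:  {dice(result.cavity_mask, sample.truth_mask):.4f}")
print(f"chamber area:          {metrics.area_px} px")
print(f"chamber mean gray:     {metrics.mean_gray:.2f} "
      f"(configured cavity mean {sample.config.cavity_mean:.0f})")
print(f"equivalent diameter:   {metrics.equivalent_diameter:.2f} px")
# Dice near 1 means the recovered cavity matches the generating ellipse;
# the chamber mean gray recovers the configured blood-pool intensity.
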