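"""Pixel-wise chemical imaging: project b through every seed pixel.

Each masked pixel's spectrum is preprocessed the same way the model was
trained, scored through the regression vector, binarised at the model
threshold, cleaned by area opening, and reduced to one call per seed by
the viable-pixel-fraction rule. Maps are written as PNGs.
"""

from pathlib import Path

from seedhsi import (EndmemberSpec, RunConfig, area_open, binarize,
                     calibrate_reflectance, median_filter3, predict_pixelwise,
                     render_outputs, render_scene, seed_decision,
                     segment_seeds, simulate_dataset)
from seedhsi.workflow import scenes_to_table, train_viability_model

config = RunConfig()
table = scenes_to_table(
    simulate_dataset(60, EndmemberSpec(), rng=4, seeds_per_scene=60), config)
model = train_viability_model(table, "mean_norm", max_lv=8, rng=5).model

cube, refs, truth = render_scene(9, EndmemberSpec(), rng=6)
cal = median_filter3(calibrate_reflectance(cube, refs))
regions, mask = segment_seeds(cal, config.seg_threshold, config.min_area)

image = binarize(predict_pixelwise(model, cal, mask), model.threshold)
cleaned = area_open(image.binary, config.min_area)
decisions = [seed_decision(cleaned, r, config.viable_fraction)
             for r in regions]

truth_labels = [s.label for s in truth.seeds]
print(f"{len(regions)} seeds imaged; decisions {decisions}")
print(f"truth                       {truth_labels}")
correct = sum(d == t for d, t in zip(decisions, truth_labels))
print(f"{correct}/{len(regions)} correct at threshold {model.threshold:.2f}")

out = Path("scratch/example_chemical_imaging")
paths = render_outputs(image, regions, decisions, out)
print("Wrote:", ", ".join(p.name for p in paths), f"-> {out}/")
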