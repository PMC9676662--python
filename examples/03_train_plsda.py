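"""Train the PLS-DA viability classifier with a shifted decision threshold.

The class code is 0 (nonviable) / 1 (viable); a PLS1 regression on the
preprocessed mean spectra gives a continuous score, cut at a threshold
shifted up from 0.5 until the accepted (predicted-viable) group is pure
on the calibration split. Both camera sides of a seed stay in the same
split; LV count comes from venetian-blind 10-fold CV.
"""

import numpy as np

from seedhsi import EndmemberSpec, RunConfig, simulate_dataset
from seedhsi.plsda import coefficient_peaks
from seedhsi.workflow import (preprocessing_comparison, scenes_to_table,
                              train_viability_model)

config = RunConfig()
table = scenes_to_table(
    simulate_dataset(80, EndmemberSpec(), rng=2, seeds_per_scene=40), config)
print(f"Spectra table: {len(table)} rows "
      f"(80 seeds/class x 2 sides), split 2:1 per class")

res = train_viability_model(table, "mean_norm", max_lv=10, rng=3)
print(f"\nSelected {res.model.n_lv} latent variables "
      f"(CV error curve: {np.round(res.cv_error, 3)})")
print(f"Threshold shifted to {res.model.threshold:.2f} "
      f"(purity target 1.0 on calibration scores)")
print(f"Calibration accuracy {100 * res.calibration.accuracy:.1f}%, "
      f"validation accuracy {100 * res.validation.accuracy:.1f}%, "
      f"validation Acc.v {100 * res.validation.acc_viable:.1f}%")

peaks = coefficient_peaks(res.model, table.grid.centers, 3)
print(f"Top |b| excursions at {np.sort(peaks).round(0)} nm — read against the "
      "1415 (C-H), 1475 (N-H) and 1605 (O-H) nm absorption bands; at larger "
      "sample sizes the peaks lock onto those bands")

print("\nPreprocessing comparison (Acc.v %, one model per method):")
print(preprocessing_comparison(table, max_lv=10, rng=3).to_string(index=False))
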