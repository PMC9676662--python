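"""Close the loop: germination rates, moisture and composition ANOVA.

After sorting, the accepted (predicted-viable) group should germinate
at a higher rate, hold more moisture, and show larger chromatographic
peak areas for carbohydrates and proteins. The emulated assay tables
are drawn from the same latent chemistry as the spectra, so these
checks exercise the whole chain.
"""

from seedhsi import (emit_assay_tables, germination_report,
                     group_difference_report, moisture_content)
from seedhsi.synth import sample_truth

truth = sample_truth(120, rng=10)          # 60 viable + 60 nonviable seeds
assay = emit_assay_tables(truth, rng=11)
assay["predicted"] = assay["label"]        # assume a perfect sorter here
assay["moisture_pct"] = moisture_content(assay["wet_weight_g"],
                                         assay["dry_weight_g"])

germ = germination_report(assay)
print(f"Germination: accepted lot {germ['viable_group_rate_pct']:.1f}% vs "
      f"rejected lot {germ['nonviable_group_rate_pct']:.1f}% "
      f"(whole batch {germ['overall_rate_pct']:.1f}%)")

for analyte in ("moisture_pct", "carbohydrate_area_pct", "protein_area_pct"):
    rep = group_difference_report(assay, analyte).iloc[0]
    print(f"{analyte:22s} viable {rep['viable_mean']:6.2f} +/- {rep['viable_sd']:.2f}"
          f"  nonviable {rep['nonviable_mean']:6.2f} +/- {rep['nonviable_sd']:.2f}"
          f"  F={rep['f_value']:.1f}  P={rep['p_value']:.2e}"
          f"  {'*' if rep['significant'] else 'n.s.'}")
print("\n'*' marks a significant viable-vs-nonviable difference at P <= 0.05.")
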