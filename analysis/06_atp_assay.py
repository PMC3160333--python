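"""Quantify ATP response: synthetic plate round trip + curated panels.

Converts the simulated luminescence plate back to zeptograms per cell
through its fitted standard curve, then reruns fold-change and
significance analysis on the curated alcohol and C1-compound panels.
"""

from pathlib import Path

import pandas as pd

from c1census import atp

OUT = Path(__file__).resolve().parent.parent / "results"

plate_frame = pd.read_csv(OUT / "atp_plate.tsv", sep="\t")
plate = atp.PlateSet(data=plate_frame, cells_in_well=6e6, well_volume_l=2e-5)
summary = atp.analyze_plate(plate)
summary.to_csv(OUT / "atp_plate_summary.tsv", sep="\t", index=False)
true = {"T": 48.0, "N": 16.0, "P": 160.0}
print("plate round trip (replicate SD 2 zg/cell):")
for _, row in summary.iterrows():
    print(f"  {row['label']}: {row['mean_zg_per_cell']:6.2f} zg/cell "
          f"(true {true[row['label']]:.0f})")

for name, loader in (("C1 compounds", atp.load_c1_assay),
                     ("alcohols", atp.load_alcohol_assay)):
    results = atp.build_assay_table(loader())
    atp.assay_table_frame(results).to_csv(
        OUT / f"atp_{name.split()[0].lower()}_results.tsv", sep="\t", index=False)
    print(f"\n{name} panel (pooled one-sided t, n=3, alpha=0.01):")
    for r in results:
        star = "*" if r.significant else " "
        print(f" {star} {r.compound:16} T {r.mean_T:5.0f}±{r.sd_T:.0f}  "
              f"N {r.mean_N:5.0f}±{r.sd_N:.0f}  "
              f"fold {r.fold_change_T_over_N:4.1f}")
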