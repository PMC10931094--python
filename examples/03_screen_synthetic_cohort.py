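"""End-to-end screen of a synthetic cohort with a planted harmful hotspot.

Generates a 400-patient MAF-style cohort in which 20 patients carry a
hotspot with hazard ratio 3, runs the full pipeline (TMB filter, hotspot
calling, the four tests), and prints the results table rows for the
planted gene.
"""

from hotspotsurv import (
    CohortSpec,
    PlantedHotspot,
    ScreenConfig,
    generate_cohort,
    screen_cohort,
    summary_table,
)
from hotspotsurv.maf_io import mutations_from_frame, survival_from_frame

spec = CohortSpec(
    n_patients=400,
    planted_hotspots=(
        PlantedHotspot("GENE1", 200, n_carriers=20, hazard_ratio=3.0),
        PlantedHotspot("GENE1", 400, n_carriers=8, hazard_ratio=1.0),
    ),
    seed=1,
)
maf, clinical, truth = generate_cohort(spec)
print(f"generated {len(maf)} mutation rows for {spec.n_patients} patients")

mutations = mutations_from_frame(maf)
survival = survival_from_frame(clinical)
config = ScreenConfig(seed=1, n_perm_per_stratum=1000, enum_limit=2000)
result = screen_cohort(mutations, survival, "SYN", config)

print(summary_table(result).to_string(index=False))
print("\nrows for the planted gene:")
for r in result.rows:
    if r.gene != "GENE1":
        continue
    label = f"{r.gene}-{r.position_x}" + (f" vs {r.position_y}" if r.position_y else "")
    hr = f"{r.hr:.2f}" if isinstance(r.hr, float) else str(r.hr)
    print(f"  {r.test:<10} {label:<18} n={r.n_with}/{r.n_without} "
          f"p_empirical={r.p_valorate:.4f} HR={hr} significant={r.significant}")

print("\nThe HR=3 hotspot at GENE1-200 should be significant vs All; the")
print("neutral HR=1 hotspot at GENE1-400 usually is not.  p_empirical is")
print("reproducible: rerunning with the same seed gives identical values.")
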