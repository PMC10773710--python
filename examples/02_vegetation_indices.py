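"""Compute the 17-index table for one flight date.

Builds plot reflectance for the silking stage (R1) of a simulated
campaign and evaluates all 17 chlorophyll-related vegetation indices.
CCCI is the campaign min-max rescaling of NDRE, so it always spans
[0, 1] over the flight's plots.
"""

from canopyspad import CampaignConfig, build_vi_table, generate_campaign

config = CampaignConfig(reps=1, seed=7, stages=("R1",))
profiles, reflectance, _ = generate_campaign(config)

table = build_vi_table(reflectance, "R1")
print(table[["NDVI", "NDRE", "CCCI", "MTCI", "CIred_edge"]].head(8).round(3))
print(f"\n{table.shape[0]} plots x {table.shape[1] - 1} indices; "
      f"CCCI range: {table['CCCI'].min():.2f}-{table['CCCI'].max():.2f}")
print("Higher NDRE/CCCI values indicate greener, higher-chlorophyll plots.")
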