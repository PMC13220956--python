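"""Score anatomic regions for senescence-marker enrichment.

Simulates a regions x genes FPKM matrix with one senescence-enriched
region and ranks all regions by the scale-flip-sum score: each gene
min-max scaled across regions, down-markers negated, contributions summed.
"""

from senescreen import gen_region_matrix, score_panels, score_regions, synthetic_marker_panel

panel = synthetic_marker_panel()
fpkm, truth = gen_region_matrix(6, panel, seed=3)

result = score_regions(fpkm, panel.region_up, panel.region_down)
print("region senescence scores (higher = more senescent profile):")
for region, score in result.scores.sort_values(ascending=False).items():
    mark = "  <- planted" if region == truth.true_region else ""
    print(f"  {region}: {score:8.2f}{mark}")

by_panel = score_panels(fpkm, [
    ("sasp", panel.sasp, set()),
    ("ecm", panel.ecm, set()),
])
print("\ntop region per accessory panel:")
for name, scores in by_panel.items():
    print(f"  {name}: {scores.top_region}")
# A positive score means the region expresses the up-markers and lacks the
# down-markers; the per-gene contributions are bounded in [-1, 1].
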