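"""Derive consensus senescence markers from simulated bulk datasets.

Simulates six senescent-vs-proliferating expression datasets with planted
markers, runs moderated differential expression on each, and derives the
consensus and "common" marker panels.
"""

from senescreen import (
    BulkPanelConfig,
    build_marker_panel,
    call_degs,
    fit_moderated,
    gen_bulk_panel,
)

# effect_consistency=6 plants the markers in every dataset, so the strict
# "FC < 0.5 in all datasets" common-down rule has qualifying genes
cfg = BulkPanelConfig(n_genes=600, n_true_up=30, n_true_down=30,
                      effect_consistency=6, seed=1)
datasets, truth = gen_bulk_panel(cfg)

tables = [call_degs(fit_moderated(ds.matrix, ds.groups)) for ds in datasets]
for ds, t in zip(datasets, tables):
    print(f"{ds.name}: {t.attrs['n_up']} up, {t.attrs['n_down']} down DEGs "
          "(adj p < .05, |log2FC| > 0.5)")

panel = build_marker_panel(tables)
up_hit = len(panel.consensus_up & truth.true_up_genes)
down_hit = len(panel.consensus_down & truth.true_down_genes)
print(f"\nconsensus: {len(panel.consensus_up)} up / {len(panel.consensus_down)} down markers")
print(f"planted markers recovered: {up_hit}/30 up, {down_hit}/30 down")
print(f"common (caller) panel: {panel.common_up}")
# The consensus sets are genes called in the same direction in >=3 of the 6
# datasets and never in the opposite direction; the short common panel keeps
# the most fold-change-consistent of them for single-cell scoring.
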