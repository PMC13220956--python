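"""Synthetic-data generators: determinism, planted structure, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senescreen import (
    BulkPanelConfig,
    CallerThresholds,
    SingleCellConfig,
    gen_bulk_panel,
    gen_paired_omics,
    gen_region_matrix,
    gen_single_cell,
    spearman_per_gene,
)
from senescreen.errors import ConfigurationError


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(n_genes=10, n_true_up=6, n_true_down=6), "n_true"),
            (dict(effect_consistency=7), "effect_consistency"),
            (dict(noise_sd=0.0), "noise_sd"),
            (dict(n_replicates_per_group=1), "n_replicates_per_group"),
        ],
    )
    def test_bulk_config_errors_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            BulkPanelConfig(**kwargs)

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(frac_senescent=1.2), "frac_senescent"),
            (dict(frac_senescent=0.6, frac_escaped=0.6), "frac_"),
            (dict(dropout_rate=1.0), "dropout_rate"),
            (dict(up_marker_boost=0.0), "up_marker_boost"),
        ],
    )
    def test_sc_config_errors_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            SingleCellConfig(**kwargs)

    def test_region_requires_two_regions(self, panel):
        with pytest.raises(ConfigurationError, match="n_regions"):
            gen_region_matrix(1, panel, seed=0)

    def test_paired_rejects_rho_out_of_range(self):
        with pytest.raises(ConfigurationError, match="rho"):
            gen_paired_omics(10, 20, {"s": 1.0}, seed=0)


class TestDeterminism:
    def test_bulk_bit_identical(self):
        cfg = BulkPanelConfig(n_genes=100, n_true_up=5, n_true_down=5, seed=9)
        a, ta = gen_bulk_panel(cfg)
        b, tb = gen_bulk_panel(cfg)
        for da, db in zip(a, b):
            pd.testing.assert_frame_equal(da.matrix, db.matrix)
        assert ta.true_up_genes == tb.true_up_genes

    def test_single_cell_bit_identical(self, panel):
        cfg = SingleCellConfig(n_cells=300, n_genes=200, seed=9)
        (ca, la, ta) = gen_single_cell(cfg, panel)
        (cb, lb, tb) = gen_single_cell(cfg, panel)
        pd.testing.assert_frame_equal(ca, cb)
        pd.testing.assert_series_equal(la, lb)
        assert ta.senescent_cell_ids == tb.senescent_cell_ids

    def test_region_and_paired_bit_identical(self, panel):
        fa, _ = gen_region_matrix(4, panel, seed=5)
        fb, _ = gen_region_matrix(4, panel, seed=5)
        pd.testing.assert_frame_equal(fa, fb)
        ma, pa, _ = gen_paired_omics(20, 10, {"s": 0.5}, seed=5)
        mb, pb, _ = gen_paired_omics(20, 10, {"s": 0.5}, seed=5)
        pd.testing.assert_frame_equal(ma, mb)
        pd.testing.assert_frame_equal(pa, pb)


class TestBulkPanel:
    def test_planted_effect_recovered_by_sample_means(self):
        """Mean senescent-minus-proliferating difference on planted up genes
        matches the planted effect (sample-mean oracle)."""
        cfg = BulkPanelConfig(
            n_genes=300, n_true_up=30, n_true_down=30,
            effect_log2fc=2.0, noise_sd=0.5, n_replicates_per_group=4,
            effect_consistency=6, seed=21,
        )
        datasets, truth = gen_bulk_panel(cfg)
        diffs = []
        for ds in datasets:
            g = np.array(ds.groups)
            sen = ds.matrix.loc[sorted(truth.true_up_genes), g == "senescent"]
            pro = ds.matrix.loc[sorted(truth.true_up_genes), g == "proliferating"]
            diffs.append((sen.mean(axis=1) - pro.mean(axis=1)).mean())
        assert 1.8 <= np.mean(diffs) <= 2.2

    def test_effect_limited_to_consistency_datasets(self):
        cfg = BulkPanelConfig(n_genes=100, n_true_up=10, n_true_down=0,
                              effect_consistency=2, seed=3)
        datasets, truth = gen_bulk_panel(cfg)
        assert all(len(v) == 2 for v in truth.effect_datasets.values())

    def test_replicate_counts_can_vary(self):
        cfg = BulkPanelConfig(n_genes=50, n_true_up=2, n_true_down=2,
                              n_replicates_per_group=(2, 2, 3, 3, 4, 5), seed=0)
        datasets, _ = gen_bulk_panel(cfg)
        assert [d.matrix.shape[1] for d in datasets] == [4, 4, 6, 6, 8, 10]


class TestSingleCell:
    def test_counts_are_nonnegative_integers(self, panel):
        counts, _, _ = gen_single_cell(SingleCellConfig(n_cells=200, n_genes=200, seed=1), panel)
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)

    def test_zero_fraction_means_no_planted_cells(self, panel):
        cfg = SingleCellConfig(n_cells=200, n_genes=200, frac_senescent=0.0,
                               frac_escaped=0.0, seed=1)
        _, _, truth = gen_single_cell(cfg, panel)
        assert truth.senescent_cell_ids == set()
        assert truth.escaped_cell_ids == set()

    def test_planted_count_matches_rounded_fraction(self, panel):
        cfg = SingleCellConfig(n_cells=5000, n_genes=200, frac_senescent=0.025, seed=1)
        _, _, truth = gen_single_cell(cfg, panel)
        assert len(truth.senescent_cell_ids) == round(0.025 * 5000)

    def test_planted_cells_pass_independent_brute_force_filter(self, panel):
        """Re-check every planted senescent cell with four independently
        written filters at the default caller thresholds."""
        cfg = SingleCellConfig(n_cells=600, n_genes=250, seed=7)
        counts, _, truth = gen_single_cell(cfg, panel)
        thr = CallerThresholds()
        sasp_tot = counts[sorted(panel.sasp)].sum(axis=1)
        ecm_tot = counts[sorted(panel.ecm)].sum(axis=1)
        sasp_cut = np.quantile(sasp_tot, 1 - thr.top_quantile, method="higher")
        ecm_cut = np.quantile(ecm_tot, 1 - thr.top_quantile, method="higher")
        for cell in truth.senescent_cell_ids:
            row = counts.loc[cell]
            assert row[panel.common_up].sum() > thr.up_sum_min
            assert row[panel.common_down].sum() == 0
            assert sasp_tot[cell] >= sasp_cut
            assert ecm_tot[cell] >= ecm_cut
            assert (row[sorted(panel.cdki)] > 0).sum() >= thr.min_cdki_expressed

    def test_planted_escaped_cells_have_escape_profile(self, panel):
        cfg = SingleCellConfig(n_cells=600, n_genes=250, frac_escaped=0.1, seed=8)
        counts, _, truth = gen_single_cell(cfg, panel)
        esc = counts.loc[sorted(truth.escaped_cell_ids)]
        assert (esc["CDKN1A"] > 0).all()
        assert (esc["MKI67"] > 0).all()
        assert (esc["PCNA"] > 0).all()
        assert (esc[sorted(panel.mcm)] > 0).any(axis=1).all()
        # escaped cells keep down markers on, so the strict caller rejects them
        assert (esc[panel.common_down].sum(axis=1) > 0).all()

    def test_empty_panel_set_rejected(self, panel):
        import dataclasses

        broken = dataclasses.replace(panel, sasp=set())
        with pytest.raises(ConfigurationError, match="sasp"):
            gen_single_cell(SingleCellConfig(n_cells=50, n_genes=200, seed=0), broken)


class TestRegionMatrix:
    def test_true_region_has_highest_score_by_construction(self, panel):
        from senescreen import score_regions

        for seed in range(5):
            fpkm, truth = gen_region_matrix(5, panel, seed=seed)
            result = score_regions(fpkm, panel.region_up, panel.region_down)
            assert result.top_region == truth.true_region

    def test_zero_effect_zero_noise_gives_equal_scores(self, panel):
        from senescreen import score_regions

        fpkm, _ = gen_region_matrix(4, panel, seed=0, up_boost=1.0,
                                    down_factor=1.0, noise_sd=0.0)
        result = score_regions(fpkm, panel.region_up, panel.region_down)
        assert np.allclose(result.scores, result.scores.iloc[0])


class TestPairedOmics:
    def test_null_rho_estimates_center_on_zero(self):
        mrna, protein, _ = gen_paired_omics(150, 99, {"null": 0.0}, seed=13)
        per_gene = spearman_per_gene(mrna, protein)
        assert abs(per_gene["rho"].mean()) < 0.05

    def test_high_rho_mostly_significant(self):
        mrna, protein, _ = gen_paired_omics(100, 99, {"hi": 0.99}, seed=14)
        per_gene = spearman_per_gene(mrna, protein)
        assert (per_gene["p"] < 0.05).mean() >= 0.95

    def test_spearman_target_recovered_within_tolerance(self):
        """Monte-Carlo oracle: mean estimated rho per set tracks the target."""
        targets = {"a": 0.6, "b": 0.2}
        mrna, protein, truth = gen_paired_omics(300, 99, targets, seed=15)
        per_gene = spearman_per_gene(mrna, protein).set_index("gene")
        for name, rho in targets.items():
            genes = sorted(truth.gene_sets[name])
            assert per_gene.loc[genes, "rho"].mean() == pytest.approx(rho, abs=0.05)

    def test_tiny_sample_size_is_legal(self):
        mrna, protein, _ = gen_paired_omics(20, 3, {"s": 0.5}, seed=16)
        assert mrna.shape == (20, 3)
        with pytest.warns(UserWarning, match="skipped"):
            per_gene = spearman_per_gene(mrna, protein, min_pairs=4)
        assert per_gene.empty
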