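"""Single-cell senescence caller: oracles, properties, escape detection."""

import numpy as np
import pandas as pd
import pytest

from senescreen import (
    CallerThresholds,
    MarkerPanel,
    compare_expression,
    detect_escape,
    score_cells,
    summarize_clusters,
)
from senescreen.errors import ConfigurationError, InputError


def _tiny_panel():
    return MarkerPanel(
        common_up=["UP1", "UP2"],
        common_down=["DN1", "DN2"],
        consensus_up={"UP1", "UP2"},
        consensus_down={"DN1", "DN2"},
        sasp={"SASP1", "SASP2"},
        ecm={"ECM1", "ECM2"},
    )


def _toy_matrix(n_cells=20, seed=0):
    rng = np.random.default_rng(seed)
    genes = ["UP1", "UP2", "DN1", "DN2", "SASP1", "SASP2", "ECM1", "ECM2",
             "CDKN1A", "MKI67", "PCNA", "MCM2", "OTHER"]
    counts = rng.integers(0, 30, (n_cells, len(genes)))
    m = pd.DataFrame(counts, index=[f"c{i}" for i in range(n_cells)], columns=genes)
    # plant 3 unambiguous senescent cells
    for c in ("c0", "c1", "c2"):
        m.loc[c, ["UP1", "UP2"]] = 600
        m.loc[c, ["DN1", "DN2"]] = 0
        m.loc[c, ["SASP1", "SASP2", "ECM1", "ECM2"]] = 500
        m.loc[c, "CDKN1A"] = 3
        m.loc[c, ["MKI67", "PCNA", "MCM2"]] = 0
    return m


def _brute_force_calls(m, panel, thr):
    """Independent reimplementation: four filters applied cell by cell."""
    sasp_tot = m[sorted(panel.sasp)].sum(axis=1)
    ecm_tot = m[sorted(panel.ecm)].sum(axis=1)
    sasp_cut = np.quantile(sasp_tot, 1 - thr.top_quantile, method="higher")
    ecm_cut = np.quantile(ecm_tot, 1 - thr.top_quantile, method="higher")
    called = set()
    for cell in m.index:
        row = m.loc[cell]
        ok = row[panel.common_up].sum() > thr.up_sum_min
        ok &= row[panel.common_down].sum() <= thr.down_tolerance
        ok &= sasp_tot[cell] >= sasp_cut
        ok &= ecm_tot[cell] >= ecm_cut
        ok &= (row[sorted(set(panel.cdki) & set(m.columns))] > 0).sum() >= thr.min_cdki_expressed
        if ok:
            called.add(cell)
    return called


class TestScoreCells:
    def test_matches_filter_intersection_oracle(self):
        m = _toy_matrix()
        panel = _tiny_panel()
        thr = CallerThresholds()
        calls = score_cells(m, panel, thr)
        assert set(calls.index[calls["senescent"]]) == _brute_force_calls(m, panel, thr)
        assert {"c0", "c1", "c2"} <= set(calls.index[calls["senescent"]])

    def test_single_down_marker_count_vetoes(self):
        m = _toy_matrix()
        m.loc["c0", "DN1"] = 1
        calls = score_cells(m, _tiny_panel(), CallerThresholds())
        assert not calls.loc["c0", "senescent"]

    def test_combined_call_is_conjunction_of_criteria(self):
        m = _toy_matrix(seed=2)
        calls = score_cells(m, _tiny_panel(), CallerThresholds())
        thr = CallerThresholds()
        expected = (
            (calls["c1_up_sum"] > thr.up_sum_min)
            & calls["c2_down_absent"]
            & calls["c3_sasp_top"]
            & calls["c4_ecm_top"]
            & calls["c5_cdki"]
        )
        assert (calls["senescent"] == expected).all()

    def test_top_quantile_counts_consistent(self):
        """About top_quantile * n cells pass c3/c4 (ties all included)."""
        rng = np.random.default_rng(3)
        n = 400
        genes = _toy_matrix().columns
        m = pd.DataFrame(rng.random((n, len(genes))) * 100,
                         index=[f"c{i}" for i in range(n)], columns=genes)
        thr = CallerThresholds(top_quantile=0.15)
        calls = score_cells(m, _tiny_panel(), thr)
        # continuous values: no ties, expect ceil within one of the nominal count
        assert abs(int(calls["c3_sasp_top"].sum()) - int(np.ceil(0.15 * n))) <= 1
        assert abs(int(calls["c4_ecm_top"].sum()) - int(np.ceil(0.15 * n))) <= 1

    def test_raising_up_threshold_never_adds_calls(self):
        m = _toy_matrix(seed=4)
        panel = _tiny_panel()
        counts = [
            int(score_cells(m, panel, CallerThresholds(up_sum_min=v))["senescent"].sum())
            for v in (100, 500, 1000, 2000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_panel_gene_in_matrix_is_fatal(self):
        m = _toy_matrix().drop(columns=["SASP1", "SASP2"])
        with pytest.raises(InputError, match="sasp"):
            score_cells(m, _tiny_panel(), CallerThresholds())

    def test_empty_matrix_rejected(self):
        with pytest.raises(InputError, match="empty"):
            score_cells(pd.DataFrame(), _tiny_panel(), CallerThresholds())

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ConfigurationError, match="top_quantile"):
            CallerThresholds(top_quantile=1.5)


class TestSummarizeClusters:
    def test_single_cluster_gets_all(self):
        m = _toy_matrix()
        clusters = pd.Series("A", index=m.index)
        calls = score_cells(m, _tiny_panel(), CallerThresholds(), clusters)
        comp = summarize_clusters(calls)
        assert comp.to_dict() == {"A": 1.0}

    def test_empty_call_set_warns_and_returns_empty(self):
        m = _toy_matrix()
        clusters = pd.Series("A", index=m.index)
        calls = score_cells(m, _tiny_panel(), CallerThresholds(up_sum_min=1e9), clusters)
        with pytest.warns(UserWarning, match="no senescent"):
            comp = summarize_clusters(calls)
        assert comp.empty

    def test_planted_composition_recovered(self):
        """A planted 30/30/40 split across clusters is recovered within
        3 points (multinomial sampling oracle)."""
        rng = np.random.default_rng(6)
        n = 1000
        calls = pd.DataFrame(
            {
                "senescent": True,
                "cluster": rng.choice(["A", "B", "C"], size=n, p=[0.3, 0.3, 0.4]),
            },
            index=[f"c{i}" for i in range(n)],
        )
        comp = summarize_clusters(calls)
        assert comp.sum() == pytest.approx(1.0)
        for name, frac in (("A", 0.3), ("B", 0.3), ("C", 0.4)):
            assert comp[name] == pytest.approx(frac, abs=0.03)


class TestDetectEscape:
    def test_manual_count_oracle_on_hand_matrix(self):
        """10 cells counted by hand.  The top-40% SASP cut (10 cells,
        'higher' interpolation) falls at total 70, so the base set (p21+
        and top SASP) is {c0, c1, c2}; 2 of them are MKI67+, of which 1 is
        PCNA+ and both are MCM+."""
        genes = ["CDKN1A", "MKI67", "PCNA", "MCM2", "SASP1", "UP1", "DN1", "ECM1"]
        rows = [
            # p21 ki67 pcna mcm sasp
            [1, 1, 1, 1, 90, 0, 0, 0],   # base, escape, PCNA+, MCM+
            [1, 1, 0, 1, 80, 0, 0, 0],   # base, escape, MCM+
            [1, 0, 1, 0, 70, 0, 0, 0],   # base, not escape
            [1, 0, 0, 0, 60, 0, 0, 0],   # base, not escape
            [0, 1, 1, 1, 95, 0, 0, 0],   # high SASP but p21- -> not base
            [1, 1, 1, 1, 5, 0, 0, 0],    # p21+ but low SASP -> not base
            [0, 0, 0, 0, 4, 0, 0, 0],
            [0, 0, 0, 0, 3, 0, 0, 0],
            [0, 0, 0, 0, 2, 0, 0, 0],
            [0, 0, 0, 0, 1, 0, 0, 0],
        ]
        m = pd.DataFrame(rows, index=[f"c{i}" for i in range(10)], columns=genes)
        panel = MarkerPanel(common_up=["UP1"], common_down=["DN1"],
                            sasp={"SASP1"}, ecm={"ECM1"})
        # top 40% of 10 cells by SASP = 4 cells (ranks 90, 95, 80, 70)
        thr = CallerThresholds(top_quantile=0.4)
        report = detect_escape(m, panel, thr)
        assert set(report.base_cell_ids) == {"c0", "c1", "c2"}
        assert set(report.escape_cell_ids) == {"c0", "c1"}
        assert report.frac_of_p21_sasp_cells_expressing_mki67 == pytest.approx(2 / 3)
        assert report.frac_escape_expressing_pcna == pytest.approx(0.5)
        assert report.frac_escape_expressing_mcm == pytest.approx(1.0)

    def test_no_mki67_in_base_gives_zero_escape_fraction(self):
        m = _toy_matrix()
        m["MKI67"] = 0
        report = detect_escape(m, _tiny_panel(), CallerThresholds())
        assert report.escape_cell_ids == []
        assert report.frac_of_p21_sasp_cells_expressing_mki67 == 0.0

    def test_empty_base_set_flagged_undefined(self):
        m = _toy_matrix()
        m["CDKN1A"] = 0
        with pytest.warns(UserWarning, match="undefined"):
            report = detect_escape(m, _tiny_panel(), CallerThresholds())
        assert report.undefined
        assert np.isnan(report.frac_of_p21_sasp_cells_expressing_mki67)

    def test_recovers_planted_escape_population(self, panel):
        from senescreen import SingleCellConfig, gen_single_cell

        cfg = SingleCellConfig(n_cells=1000, n_genes=250, frac_escaped=0.1, seed=11)
        counts, clusters, truth = gen_single_cell(cfg, panel)
        report = detect_escape(counts, panel, CallerThresholds(), clusters)
        recovered = set(map(str, report.escape_cell_ids)) & truth.escaped_cell_ids
        assert len(recovered) >= 0.95 * len(truth.escaped_cell_ids)
        assert abs(sum(report.cluster_composition.values()) - 1.0) < 1e-9


class TestCompareExpression:
    def test_u_statistic_matches_rank_count_oracle(self):
        m = _toy_matrix()
        calls = score_cells(m, _tiny_panel(), CallerThresholds())
        u, p = compare_expression(m, calls, "OTHER")
        sen = calls["senescent"].to_numpy()
        x = m.loc[sen, "OTHER"].to_numpy()
        y = m.loc[~sen, "OTHER"].to_numpy()
        u_oracle = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        assert u == pytest.approx(u_oracle)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(8)
        m = _toy_matrix(n_cells=40, seed=8)
        calls = score_cells(m, _tiny_panel(), CallerThresholds(up_sum_min=1))
        # force 20/20 split independent of the caller for a clean comparison
        calls["senescent"] = [True] * 20 + [False] * 20
        m["OTHER"] = np.r_[rng.normal(100, 1, 20), rng.normal(0, 1, 20)]
        _, p = compare_expression(m, calls, "OTHER")
        assert p < 1e-4

    def test_empty_group_rejected(self):
        m = _toy_matrix()
        calls = score_cells(m, _tiny_panel(), CallerThresholds(up_sum_min=1e9))
        with pytest.raises(InputError, match="non-empty"):
            compare_expression(m, calls, "OTHER")
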