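"""Stage orchestration: each pipeline stage as a disk-to-disk operation.

Stages read their inputs from ``AnalysisConfig.inputs`` (logical name ->
path), write their outputs under ``config.outdir`` and return the mapping
of produced artifacts.  ``run_all`` chains every stage on a fully
synthetic study, threading the global seed through all generators, and
writes a run record with per-stage timings.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import concordance as conc
from . import io as sio
from .config import AnalysisConfig
from .consensus import build_marker_panel
from .diffexpr import call_degs, fit_moderated
from .errors import ConfigurationError
from .ligrec import LRPair, count_significant, permutation_test
from .regions import score_regions
from .reporting import RunRecord, export_spia_input
from .sc_calls import detect_escape, score_cells, summarize_clusters
from .simulate import (
    BulkPanelConfig,
    SingleCellConfig,
    gen_bulk_panel,
    gen_paired_omics,
    gen_region_matrix,
    gen_single_cell,
    synthetic_marker_panel,
)

__all__ = ["STAGES", "run_stage", "run_all"]

logger = logging.getLogger("senescreen")

STAGES = (
    "simulate",
    "de",
    "consensus",
    "sc-call",
    "region-score",
    "ligrec",
    "concordance",
    "overlap",
    "report",
)


def _outdir(cfg: AnalysisConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _stage_simulate(cfg: AnalysisConfig) -> dict[str, str]:
    """Generate every synthetic input and register it in ``cfg.inputs``."""
    out = _outdir(cfg) / "sim"
    out.mkdir(exist_ok=True)
    seed = cfg.seed

    sim = cfg.simulate or {}
    bulk_cfg = BulkPanelConfig(seed=seed, **sim.get("bulk", {}))
    datasets, bulk_truth = gen_bulk_panel(bulk_cfg)
    bulk_paths = []
    for ds in datasets:
        mpath, lpath = out / f"bulk_{ds.name}.tsv", out / f"bulk_{ds.name}.labels.tsv"
        sio.write_matrix_tsv(ds.matrix, mpath)
        sio.write_labels_tsv(
            pd.Series(ds.groups, index=ds.matrix.columns, name="group"), lpath, id_name="sample"
        )
        bulk_paths.append(str(mpath))

    # Protein-level differential table: one dataset drawn from the same
    # seed, so its planted genes coincide with the bulk panel's.
    prot_cfg = dataclasses.replace(bulk_cfg, n_datasets=1, n_replicates_per_group=3,
                                   effect_consistency=1)
    (prot_ds,), _ = gen_bulk_panel(prot_cfg)
    sio.write_matrix_tsv(prot_ds.matrix, out / "proteome.tsv")
    sio.write_labels_tsv(
        pd.Series(prot_ds.groups, index=prot_ds.matrix.columns, name="group"),
        out / "proteome.labels.tsv",
        id_name="sample",
    )

    panel = synthetic_marker_panel()
    sio.panel_to_gmt(panel, out / "panel.gmt")

    sc_cfg = SingleCellConfig(seed=seed + 1, **sim.get("single_cell", {}))
    counts, clusters, sc_truth = gen_single_cell(sc_cfg, panel)
    sio.write_mtx_triplet(counts, out / "sc")
    sio.write_labels_tsv(clusters, out / "sc_clusters.tsv", id_name="cell")

    fpkm, region_truth = gen_region_matrix(sim.get("n_regions", 6), panel, seed + 2)
    sio.write_matrix_tsv(fpkm, out / "regions.tsv", index_label="region")

    paired = {"n_genes": 300, "n_samples": 99, **sim.get("paired", {})}
    mrna, protein, omics_truth = gen_paired_omics(
        paired["n_genes"], paired["n_samples"], {"markers": 0.6, "background": 0.2}, seed + 3
    )
    sio.write_matrix_tsv(mrna, out / "mrna.tsv")
    sio.write_matrix_tsv(protein, out / "protein.tsv")

    sasp_sorted, ecm_sorted = sorted(panel.sasp), sorted(panel.ecm)
    pairs = [LRPair(lig, (rec,)) for lig, rec in zip(sasp_sorted[:10], ecm_sorted[:10])]
    sio.write_lr_pairs(pairs, out / "lr_pairs.tsv")

    sio.write_json(
        {
            "true_up_genes": bulk_truth.true_up_genes,
            "true_down_genes": bulk_truth.true_down_genes,
            "senescent_cell_ids": sc_truth.senescent_cell_ids,
            "escaped_cell_ids": sc_truth.escaped_cell_ids,
            "true_region": region_truth.true_region,
            "true_rho_per_gene": omics_truth.true_rho_per_gene,
        },
        out / "ground_truth.json",
    )

    produced = {
        "bulk_matrices": bulk_paths,
        "panel_gmt": str(out / "panel.gmt"),
        "sc_dir": str(out / "sc"),
        "sc_clusters": str(out / "sc_clusters.tsv"),
        "region_matrix": str(out / "regions.tsv"),
        "mrna": str(out / "mrna.tsv"),
        "protein": str(out / "protein.tsv"),
        "proteome_matrix": str(out / "proteome.tsv"),
        "lr_pairs": str(out / "lr_pairs.tsv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    cfg.inputs.update(produced)
    return produced


def _de_one(cfg: AnalysisConfig, matrix_path: str, out_path: Path) -> None:
    matrix = sio.read_matrix_tsv(matrix_path)
    labels = sio.read_labels_tsv(str(matrix_path).replace(".tsv", ".labels.tsv"))
    groups = labels.reindex(matrix.columns)
    table = call_degs(fit_moderated(matrix, groups), cfg.deg)
    logger.info(
        "DE %s: %d up / %d down at adj p<%g, |log2FC|>%g",
        Path(matrix_path).name, table.attrs["n_up"], table.attrs["n_down"],
        cfg.deg.alpha, cfg.deg.lfc_cut,
    )
    sio.write_de_table(table, out_path)


def _stage_de(cfg: AnalysisConfig) -> dict[str, str]:
    out = _outdir(cfg) / "de"
    out.mkdir(exist_ok=True)
    paths = cfg.require_input("bulk_matrices")
    if isinstance(paths, str):
        paths = [paths]
    produced = {}
    for path in paths:
        name = Path(path).stem
        de_path = out / f"{name}.de.tsv"
        _de_one(cfg, path, de_path)
        produced[name] = str(de_path)
    if "proteome_matrix" in cfg.inputs:
        de_path = out / "proteome.de.tsv"
        _de_one(cfg, cfg.inputs["proteome_matrix"], de_path)
        produced["proteome"] = str(de_path)
        cfg.inputs["proteome_de"] = str(de_path)
    cfg.inputs["de_tables"] = [v for k, v in produced.items() if k != "proteome"]
    return produced


def _stage_consensus(cfg: AnalysisConfig) -> dict[str, str]:
    out = _outdir(cfg)
    tables = [sio.read_de_table(p) for p in cfg.require_input("de_tables")]
    sasp = ecm = None
    if "panel_gmt" in cfg.inputs:
        ext = sio.panel_from_gmt(cfg.inputs["panel_gmt"])
        sasp, ecm = ext.sasp, ext.ecm
    panel = build_marker_panel(tables, cfg.consensus, sasp=sasp, ecm=ecm)
    logger.info(
        "consensus: %d up, %d down (min_datasets=%d); common %d up / %d down",
        len(panel.consensus_up), len(panel.consensus_down), cfg.consensus.min_datasets,
        len(panel.common_up), len(panel.common_down),
    )
    path = out / "consensus_panel.gmt"
    sio.panel_to_gmt(panel, path)
    cfg.inputs["consensus_panel"] = str(path)
    return {"consensus_panel": str(path)}


def _read_sc(cfg: AnalysisConfig) -> tuple[pd.DataFrame, pd.Series]:
    if "sc_dir" in cfg.inputs:
        counts = sio.read_mtx_triplet(cfg.inputs["sc_dir"])
    else:
        counts = sio.read_matrix_tsv(cfg.require_input("sc_matrix"))
    clusters = sio.read_labels_tsv(cfg.require_input("sc_clusters"))
    return counts, clusters


def _stage_sc_call(cfg: AnalysisConfig) -> dict[str, str]:
    out = _outdir(cfg) / "sc_call"
    out.mkdir(exist_ok=True)
    counts, clusters = _read_sc(cfg)
    panel = sio.panel_from_gmt(cfg.require_input("panel_gmt"))
    calls = score_cells(counts, panel, cfg.caller, clusters)
    logger.info(
        "sc-call: %d/%d senescent (up_sum>%g, down<=%g, top %g%% SASP/ECM, >=%d CDKi)",
        int(calls["senescent"].sum()), len(calls), cfg.caller.up_sum_min,
        cfg.caller.down_tolerance, 100 * cfg.caller.top_quantile,
        cfg.caller.min_cdki_expressed,
    )
    calls.to_csv(out / "calls.tsv", sep="\t", index_label="cell")
    comp = summarize_clusters(calls)
    comp.rename_axis("cluster").to_csv(out / "cluster_composition.tsv", sep="\t")
    escape = detect_escape(counts, panel, cfg.caller, clusters)
    sio.write_json(escape.to_dict(), out / "escape.json")
    return {
        "calls": str(out / "calls.tsv"),
        "cluster_composition": str(out / "cluster_composition.tsv"),
        "escape": str(out / "escape.json"),
    }


def _stage_region_score(cfg: AnalysisConfig) -> dict[str, str]:
    out = _outdir(cfg)
    fpkm = sio.read_matrix_tsv(cfg.require_input("region_matrix"))
    panel = sio.panel_from_gmt(cfg.require_input("panel_gmt"))
    up = panel.region_up or sorted(panel.consensus_up)
    down = panel.region_down or sorted(panel.consensus_down)
    result = score_regions(fpkm, up, down)
    logger.info("region-score: top region %s", result.top_region)
    ranked = result.scores.sort_values(ascending=False).rename("score")
    ranked.rename_axis("region").to_csv(out / "region_scores.tsv", sep="\t")
    return {"region_scores": str(out / "region_scores.tsv")}


def _stage_ligrec(cfg: AnalysisConfig) -> dict[str, str]:
    out = _outdir(cfg)
    counts, clusters = _read_sc(cfg)
    pairs = sio.read_lr_pairs(cfg.require_input("lr_pairs"))
    results = permutation_test(
        counts, clusters, pairs,
        n_perm=cfg.ligrec.n_perm, seed=cfg.seed,
        alpha=cfg.ligrec.alpha, min_cells=cfg.ligrec.min_cells,
    )
    logger.info(
        "ligrec: %d/%d interactions significant at p<%g (n_perm=%d)",
        int(results["significant"].sum()), len(results), cfg.ligrec.alpha, cfg.ligrec.n_perm,
    )
    results.to_csv(out / "ligrec_results.tsv", sep="\t", index=False)
    counts_mat = count_significant(results, cfg.ligrec.alpha)
    counts_mat.rename_axis("sender").to_csv(out / "ligrec_counts.tsv", sep="\t")
    return {
        "ligrec_results": str(out / "ligrec_results.tsv"),
        "ligrec_counts": str(out / "ligrec_counts.tsv"),
    }


def _stage_concordance(cfg: AnalysisConfig) -> dict[str, str]:
    out = _outdir(cfg)
    mrna = sio.read_matrix_tsv(cfg.require_input("mrna"))
    protein = sio.read_matrix_tsv(cfg.require_input("protein"))
    per_gene = conc.spearman_per_gene(mrna, protein, min_pairs=cfg.concordance.min_pairs)
    per_gene.to_csv(out / "spearman_per_gene.tsv", sep="\t", index=False)
    report: dict = {
        "fraction_significant": conc.fraction_significant(per_gene["p"], cfg.concordance.alpha)
    }
    truth_path = cfg.inputs.get("ground_truth")
    sets = {}
    if truth_path:
        rho_map = sio.read_json(truth_path).get("true_rho_per_gene", {})
        set_names = {g: g.rstrip("0123456789") for g in rho_map}
        for name in sorted(set(set_names.values())):
            sets[name] = {g for g, s in set_names.items() if s == name}
    if len(sets) >= 2:
        names = sorted(sets, key=lambda n: (n == "BACKGROUND", n))
        in_first = per_gene["gene"].isin(sets[names[0]])
        cmp = conc.compare_rho_sets(
            per_gene.loc[in_first, "rho"], per_gene.loc[~in_first, "rho"]
        )
        report["set_comparison"] = {
            "set": names[0],
            "median_set": cmp.median_set,
            "median_background": cmp.median_background,
            "p": cmp.p,
        }
    logger.info("concordance: %.1f%% of genes significant at p<%g",
                100 * report["fraction_significant"], cfg.concordance.alpha)
    sio.write_json(report, out / "concordance.json")
    return {"concordance": str(out / "concordance.json")}


def _stage_overlap(cfg: AnalysisConfig) -> dict[str, str]:
    out = _outdir(cfg)
    protein_de = sio.read_de_table(cfg.require_input("proteome_de"))
    panel = sio.panel_from_gmt(cfg.require_input("consensus_panel"))
    sets = {
        "consensus_up": panel.consensus_up,
        "consensus_down": panel.consensus_down,
    }
    if panel.sasp:
        sets["sasp"] = panel.sasp
    if panel.ecm:
        sets["ecm"] = panel.ecm
    report = conc.proteome_marker_overlap(protein_de, sets)
    sio.write_json(report.to_dict(), out / "overlap.json")
    spia = export_spia_input(protein_de, cfg.deg)
    pd.Series(spia, name="log2fc").rename_axis("gene").to_csv(out / "spia_input.tsv", sep="\t")
    return {"overlap": str(out / "overlap.json"), "spia_input": str(out / "spia_input.tsv")}


def _stage_report(cfg: AnalysisConfig) -> dict[str, str]:
    out = _outdir(cfg)
    summary = {"outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())}
    sio.write_json(summary, out / "summary.json")
    return {"summary": str(out / "summary.json")}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "consensus": _stage_consensus,
    "sc-call": _stage_sc_call,
    "region-score": _stage_region_score,
    "ligrec": _stage_ligrec,
    "concordance": _stage_concordance,
    "overlap": _stage_overlap,
    "report": _stage_report,
}


def run_stage(name: str, cfg: AnalysisConfig, record: RunRecord | None = None) -> dict:
    """Run one named stage; returns the mapping of produced artifacts."""
    if name not in _STAGE_FUNCS:
        raise ConfigurationError(f"unknown stage {name!r}; choose from {STAGES}")
    if record is None:
        record = RunRecord(seed=cfg.seed, config=cfg.to_dict())
    with record.time_stage(name):
        produced = _STAGE_FUNCS[name](cfg)
    return produced


def run_all(cfg: AnalysisConfig) -> RunRecord:
    """Run the full synthetic pipeline end to end under one seed."""
    record = RunRecord(seed=cfg.seed, config=cfg.to_dict())
    for name in STAGES:
        logger.info("=== stage %s ===", name)
        run_stage(name, cfg, record)
    record.write(_outdir(cfg) / "run_record.json")
    return record
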