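"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the *statistical* structure the pipeline reads, not
tumor biology: multi-dataset log2-intensity bulk panels with
direction-consistent planted markers, a single-cell count matrix
(negative-binomial counts thinned by Bernoulli dropout) with a planted
senescent subpopulation and a planted senescence-escape subpopulation, a
region x gene FPKM matrix with one senescence-enriched region, and paired
mRNA/protein tables with controlled per-gene rank correlation.

Every generator takes an explicit seed and is bit-reproducible; planted
structure is enforced by construction so that downstream callers succeed
on planted cells/genes at their default thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import CDKI_GENES, MCM_GENES, MarkerPanel
from .errors import ConfigurationError
from .sc_calls import CallerThresholds

__all__ = [
    "BulkPanelConfig",
    "SingleCellConfig",
    "GroundTruth",
    "BulkDataset",
    "gen_bulk_panel",
    "gen_single_cell",
    "gen_region_matrix",
    "gen_paired_omics",
    "synthetic_marker_panel",
]

#: Replicate counts of the six senescent-vs-proliferating source datasets.
STUDY_REPLICATES = (2, 2, 3, 3, 4, 5)


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every synthetic dataset."""

    true_up_genes: set[str] = field(default_factory=set)
    true_down_genes: set[str] = field(default_factory=set)
    senescent_cell_ids: set[str] = field(default_factory=set)
    escaped_cell_ids: set[str] = field(default_factory=set)
    true_region: str | None = None
    true_rho_per_gene: dict[str, float] = field(default_factory=dict)
    gene_sets: dict[str, set[str]] = field(default_factory=dict)
    effect_datasets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_up_genes & self.true_down_genes:
            raise ConfigurationError("true up and down gene sets overlap")
        if self.senescent_cell_ids & self.escaped_cell_ids:
            raise ConfigurationError("senescent and escaped cell sets overlap")


@dataclass
class BulkDataset:
    """One synthetic bulk dataset: log2 intensities plus group labels."""

    name: str
    matrix: pd.DataFrame  # genes x samples, log2 intensity
    groups: list[str]  # per-sample: "proliferating" / "senescent"


@dataclass(frozen=True)
class BulkPanelConfig:
    """Configuration of the multi-dataset bulk panel generator.

    ``n_replicates_per_group`` may be a single integer or one per dataset
    (the source datasets ranged 2-5).  Each planted marker carries a
    ``±effect_log2fc`` shift of the senescent group mean in exactly
    ``effect_consistency`` randomly chosen datasets.
    """

    n_datasets: int = 6
    n_genes: int = 800
    n_true_up: int = 40
    n_true_down: int = 40
    n_replicates_per_group: int | tuple[int, ...] = 4
    effect_log2fc: float = 2.0
    effect_consistency: int = 4
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_up + self.n_true_down > self.n_genes:
            raise ConfigurationError(
                "n_true_up + n_true_down exceeds n_genes "
                f"({self.n_true_up}+{self.n_true_down} > {self.n_genes})"
            )
        if self.effect_consistency > self.n_datasets:
            raise ConfigurationError(
                f"effect_consistency ({self.effect_consistency}) exceeds "
                f"n_datasets ({self.n_datasets})"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        reps = self.replicates()
        if len(reps) != self.n_datasets or any(r < 2 for r in reps):
            raise ConfigurationError(
                "n_replicates_per_group must be >=2 and match n_datasets"
            )

    def replicates(self) -> tuple[int, ...]:
        if isinstance(self.n_replicates_per_group, int):
            return (self.n_replicates_per_group,) * self.n_datasets
        return tuple(self.n_replicates_per_group)


def gen_bulk_panel(cfg: BulkPanelConfig) -> tuple[list[BulkDataset], GroundTruth]:
    """Simulate senescent-vs-proliferating bulk panels with planted markers.

    Gaussian log2 intensities (microarray-like): per-gene baseline shared
    across datasets plus independent noise of ``noise_sd``.  Planted up
    (down) markers add ``+effect_log2fc`` (``-effect_log2fc``) to the
    senescent group in exactly ``effect_consistency`` datasets per gene.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    planted = rng.choice(cfg.n_genes, cfg.n_true_up + cfg.n_true_down, replace=False)
    up_idx = planted[: cfg.n_true_up]
    down_idx = planted[cfg.n_true_up :]
    baseline = rng.normal(cfg.baseline_mean, 1.5, size=cfg.n_genes)

    dataset_names = [f"DS{d + 1}" for d in range(cfg.n_datasets)]
    effect_sets: dict[str, tuple[str, ...]] = {}
    effect_in = np.zeros((cfg.n_genes, cfg.n_datasets), dtype=bool)
    for idx in planted:
        chosen = rng.choice(cfg.n_datasets, cfg.effect_consistency, replace=False)
        effect_in[idx, chosen] = True
        effect_sets[genes[idx]] = tuple(dataset_names[d] for d in sorted(chosen))

    sign = np.zeros(cfg.n_genes)
    sign[up_idx] = 1.0
    sign[down_idx] = -1.0

    datasets = []
    for d, (name, reps) in enumerate(zip(dataset_names, cfg.replicates())):
        n_samples = 2 * reps
        values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n_samples))
        shift = sign * effect_in[:, d] * cfg.effect_log2fc
        values[:, reps:] += shift[:, None]
        columns = [f"{name}_prolif_{i + 1}" for i in range(reps)] + [
            f"{name}_senescent_{i + 1}" for i in range(reps)
        ]
        datasets.append(
            BulkDataset(
                name=name,
                matrix=pd.DataFrame(values, index=genes, columns=columns),
                groups=["proliferating"] * reps + ["senescent"] * reps,
            )
        )
    truth = GroundTruth(
        true_up_genes={genes[i] for i in up_idx},
        true_down_genes={genes[i] for i in down_idx},
        effect_datasets=effect_sets,
    )
    return datasets, truth


def synthetic_marker_panel(
    n_sasp: int = 30, n_ecm: int = 30, n_consensus_extra: int = 20
) -> MarkerPanel:
    """A self-contained marker panel for driving the downstream generators.

    Common up/down markers and SASP/ECM members get synthetic symbols;
    CDKi, MCM and proliferation sets use the canonical human symbols the
    caller expects.  Useful for exercising the single-cell, region and
    communication stages without first running the bulk consensus stage.
    """
    common_up = [f"SENUP{i + 1:03d}" for i in range(8)]
    common_down = [f"SENDN{i + 1:03d}" for i in range(7)]
    extra_up = [f"SENUPX{i + 1:03d}" for i in range(n_consensus_extra)]
    extra_down = [f"SENDNX{i + 1:03d}" for i in range(n_consensus_extra)]
    sasp = {f"SASP{i + 1:03d}" for i in range(n_sasp)}
    ecm = {f"ECM{i + 1:03d}" for i in range(n_ecm)}
    consensus_up = set(common_up) | set(extra_up)
    consensus_down = set(common_down) | set(extra_down)
    return MarkerPanel(
        consensus_up=consensus_up,
        consensus_down=consensus_down,
        common_up=common_up,
        common_down=common_down,
        region_up=sorted(consensus_up),
        region_down=sorted(consensus_down),
        sasp=sasp,
        ecm=ecm,
        provenance={"source": "synthetic"},
    )


@dataclass(frozen=True)
class SingleCellConfig:
    """Configuration of the single-cell count-matrix generator.

    Counts are negative-binomial (dispersion ``nb_dispersion``) around
    per-gene means summing to ``library_size_mean`` per cell, thinned by
    Bernoulli dropout.  Planted senescent cells carry multiplicatively
    boosted up-marker / SASP / ECM expression, hard-zero down markers and
    proliferation genes, and guaranteed CDKi expression; planted escaped
    cells are CDKN1A+/high-SASP/MKI67+/PCNA+/MCM+ and keep down-marker
    expression so the strict caller rejects them.
    """

    n_cells: int = 5000
    n_genes: int = 1000
    n_clusters: int = 8
    frac_senescent: float = 0.025
    frac_escaped: float = 0.01
    library_size_mean: float = 5000.0
    dropout_rate: float = 0.3
    up_marker_boost: float = 60.0
    sasp_boost: float = 15.0
    ecm_boost: float = 15.0
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_senescent <= 1.0:
            raise ConfigurationError(f"frac_senescent must be in [0,1], got {self.frac_senescent}")
        if not 0.0 <= self.frac_escaped <= 1.0:
            raise ConfigurationError(f"frac_escaped must be in [0,1], got {self.frac_escaped}")
        if self.frac_senescent + self.frac_escaped > 1.0:
            raise ConfigurationError("frac_senescent + frac_escaped exceeds 1")
        if self.library_size_mean <= 0:
            raise ConfigurationError(f"library_size_mean must be > 0, got {self.library_size_mean}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")
        for name in ("up_marker_boost", "sasp_boost", "ecm_boost", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def _panel_gene_universe(cfg: SingleCellConfig, panel: MarkerPanel) -> list[str]:
    named: list[str] = []
    for group in (
        panel.common_up,
        panel.common_down,
        sorted(panel.sasp),
        sorted(panel.ecm),
        sorted(panel.cdki),
        sorted(panel.mcm),
        ["MKI67", "PCNA"],
    ):
        for g in group:
            if g not in named:
                named.append(g)
    if len(named) > cfg.n_genes:
        raise ConfigurationError(
            f"n_genes={cfg.n_genes} too small for the {len(named)} panel genes"
        )
    fillers = [f"FILLER{i + 1:05d}" for i in range(cfg.n_genes - len(named))]
    return named + fillers


def gen_single_cell(
    cfg: SingleCellConfig, panel: MarkerPanel
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a cells x genes count matrix with planted subpopulations.

    Returns ``(counts, cluster_labels, truth)``.  Planted senescent cells
    pass all four caller criteria at the default
    :class:`~senescreen.sc_calls.CallerThresholds` by construction,
    provided ``frac_senescent + frac_escaped <= top_quantile`` so the
    planted cells fit inside the top-SASP/ECM quantile.
    """
    for name in ("common_up", "common_down", "sasp", "ecm", "cdki"):
        if not getattr(panel, name):
            raise ConfigurationError(f"panel set {name!r} is empty")
    thr = CallerThresholds()
    rng = np.random.default_rng(cfg.seed)
    genes = _panel_gene_universe(cfg, panel)
    gi = {g: i for i, g in enumerate(genes)}
    cells = [f"CELL{i + 1:05d}" for i in range(cfg.n_cells)]

    n_sen = round(cfg.frac_senescent * cfg.n_cells)
    n_esc = round(cfg.frac_escaped * cfg.n_cells)
    chosen = rng.choice(cfg.n_cells, n_sen + n_esc, replace=False)
    sen_rows = np.sort(chosen[:n_sen])
    esc_rows = np.sort(chosen[n_sen:])

    up = [gi[g] for g in panel.common_up if g in gi]
    down = [gi[g] for g in panel.common_down]
    sasp = [gi[g] for g in sorted(panel.sasp)]
    ecm = [gi[g] for g in sorted(panel.ecm)]
    prolif = [gi[g] for g in sorted({"MKI67", "PCNA"} | set(panel.mcm)) if g in gi]
    p21 = gi["CDKN1A"] if "CDKN1A" in gi else gi[sorted(panel.cdki)[0]]

    # Per-gene base means normalized to the target library size.
    raw = rng.lognormal(0.0, 1.0, cfg.n_genes)
    mu_gene = raw / raw.sum() * cfg.library_size_mean
    cell_factor = rng.lognormal(0.0, 0.3, cfg.n_cells)
    mu = np.outer(cell_factor, mu_gene)

    mu[sen_rows[:, None], up] *= cfg.up_marker_boost
    mu[sen_rows[:, None], sasp] *= cfg.sasp_boost
    mu[sen_rows[:, None], ecm] *= cfg.ecm_boost
    mu[sen_rows[:, None], down] = 0.0
    mu[sen_rows[:, None], prolif] = 0.0
    mu[sen_rows, p21] = np.maximum(mu[sen_rows, p21], 5.0)
    if n_esc:
        mu[esc_rows[:, None], sasp] *= cfg.sasp_boost
        mu[esc_rows, p21] = np.maximum(mu[esc_rows, p21], 5.0)
        mu[esc_rows[:, None], prolif] *= 5.0

    r = cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    keep = rng.random(counts.shape) >= cfg.dropout_rate
    counts *= keep

    # Post-sampling enforcement of the planted guarantees (dropout and NB
    # noise must not break them).
    counts[sen_rows[:, None], down] = 0
    counts[sen_rows[:, None], prolif] = 0
    counts[sen_rows, p21] = np.maximum(counts[sen_rows, p21], 1)
    if n_esc:
        counts[esc_rows, p21] = np.maximum(counts[esc_rows, p21], 1)
        counts[esc_rows, gi["MKI67"]] = np.maximum(counts[esc_rows, gi["MKI67"]], 1)
        counts[esc_rows, gi["PCNA"]] = np.maximum(counts[esc_rows, gi["PCNA"]], 1)
        first_mcm = gi[sorted(panel.mcm)[0]]
        counts[esc_rows, first_mcm] = np.maximum(counts[esc_rows, first_mcm], 1)
        # Escaped cells keep proliferation-associated down markers on, so
        # the strict absence criterion rejects them.
        counts[esc_rows, down[0]] = np.maximum(counts[esc_rows, down[0]], 1)

    planted = np.concatenate([sen_rows, esc_rows]).astype(int)
    background = np.setdiff1d(np.arange(cfg.n_cells), planted)
    # Up-marker sum strictly above the caller threshold.
    if n_sen:
        up_sum = counts[sen_rows[:, None], up].sum(axis=1)
        deficit = np.maximum(0, int(thr.up_sum_min) + 1 - up_sum)
        counts[sen_rows, up[0]] += deficit
    # SASP totals of every planted cell strictly above the background max.
    if planted.size and background.size:
        sasp_bg_max = counts[background[:, None], sasp].sum(axis=1).max()
        sasp_tot = counts[planted[:, None], sasp].sum(axis=1)
        counts[planted, sasp[0]] += np.maximum(0, sasp_bg_max + 1 - sasp_tot)
    # ECM totals of senescent cells above everything else.
    if n_sen:
        non_sen = np.setdiff1d(np.arange(cfg.n_cells), sen_rows)
        ecm_bg_max = counts[non_sen[:, None], ecm].sum(axis=1).max() if non_sen.size else 0
        ecm_tot = counts[sen_rows[:, None], ecm].sum(axis=1)
        counts[sen_rows, ecm[0]] += np.maximum(0, ecm_bg_max + 1 - ecm_tot)

    clusters = _assign_clusters(rng, cfg, sen_rows, esc_rows)
    counts_df = pd.DataFrame(counts, index=cells, columns=genes)
    labels = pd.Series(clusters, index=cells, name="cluster")
    truth = GroundTruth(
        senescent_cell_ids={cells[i] for i in sen_rows},
        escaped_cell_ids={cells[i] for i in esc_rows},
        gene_sets={"filler": {g for g in genes if g.startswith("FILLER")}},
    )
    return counts_df, labels, truth


def _assign_clusters(rng, cfg: SingleCellConfig, sen_rows, esc_rows) -> np.ndarray:
    """Background cells spread uniformly; planted cells concentrate.

    Senescent cells occupy the first three clusters (emulating enrichment
    in a few cell types); escaped cells the last three.
    """
    names = np.array([f"Cluster{i + 1:02d}" for i in range(cfg.n_clusters)])
    assign = rng.integers(0, cfg.n_clusters, cfg.n_cells)
    k_focus = min(3, cfg.n_clusters)
    if len(sen_rows):
        assign[sen_rows] = rng.integers(0, k_focus, len(sen_rows))
    if len(esc_rows):
        assign[esc_rows] = cfg.n_clusters - 1 - rng.integers(0, k_focus, len(esc_rows))
    return names[assign]


def gen_region_matrix(
    n_regions: int,
    panel: MarkerPanel,
    seed: int,
    *,
    up_boost: float = 4.0,
    down_factor: float = 0.25,
    noise_sd: float = 0.3,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a regions x genes FPKM matrix with one senescent region.

    Lognormal per-gene baselines with multiplicative lognormal noise; in
    the (randomly chosen) true region, up-panel genes are multiplied by
    ``up_boost`` and down-panel genes by ``down_factor``.  Setting
    ``up_boost=1, down_factor=1, noise_sd=0`` yields a matrix constant
    across regions (all region scores equal).
    """
    if n_regions < 2:
        raise ConfigurationError(f"n_regions must be >= 2, got {n_regions}")
    up = list(panel.region_up) or sorted(panel.consensus_up) or list(panel.common_up)
    down = list(panel.region_down) or sorted(panel.consensus_down) or list(panel.common_down)
    if not up or not down:
        raise ConfigurationError("panel has no up/down genes for region simulation")
    extra = sorted((panel.sasp | panel.ecm) - set(up) - set(down))
    genes = up + down + extra

    rng = np.random.default_rng(seed)
    base = rng.lognormal(np.log(10.0), 1.0, len(genes))
    noise = (
        rng.lognormal(0.0, noise_sd, (n_regions, len(genes)))
        if noise_sd > 0
        else np.ones((n_regions, len(genes)))
    )
    fpkm = base[None, :] * noise
    true_idx = int(rng.integers(0, n_regions))
    fpkm[true_idx, : len(up)] *= up_boost
    fpkm[true_idx, len(up) : len(up) + len(down)] *= down_factor

    regions = [f"Region{i + 1:02d}" for i in range(n_regions)]
    truth = GroundTruth(
        true_up_genes=set(up), true_down_genes=set(down), true_region=regions[true_idx]
    )
    return pd.DataFrame(fpkm, index=regions, columns=genes), truth


def gen_paired_omics(
    n_genes: int,
    n_samples: int,
    rho_by_set: dict[str, float],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate paired mRNA/protein tables with per-set rank correlation.

    Genes are split evenly across the named sets (insertion order;
    remainder to the earlier sets).  Each gene's (mRNA, protein) sample
    pairs are bivariate Gaussian with the Pearson coefficient
    ``2*sin(pi*rho/6)`` whose population Spearman correlation equals the
    set's target rho.
    """
    for name, rho in rho_by_set.items():
        if not -1.0 < rho < 1.0:
            raise ConfigurationError(f"target rho for set {name!r} must be in (-1,1), got {rho}")
    if not rho_by_set:
        raise ConfigurationError("rho_by_set must name at least one set")
    rng = np.random.default_rng(seed)
    names = list(rho_by_set)
    sizes = np.full(len(names), n_genes // len(names))
    sizes[: n_genes % len(names)] += 1

    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    gene_ids, rho_target, gene_sets = [], [], {}
    for name, size in zip(names, sizes):
        ids = [f"{name.upper()}{i + 1:04d}" for i in range(size)]
        gene_ids += ids
        rho_target += [rho_by_set[name]] * size
        gene_sets[name] = set(ids)

    rho_target_arr = np.array(rho_target)
    pearson = 2.0 * np.sin(np.pi * rho_target_arr / 6.0)
    z1 = rng.normal(size=(n_genes, n_samples))
    z2 = pearson[:, None] * z1 + np.sqrt(1.0 - pearson[:, None] ** 2) * rng.normal(
        size=(n_genes, n_samples)
    )
    mrna = pd.DataFrame(8.0 + z1, index=gene_ids, columns=samples)
    protein = pd.DataFrame(z2, index=gene_ids, columns=samples)
    truth = GroundTruth(
        true_rho_per_gene=dict(zip(gene_ids, rho_target_arr)),
        gene_sets=gene_sets,
    )
    return mrna, protein, truth
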