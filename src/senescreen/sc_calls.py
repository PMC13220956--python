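"""Four-criterion senescent-cell calling and senescence-escape detection.

A cell is called senescent when it simultaneously

1. accumulates high expression of the upregulated common senescence
   markers (summed expression above ``up_sum_min``),
2. lacks expression of the downregulated senescence markers (summed
   expression at or below ``down_tolerance``, default zero),
3. ranks in the top ``top_quantile`` of cells by total SASP expression,
4. ranks in the top ``top_quantile`` of cells by total ECM expression, and
5. expresses at least ``min_cdki_expressed`` CDK-inhibitor genes.

(Criteria 1-2 together form the "common marker" criterion; SASP, ECM and
CDKi expression are the remaining three.)

Senescence *escape* is flagged among cells that are p21 (CDKN1A) positive
with top-quantile SASP: those that additionally express the proliferation
marker MKI67 are escape candidates, further profiled for PCNA and MCM
complex co-expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import MarkerPanel
from .errors import ConfigurationError, InputError

__all__ = [
    "CallerThresholds",
    "EscapeReport",
    "score_cells",
    "summarize_clusters",
    "detect_escape",
    "compare_expression",
]


@dataclass(frozen=True)
class CallerThresholds:
    """Thresholds of the senescent-cell caller.

    ``up_sum_min``        minimum summed up-marker expression, in the same
                          units as the input matrix (default 1000 — chosen
                          for raw-count-scale matrices; recalibrate for
                          normalized data);
    ``down_tolerance``    maximum summed down-marker expression tolerated
                          (0 = strict absence);
    ``top_quantile``      fraction of cells counted as "high" SASP/ECM;
    ``min_cdki_expressed`` how many distinct CDKi genes must be non-zero;
    ``up_gene_set``       which panel list feeds criterion 1
                          (``"common_up"`` or ``"consensus_up"``);
    ``mcm_rule``          escape MCM co-expression rule: ``"any"`` subunit
                          or ``"all"`` six.
    """

    up_sum_min: float = 1000.0
    down_tolerance: float = 0.0
    top_quantile: float = 0.15
    min_cdki_expressed: int = 1
    up_gene_set: str = "common_up"
    mcm_rule: str = "any"

    def __post_init__(self) -> None:
        if not 0.0 < self.top_quantile < 1.0:
            raise ConfigurationError(f"top_quantile must be in (0,1), got {self.top_quantile}")
        if self.up_sum_min <= 0:
            raise ConfigurationError(f"up_sum_min must be > 0, got {self.up_sum_min}")
        if self.down_tolerance < 0:
            raise ConfigurationError(f"down_tolerance must be >= 0, got {self.down_tolerance}")
        if self.up_gene_set not in ("common_up", "consensus_up"):
            raise ConfigurationError(f"unknown up_gene_set {self.up_gene_set!r}")
        if self.mcm_rule not in ("any", "all"):
            raise ConfigurationError(f"unknown mcm_rule {self.mcm_rule!r}")


@dataclass
class EscapeReport:
    """Senescence-escape summary.

    ``base_cell_ids``: p21-positive cells with top-quantile SASP.
    ``escape_cell_ids``: base cells additionally expressing MKI67.
    Fractions are NaN (and ``undefined`` True) when the base set is empty.
    """

    base_cell_ids: list = field(default_factory=list)
    escape_cell_ids: list = field(default_factory=list)
    frac_of_p21_sasp_cells_expressing_mki67: float = float("nan")
    frac_escape_expressing_pcna: float = float("nan")
    frac_escape_expressing_mcm: float = float("nan")
    cluster_composition: dict = field(default_factory=dict)
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "n_base": len(self.base_cell_ids),
            "n_escape": len(self.escape_cell_ids),
            "escape_cell_ids": list(map(str, self.escape_cell_ids)),
            "frac_of_p21_sasp_cells_expressing_mki67": self.frac_of_p21_sasp_cells_expressing_mki67,
            "frac_escape_expressing_pcna": self.frac_escape_expressing_pcna,
            "frac_escape_expressing_mcm": self.frac_escape_expressing_mcm,
            "cluster_composition": self.cluster_composition,
            "undefined": self.undefined,
        }


def _present(matrix: pd.DataFrame, genes, label: str) -> list[str]:
    """Panel genes present in the matrix; warn on misses, error if none."""
    genes = list(genes)
    if not genes:
        raise InputError(f"panel set {label!r} is empty")
    present = [g for g in genes if g in matrix.columns]
    if not present:
        raise InputError(f"no {label} panel gene found in the expression matrix")
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} of {len(genes)} {label} genes absent "
            "from the matrix; scoring uses the rest",
            stacklevel=3,
        )
    return present


def _top_quantile_flag(totals: np.ndarray, top_quantile: float) -> tuple[np.ndarray, float]:
    """Inclusive membership in the top ``top_quantile`` fraction of cells.

    The cut is the (1 - top_quantile) quantile with 'higher' interpolation;
    ties at the cut all pass, so slightly more than the nominal fraction
    may qualify.
    """
    cut = float(np.quantile(totals, 1.0 - top_quantile, method="higher"))
    return totals >= cut, cut


def score_cells(
    matrix: pd.DataFrame,
    panel: MarkerPanel,
    thr: CallerThresholds = CallerThresholds(),
    clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the 4-criterion senescence caller to a cells x genes matrix.

    Returns a per-cell DataFrame with the criterion columns ``c1_up_sum``,
    ``c2_down_absent``, ``c3_sasp_top``, ``c4_ecm_top``, ``c5_cdki``, the
    combined ``senescent`` call and (if given) the ``cluster`` label.
    The thresholds actually applied are stored in ``result.attrs``.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise InputError("expression matrix is empty")
    up_genes = getattr(panel, thr.up_gene_set)
    up = _present(matrix, up_genes, thr.up_gene_set)
    down = _present(matrix, panel.common_down, "common_down")
    sasp = _present(matrix, panel.sasp, "sasp")
    ecm = _present(matrix, panel.ecm, "ecm")
    cdki = _present(matrix, panel.cdki, "cdki")

    up_sum = matrix[up].sum(axis=1).to_numpy(dtype=float)
    down_sum = matrix[down].sum(axis=1).to_numpy(dtype=float)
    sasp_total = matrix[sasp].sum(axis=1).to_numpy(dtype=float)
    ecm_total = matrix[ecm].sum(axis=1).to_numpy(dtype=float)
    n_cdki = (matrix[cdki] > 0).sum(axis=1).to_numpy()

    c3, sasp_cut = _top_quantile_flag(sasp_total, thr.top_quantile)
    c4, ecm_cut = _top_quantile_flag(ecm_total, thr.top_quantile)
    c1 = up_sum > thr.up_sum_min
    c2 = down_sum <= thr.down_tolerance
    c5 = n_cdki >= thr.min_cdki_expressed

    calls = pd.DataFrame(
        {
            "c1_up_sum": up_sum,
            "c2_down_absent": c2,
            "c3_sasp_top": c3,
            "c4_ecm_top": c4,
            "c5_cdki": c5,
            "sasp_total": sasp_total,
            "ecm_total": ecm_total,
            "senescent": c1 & c2 & c3 & c4 & c5,
        },
        index=matrix.index,
    )
    if clusters is not None:
        calls["cluster"] = pd.Series(clusters).reindex(matrix.index)
    calls.attrs["thresholds"] = thr
    calls.attrs["sasp_cut"] = sasp_cut
    calls.attrs["ecm_cut"] = ecm_cut
    return calls


def summarize_clusters(calls: pd.DataFrame) -> pd.Series:
    """Fraction of senescent cells contributed by each cluster.

    Fractions are over *senescent* cells and sum to 1; an empty call set
    yields an empty mapping with a warning.
    """
    if "cluster" not in calls.columns:
        raise InputError("calls lack a cluster column; pass clusters to score_cells")
    sen = calls[calls["senescent"]]
    if sen.empty:
        warnings.warn("no senescent cells called; cluster summary is empty", stacklevel=2)
        return pd.Series(dtype=float, name="fraction")
    comp = sen["cluster"].value_counts(normalize=True).sort_values(ascending=False)
    comp.name = "fraction"
    return comp


def detect_escape(
    matrix: pd.DataFrame,
    panel: MarkerPanel,
    thr: CallerThresholds = CallerThresholds(),
    clusters: pd.Series | None = None,
) -> EscapeReport:
    """Find cells bearing senescence hallmarks yet expressing MKI67.

    Base set: CDKN1A-positive cells whose SASP total is in the top
    ``top_quantile`` (same rule as the main caller).  Escape set: base
    cells with MKI67 > 0, profiled for PCNA and MCM co-expression.
    """
    for gene in ("CDKN1A", "MKI67", "PCNA"):
        if gene not in matrix.columns:
            raise InputError(f"escape detection requires {gene} in the matrix")
    mcm = [g for g in sorted(panel.mcm) if g in matrix.columns]
    if not mcm:
        raise InputError("escape detection requires at least one MCM gene in the matrix")

    sasp = _present(matrix, panel.sasp, "sasp")
    sasp_total = matrix[sasp].sum(axis=1).to_numpy(dtype=float)
    sasp_top, _ = _top_quantile_flag(sasp_total, thr.top_quantile)
    base_mask = (matrix["CDKN1A"].to_numpy() > 0) & sasp_top
    base_ids = list(matrix.index[base_mask])
    if not base_ids:
        warnings.warn("no p21-positive high-SASP cell found; escape report undefined", stacklevel=2)
        return EscapeReport(undefined=True)

    base = matrix.loc[base_ids]
    escape_mask = base["MKI67"].to_numpy() > 0
    escape_ids = list(base.index[escape_mask])
    report = EscapeReport(
        base_cell_ids=base_ids,
        escape_cell_ids=escape_ids,
        frac_of_p21_sasp_cells_expressing_mki67=len(escape_ids) / len(base_ids),
    )
    if escape_ids:
        esc = matrix.loc[escape_ids]
        report.frac_escape_expressing_pcna = float((esc["PCNA"] > 0).mean())
        if thr.mcm_rule == "all":
            mcm_pos = (esc[mcm] > 0).all(axis=1)
        else:
            mcm_pos = (esc[mcm] > 0).any(axis=1)
        report.frac_escape_expressing_mcm = float(mcm_pos.mean())
        if clusters is not None:
            comp = pd.Series(clusters).reindex(escape_ids).value_counts(normalize=True)
            report.cluster_composition = comp.to_dict()
    else:
        report.frac_escape_expressing_pcna = float("nan")
        report.frac_escape_expressing_mcm = float("nan")
    return report


def compare_expression(
    matrix: pd.DataFrame, calls: pd.DataFrame, gene: str
) -> tuple[float, float]:
    """Mann-Whitney U comparison of one gene, senescent vs non-senescent.

    Returns ``(U, two-sided p)`` with tie correction (exact for small
    groups without ties, normal approximation otherwise).
    """
    if gene not in matrix.columns:
        raise InputError(f"gene {gene!r} not in the matrix")
    sen_mask = calls["senescent"].reindex(matrix.index).to_numpy(dtype=bool)
    x = matrix.loc[sen_mask, gene].to_numpy(dtype=float)
    y = matrix.loc[~sen_mask, gene].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both senescent and non-senescent groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
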