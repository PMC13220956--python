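"""mRNA-protein concordance, phosphosite prevalence, and proteome overlap.

Concordance between transcript and protein abundance is measured per gene
by the Spearman rank correlation over paired samples (pairwise-complete;
genes with fewer than ``min_pairs`` complete pairs are skipped).  Gene-set
concordance is compared against the background by a Mann-Whitney U test on
the per-gene correlation coefficients.

Phosphosite prevalence is the fraction of tumor samples in which a site
was detected (non-missing intensity); tumor-vs-normal intensity shifts use
Welch's unequal-variance t-test.

Proteome overlap summarizes how the members of a marker panel behave in a
protein-level differential table: fractions up, down, detected-unchanged
and not-detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "spearman_per_gene",
    "compare_rho_sets",
    "fraction_significant",
    "phospho_prevalence",
    "proteome_marker_overlap",
    "RhoComparison",
    "PhosphoSiteResult",
    "OverlapReport",
]

_VALID_RESIDUES = {"S", "T", "Y"}


def spearman_per_gene(
    mrna: pd.DataFrame, protein: pd.DataFrame, *, min_pairs: int = 4
) -> pd.DataFrame:
    """Per-gene Spearman correlation between mRNA and protein levels.

    Both inputs are genes x samples; only genes present in both tables are
    tested, on their pairwise-complete (non-missing in both layers)
    samples.  Returns a DataFrame with columns ``gene``, ``n``, ``rho``,
    ``p`` for the tested genes; genes with fewer than ``min_pairs``
    complete pairs are skipped with a warning count.
    """
    shared_genes = mrna.index.intersection(protein.index)
    shared_samples = mrna.columns.intersection(protein.columns)
    if len(shared_samples) == 0:
        raise InputError("mRNA and protein tables share no samples")
    x = mrna.loc[shared_genes, shared_samples].to_numpy(dtype=float)
    y = protein.loc[shared_genes, shared_samples].to_numpy(dtype=float)

    rows = []
    n_skipped = 0
    for gene, xi, yi in zip(shared_genes, x, y):
        ok = ~(np.isnan(xi) | np.isnan(yi))
        n = int(ok.sum())
        if n < min_pairs:
            n_skipped += 1
            continue
        rho, p = stats.spearmanr(xi[ok], yi[ok])
        rows.append((gene, n, float(rho), float(p)))
    if n_skipped:
        warnings.warn(
            f"{n_skipped} genes skipped with <{min_pairs} complete mRNA/protein pairs",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["gene", "n", "rho", "p"])


@dataclass
class RhoComparison:
    """Set-vs-background comparison of per-gene correlation coefficients."""

    median_set: float
    median_background: float
    u_statistic: float
    p: float


def compare_rho_sets(rhos_set, rhos_background) -> RhoComparison:
    """Compare a gene set's rho distribution against the background.

    Two-sided Mann-Whitney U test on the per-gene Spearman coefficients,
    plus the two medians as summary statistics.
    """
    rhos_set = np.asarray(rhos_set, dtype=float)
    rhos_background = np.asarray(rhos_background, dtype=float)
    if rhos_set.size == 0 or rhos_background.size == 0:
        raise InputError("both rho sets must be non-empty")
    res = stats.mannwhitneyu(rhos_set, rhos_background, alternative="two-sided")
    return RhoComparison(
        median_set=float(np.median(rhos_set)),
        median_background=float(np.median(rhos_background)),
        u_statistic=float(res.statistic),
        p=float(res.pvalue),
    )


def fraction_significant(pvals, alpha: float = 0.05) -> float:
    """Fraction of tested genes with raw p below alpha."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise InputError("no tested genes")
    return float((pvals < alpha).mean())


@dataclass
class PhosphoSiteResult:
    """Prevalence and tumor-vs-normal intensity shift of one phosphosite."""

    site: tuple[str, str, int]
    prevalence_tumor: float
    n_tumor: int
    n_normal: int
    t_welch: float = float("nan")
    p: float = float("nan")


def phospho_prevalence(
    table: pd.DataFrame, sample_class: pd.Series, site: tuple[str, str, int]
) -> PhosphoSiteResult:
    """Detection prevalence and Welch comparison for one phosphosite.

    ``table`` has the key columns ``protein``, ``residue``, ``position``
    and one column per sample with normalized log2 intensity (NaN =
    not detected).  ``sample_class`` maps sample -> ``"tumor"``/``"normal"``.
    Prevalence is the fraction of tumor samples with the site detected;
    the Welch t-test (two-sided) runs when both classes have >=2 detected
    intensities, else only prevalence is reported.
    """
    protein, residue, position = site
    if residue not in _VALID_RESIDUES:
        raise InputError(f"residue must be one of {sorted(_VALID_RESIDUES)}, got {residue!r}")
    if position < 1:
        raise InputError(f"position must be >= 1, got {position}")
    key = (
        (table["protein"] == protein)
        & (table["residue"] == residue)
        & (table["position"] == position)
    )
    if not key.any():
        raise InputError(f"site {protein} {residue}{position} not found in the table")
    row = table.loc[key].iloc[0]

    sample_class = pd.Series(sample_class)
    samples = [s for s in table.columns if s in sample_class.index]
    tumor = [s for s in samples if sample_class[s] == "tumor"]
    normal = [s for s in samples if sample_class[s] == "normal"]
    if not tumor:
        raise InputError("no tumor samples in the table")
    tumor_vals = row[tumor].to_numpy(dtype=float)
    normal_vals = row[normal].to_numpy(dtype=float)
    detected_t = tumor_vals[~np.isnan(tumor_vals)]
    detected_n = normal_vals[~np.isnan(normal_vals)]

    result = PhosphoSiteResult(
        site=(protein, residue, int(position)),
        prevalence_tumor=float(detected_t.size / len(tumor)),
        n_tumor=len(tumor),
        n_normal=len(normal),
    )
    if detected_t.size >= 2 and detected_n.size >= 2:
        t, p = stats.ttest_ind(detected_t, detected_n, equal_var=False)
        result.t_welch, result.p = float(t), float(p)
    return result


@dataclass
class OverlapReport:
    """How panel members behave in a protein-level differential table.

    ``fractions`` (per set): up / down / unchanged / missing over *all*
    members — these four sum to 1.  ``fractions_detected`` re-bases
    up / down / unchanged on detected members only, so either convention
    of a summary pie chart can be reproduced.
    """

    fractions: dict = field(default_factory=dict)
    fractions_detected: dict = field(default_factory=dict)
    n_members: dict = field(default_factory=dict)
    overall_deregulated_fraction: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "fractions": self.fractions,
            "fractions_detected": self.fractions_detected,
            "n_members": self.n_members,
            "overall_deregulated_fraction": self.overall_deregulated_fraction,
        }


def proteome_marker_overlap(
    protein_de: pd.DataFrame, panel_sets: dict[str, set[str]]
) -> OverlapReport:
    """Overlap of marker panels with a direction-called protein DE table.

    For each named gene set, members are classified as ``up`` / ``down`` /
    ``unchanged`` (detected, direction ``none``) / ``missing`` (absent from
    the table).  The overall deregulated fraction pools every member of
    every set and reports the share called in either direction.
    """
    if "direction" not in protein_de.columns:
        raise InputError("protein DE table lacks direction calls")
    direction = protein_de.set_index("gene")["direction"]
    report = OverlapReport()
    pooled_members: set[str] = set()
    pooled_dereg: set[str] = set()
    for name, members in panel_sets.items():
        members = set(members)
        if not members:
            warnings.warn(f"panel set {name!r} is empty; skipped", stacklevel=2)
            continue
        detected = members & set(direction.index)
        up = {g for g in detected if direction[g] == "up"}
        down = {g for g in detected if direction[g] == "down"}
        unchanged = detected - up - down
        n = len(members)
        report.fractions[name] = {
            "up": len(up) / n,
            "down": len(down) / n,
            "unchanged": len(unchanged) / n,
            "missing": (n - len(detected)) / n,
        }
        report.fractions_detected[name] = {
            "up": len(up) / len(detected) if detected else float("nan"),
            "down": len(down) / len(detected) if detected else float("nan"),
            "unchanged": len(unchanged) / len(detected) if detected else float("nan"),
        }
        report.n_members[name] = {"total": n, "detected": len(detected)}
        pooled_members |= members
        pooled_dereg |= up | down
    if pooled_members:
        report.overall_deregulated_fraction = len(pooled_dereg) / len(pooled_members)
    return report
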