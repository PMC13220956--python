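"""Moderated two-group differential expression and DEG calling.

The differential-expression model is the classic gene-wise linear model with
empirical-Bayes variance moderation: each gene's residual variance is shrunk
toward a prior variance estimated from the ensemble of gene-wise sample
variances, and the resulting moderated t-statistic gains the prior degrees
of freedom.  The same routine serves log2 microarray intensities and log2
protein abundances — anything with approximately Gaussian noise on the log
scale and one row per feature.

Differentially expressed genes (DEGs) are then called with strict
thresholds on the BH-adjusted p value and the log2 fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError

__all__ = [
    "DEGThresholds",
    "fit_moderated",
    "call_degs",
    "adjust_bh",
    "DE_COLUMNS",
]

#: Fixed column order of a differential-expression table on disk.
DE_COLUMNS = ["gene", "log2fc", "t", "p", "p_adj", "direction"]


@dataclass(frozen=True)
class DEGThresholds:
    """Cut-offs for calling differentially expressed genes.

    alpha:        BH-adjusted p-value threshold (strict ``<``).
    lfc_cut:      absolute log2 fold-change threshold (strict ``>``).
    lfc_cut_spia: stricter |log2FC| cut used when exporting genes for
                  signalling-pathway impact analysis.
    """

    alpha: float = 0.05
    lfc_cut: float = 0.5
    lfc_cut_spia: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.lfc_cut < 0:
            raise ConfigurationError(f"lfc_cut must be >= 0, got {self.lfc_cut}")
        if self.lfc_cut_spia < 0:
            raise ConfigurationError(
                f"lfc_cut_spia must be >= 0, got {self.lfc_cut_spia}"
            )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    # For very large y the solution approaches 1/y; for small y, 1/sqrt(y).
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def _estimate_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Matches the sample variances against the marginal distribution implied
    by ``s2 | sigma2 ~ sigma2 * chi2(df)/df`` with ``1/sigma2`` gamma
    distributed: moments of ``log s2`` identify the prior df and variance.
    Returns ``(prior_df, prior_var)``; prior_df may be ``inf``.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - special.polygamma(1, df_resid / 2.0)
    if excess <= 0:
        # Sample variances less dispersed than chi-square alone: variances
        # are effectively common, prior is infinitely informative.
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(excess)
    prior_df = 2.0 * half_d0
    prior_var = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return prior_df, prior_var


def fit_moderated(
    matrix: pd.DataFrame,
    groups,
    *,
    reference: str | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated differential expression.

    Parameters
    ----------
    matrix
        Features (genes or proteins) x samples table of log2 values.
    groups
        Sample-aligned vector with exactly two levels.  ``log2fc`` is
        ``mean(test) - mean(reference)`` where the reference level is
        ``reference`` if given, else the first level in order of appearance.
    reference
        Which group level to treat as baseline.
    prior_df
        Override the estimated prior degrees of freedom.  ``0`` disables
        moderation (ordinary pooled-variance t); ``inf`` forces a single
        common variance for all features.

    Returns
    -------
    DataFrame indexed like ``matrix`` with columns ``gene``, ``log2fc``,
    ``t_ordinary``, ``t_moderated``, ``df_total``, ``p``, ``p_adj``,
    ``direction`` (all ``"none"``; see :func:`call_degs`) and
    ``zero_variance``.
    """
    groups = np.asarray(list(groups), dtype=object)
    if groups.shape[0] != matrix.shape[1]:
        raise InputError(
            f"groups has {groups.shape[0]} entries but matrix has "
            f"{matrix.shape[1]} samples"
        )
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise InputError(f"exactly two group levels required, got {levels}")
    if reference is not None:
        if reference not in levels:
            raise InputError(f"reference level {reference!r} not in {levels}")
        levels = [reference] + [lv for lv in levels if lv != reference]
    mask2 = groups == levels[1]
    n1 = int((~mask2).sum())
    n2 = int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise InputError(
            f"each group needs >=2 samples (got {n1} {levels[0]!r}, {n2} {levels[1]!r})"
        )

    x = matrix.to_numpy(dtype=float)
    x1, x2 = x[:, ~mask2], x[:, mask2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    log2fc = m2 - m1
    df_resid = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    zero_var = s2 <= 0
    if zero_var.all():
        warnings.warn(
            "matrix has zero residual variance for every feature; all p set to 1",
            stacklevel=2,
        )

    if prior_df is None:
        d0, s02 = _estimate_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s02 = 0.0, 0.0
    elif np.isinf(prior_df):
        _, s02 = _estimate_prior(s2, df_resid)
        d0 = np.inf
    else:
        if prior_df < 0:
            raise ConfigurationError(f"prior_df must be >= 0, got {prior_df}")
        d0 = float(prior_df)
        _, s02 = _estimate_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = log2fc / (np.sqrt(s2) * se_factor)
        t_mod = log2fc / (np.sqrt(s2_post) * se_factor)
    t_ord[zero_var] = 0.0
    t_mod[~np.isfinite(t_mod)] = 0.0

    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    # Residual variance exactly zero cannot support inference; such genes are
    # kept (universe stays aligned across datasets) but flagged with p = 1.
    p[zero_var] = 1.0

    table = pd.DataFrame(
        {
            "gene": matrix.index.astype(str),
            "log2fc": log2fc,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "df_total": df_total,
            "p": p,
            "p_adj": adjust_bh(p),
            "direction": "none",
            "zero_variance": zero_var,
        },
        index=matrix.index,
    )
    table.attrs["prior_df"] = d0
    table.attrs["prior_var"] = s02
    table.attrs["groups"] = (levels[0], levels[1])
    return table


def call_degs(table: pd.DataFrame, thr: DEGThresholds = DEGThresholds()) -> pd.DataFrame:
    """Fill the ``direction`` column with strict-threshold DEG calls.

    ``up``  : ``p_adj < alpha`` and ``log2fc > lfc_cut``;
    ``down``: ``p_adj < alpha`` and ``log2fc < -lfc_cut``; else ``none``.
    """
    if "p_adj" not in table.columns:
        raise InputError("DE table lacks the p_adj column; run fit_moderated first")
    out = table.copy()
    sig = out["p_adj"].to_numpy() < thr.alpha
    lfc = out["log2fc"].to_numpy()
    direction = np.where(
        sig & (lfc > thr.lfc_cut), "up", np.where(sig & (lfc < -thr.lfc_cut), "down", "none")
    )
    out["direction"] = direction
    out.attrs.update(table.attrs)
    out.attrs["n_up"] = int((direction == "up").sum())
    out.attrs["n_down"] = int((direction == "down").sum())
    return out


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
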