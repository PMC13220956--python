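"""Anatomic-region senescence scoring by the scale-flip-sum recipe.

Each gene's expression is min-max scaled to [0, 1] across regions, scaled
values of downregulated markers are multiplied by -1, and per-region
contributions are summed; the region with the highest sum expresses the
panel the most.  Genes constant across regions have undefined scaling and
contribute zero everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["RegionScores", "score_regions", "score_panels", "aggregate_region_samples"]


@dataclass
class RegionScores:
    """Per-region summed score with per-gene contributions.

    ``contributions`` is regions x genes; up-gene columns lie in [0, 1],
    down-gene columns in [-1, 0]; ``scores[r] == contributions.loc[r].sum()``.
    """

    scores: pd.Series
    contributions: pd.DataFrame
    top_region: str


def _scale01(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each gene (column) across regions; constant genes -> 0."""
    lo = fpkm.min(axis=0)
    span = fpkm.max(axis=0) - lo
    scaled = (fpkm - lo).div(span.where(span > 0, np.inf), axis=1)
    return scaled.fillna(0.0)


def score_regions(fpkm: pd.DataFrame, up_set, down_set) -> RegionScores:
    """Score every region for a panel of up- and down-regulated genes.

    Parameters
    ----------
    fpkm
        Regions x genes expression matrix (any non-negative unit; the
        scaling removes per-gene magnitude).
    up_set, down_set
        Gene collections; a gene may not appear in both.  Genes absent
        from the matrix are dropped with a warning.
    """
    up_set, down_set = set(up_set), set(down_set)
    if up_set & down_set:
        raise InputError(
            f"genes in both up and down sets: {sorted(up_set & down_set)[:5]}"
        )
    if fpkm.shape[0] < 2:
        raise InputError("region scoring needs at least 2 regions")
    up = sorted(up_set & set(fpkm.columns))
    down = sorted(down_set & set(fpkm.columns))
    missing = (len(up_set) - len(up)) + (len(down_set) - len(down))
    if missing:
        warnings.warn(f"{missing} panel genes absent from the region matrix; dropped", stacklevel=2)
    if not up and not down:
        raise InputError("no panel gene present in the region matrix")

    scaled = _scale01(fpkm[up + down])
    contributions = scaled.copy()
    if down:
        contributions[down] = -contributions[down]
    scores = contributions.sum(axis=1)
    return RegionScores(
        scores=scores,
        contributions=contributions,
        top_region=str(scores.idxmax()),
    )


def score_panels(
    fpkm: pd.DataFrame, panels: list[tuple[str, set, set]]
) -> dict[str, RegionScores]:
    """Score each named (up_set, down_set) panel independently."""
    return {name: score_regions(fpkm, up, down) for name, up, down in panels}


def aggregate_region_samples(
    samples: pd.DataFrame, region_labels, how: str = "mean"
) -> pd.DataFrame:
    """Collapse a samples x genes matrix to regions x genes.

    Multi-donor atlases carry several samples per histological region;
    scoring operates on one row per region, aggregated by ``mean``
    (default) or ``median``.
    """
    if how not in ("mean", "median"):
        raise InputError(f"unknown aggregation {how!r}")
    labels = pd.Series(region_labels, index=samples.index)
    grouped = samples.groupby(labels)
    return grouped.mean() if how == "mean" else grouped.median()
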