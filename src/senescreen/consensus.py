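"""Consensus senescence-marker derivation across differential-expression tables.

Given one DEG-called table per bulk dataset (senescent vs proliferating),
this module derives

* the *consensus* marker sets — genes called in the same direction in at
  least ``min_datasets`` datasets and never in the opposite direction;
* the small *common* marker set used by the single-cell caller — the most
  upregulated genes at a linear fold-change cut in most datasets and the
  most downregulated genes at a linear cut in *all* datasets;
* the wider *region* panel (all consensus-up genes plus the N most
  downregulated consensus-down genes) used for anatomic-region scoring.

Rankings of "most up/down regulated" use the unweighted mean log2 fold
change across datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "CDKI_GENES",
    "MCM_GENES",
    "PROLIFERATION_GENES",
    "ConsensusRules",
    "MarkerPanel",
    "consensus_markers",
    "common_marker_set",
    "region_marker_panel",
    "build_marker_panel",
]

#: INK4 family (CDKN2A-D) plus CIP/KIP family (CDKN1A-C) CDK inhibitors.
CDKI_GENES = frozenset(
    {"CDKN1A", "CDKN1B", "CDKN1C", "CDKN2A", "CDKN2B", "CDKN2C", "CDKN2D"}
)
#: Replicative helicase (MCM) complex subunits.
MCM_GENES = frozenset({"MCM2", "MCM3", "MCM4", "MCM5", "MCM6", "MCM7"})
#: Canonical proliferation markers used by the escape detector.
PROLIFERATION_GENES = frozenset({"MKI67", "PCNA"} | MCM_GENES)


@dataclass(frozen=True)
class ConsensusRules:
    """Thresholds governing consensus and common-marker derivation.

    ``min_datasets``            minimum same-direction DEG calls for consensus;
    ``common_up_fc``            linear fold change a common-up gene must exceed;
    ``common_up_min_datasets``  in how many datasets it must exceed it;
    ``common_down_fc``          linear fold change a common-down gene must stay
                                below in *every* dataset;
    ``n_common_up/down``        truncation lengths of the common lists;
    ``n_region_down``           size of the most-downregulated region panel;
    ``require_exclusive``       whether a single opposite-direction call
                                disqualifies a gene from the consensus.
    """

    min_datasets: int = 3
    common_up_fc: float = 1.7
    common_up_min_datasets: int = 4
    common_down_fc: float = 0.5
    n_common_up: int = 8
    n_common_down: int = 7
    n_region_down: int = 133
    require_exclusive: bool = True

    def __post_init__(self) -> None:
        if self.min_datasets < 1:
            raise ConfigurationError(f"min_datasets must be >= 1, got {self.min_datasets}")
        for name in ("common_up_fc", "common_down_fc"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


@dataclass
class MarkerPanel:
    """Named senescence gene sets with their derivation thresholds.

    ``consensus_up/down`` are the full consensus sets, ``common_up/down``
    the short ordered lists used by the single-cell caller, and
    ``region_up/down`` the wider panel for anatomic-region scoring.  SASP,
    ECM, CDKi, MCM and proliferation sets are externally defined
    (secretome / matrix / cell-cycle annotation) rather than derived here.
    """

    consensus_up: set[str] = field(default_factory=set)
    consensus_down: set[str] = field(default_factory=set)
    common_up: list[str] = field(default_factory=list)
    common_down: list[str] = field(default_factory=list)
    region_up: list[str] = field(default_factory=list)
    region_down: list[str] = field(default_factory=list)
    sasp: set[str] = field(default_factory=set)
    ecm: set[str] = field(default_factory=set)
    cdki: set[str] = field(default_factory=lambda: set(CDKI_GENES))
    mcm: set[str] = field(default_factory=lambda: set(MCM_GENES))
    proliferation: set[str] = field(default_factory=lambda: set(PROLIFERATION_GENES))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.consensus_up & self.consensus_down:
            raise ConfigurationError(
                "consensus_up and consensus_down overlap: "
                f"{sorted(self.consensus_up & self.consensus_down)[:5]}"
            )
        if not set(self.common_up) <= self.consensus_up and self.consensus_up:
            raise ConfigurationError("common_up must be a subset of consensus_up")
        if not set(self.common_down) <= self.consensus_down and self.consensus_down:
            raise ConfigurationError("common_down must be a subset of consensus_down")

    def sets(self) -> dict[str, set[str]]:
        """All named sets as plain ``dict`` of ``set`` (lists included as sets)."""
        return {
            "consensus_up": set(self.consensus_up),
            "consensus_down": set(self.consensus_down),
            "common_up": set(self.common_up),
            "common_down": set(self.common_down),
            "region_up": set(self.region_up),
            "region_down": set(self.region_down),
            "sasp": set(self.sasp),
            "ecm": set(self.ecm),
            "cdki": set(self.cdki),
            "mcm": set(self.mcm),
            "proliferation": set(self.proliferation),
        }


def _vote_counts(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-gene up/down DEG vote counts over the shared gene universe."""
    genes = sorted(set().union(*(set(t["gene"]) for t in tables)))
    votes = pd.DataFrame(0, index=genes, columns=["up", "down"], dtype=int)
    for t in tables:
        if "direction" not in t.columns:
            raise InputError("DE table lacks direction calls; run call_degs first")
        for direction in ("up", "down"):
            hit = t.loc[t["direction"] == direction, "gene"]
            votes.loc[hit, direction] += 1
    return votes


def consensus_markers(
    tables: list[pd.DataFrame], rules: ConsensusRules = ConsensusRules()
) -> tuple[set[str], set[str]]:
    """Genes consistently deregulated across at least ``min_datasets`` tables.

    A gene enters ``consensus_up`` when it is an up-DEG in at least
    ``rules.min_datasets`` tables and (by default) a down-DEG in none;
    symmetrically for ``consensus_down``.
    """
    if len(tables) < rules.min_datasets:
        raise InputError(
            f"need at least {rules.min_datasets} DE tables, got {len(tables)}"
        )
    votes = _vote_counts(tables)
    up_ok = votes["up"] >= rules.min_datasets
    down_ok = votes["down"] >= rules.min_datasets
    if rules.require_exclusive:
        up_ok &= votes["down"] == 0
        down_ok &= votes["up"] == 0
    else:
        # Keep the sets disjoint: a gene passing both ways goes with the
        # majority direction, or with neither on a tie.
        both = up_ok & down_ok
        up_ok &= ~both | (votes["up"] > votes["down"])
        down_ok &= ~both | (votes["down"] > votes["up"])
    return set(votes.index[up_ok]), set(votes.index[down_ok])


def _lfc_matrix(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """genes x datasets matrix of log2 fold changes (NaN where absent)."""
    cols = {}
    for i, t in enumerate(tables):
        cols[i] = t.set_index("gene")["log2fc"]
    return pd.DataFrame(cols)


def common_marker_set(
    tables: list[pd.DataFrame],
    consensus: tuple[set[str], set[str]],
    rules: ConsensusRules = ConsensusRules(),
) -> tuple[list[str], list[str]]:
    """The short "common" marker lists used by the single-cell caller.

    ``common_up``: consensus-up genes with linear fold change above
    ``common_up_fc`` in at least ``common_up_min_datasets`` datasets, ranked
    by mean log2FC descending, truncated to ``n_common_up``.
    ``common_down``: consensus-down genes with linear fold change below
    ``common_down_fc`` in *all* datasets, ranked ascending, truncated to
    ``n_common_down``.
    """
    consensus_up, consensus_down = consensus
    lfc = _lfc_matrix(tables)
    fc = np.exp2(lfc)

    up_candidates = sorted(consensus_up & set(lfc.index))
    n_pass = (fc.loc[up_candidates] > rules.common_up_fc).sum(axis=1)
    up_pool = [g for g in up_candidates if n_pass[g] >= rules.common_up_min_datasets]
    up_rank = lfc.loc[up_pool].mean(axis=1).sort_values(ascending=False)
    common_up = list(up_rank.index[: rules.n_common_up])

    down_candidates = sorted(consensus_down & set(lfc.index))
    all_below = (fc.loc[down_candidates] < rules.common_down_fc).all(axis=1)
    down_pool = [g for g in down_candidates if all_below[g]]
    down_rank = lfc.loc[down_pool].mean(axis=1).sort_values(ascending=True)
    common_down = list(down_rank.index[: rules.n_common_down])

    if not common_up:
        warnings.warn("no gene qualified for common_up", stacklevel=2)
    if not common_down:
        warnings.warn("no gene qualified for common_down", stacklevel=2)
    return common_up, common_down


def region_marker_panel(
    consensus: tuple[set[str], set[str]],
    tables: list[pd.DataFrame],
    rules: ConsensusRules = ConsensusRules(),
) -> tuple[list[str], list[str]]:
    """Region-scoring panel: all consensus-up plus the most-down genes.

    The down panel holds the ``n_region_down`` consensus-down genes with
    the lowest mean log2FC across datasets (ascending order).  If fewer
    qualify, all are returned with a warning.
    """
    consensus_up, consensus_down = consensus
    lfc = _lfc_matrix(tables)
    up_panel = sorted(consensus_up)
    down_rank = (
        lfc.loc[sorted(consensus_down & set(lfc.index))].mean(axis=1).sort_values()
    )
    if len(down_rank) < rules.n_region_down:
        warnings.warn(
            f"only {len(down_rank)} consensus-down genes available "
            f"(requested {rules.n_region_down}); returning all",
            stacklevel=2,
        )
    down_panel = list(down_rank.index[: rules.n_region_down])
    return up_panel, down_panel


def build_marker_panel(
    tables: list[pd.DataFrame],
    rules: ConsensusRules = ConsensusRules(),
    *,
    sasp: set[str] | None = None,
    ecm: set[str] | None = None,
) -> MarkerPanel:
    """Derive a full :class:`MarkerPanel` from DEG-called tables.

    SASP and ECM sets come from external annotation and are passed through.
    The provenance record captures every threshold and the per-gene vote
    counts so a panel file is self-documenting.
    """
    consensus = consensus_markers(tables, rules)
    common_up, common_down = common_marker_set(tables, consensus, rules)
    region_up, region_down = region_marker_panel(consensus, tables, rules)
    votes = _vote_counts(tables)
    panel = MarkerPanel(
        consensus_up=consensus[0],
        consensus_down=consensus[1],
        common_up=common_up,
        common_down=common_down,
        region_up=region_up,
        region_down=region_down,
        sasp=set(sasp or ()),
        ecm=set(ecm or ()),
        provenance={
            "rules": asdict(rules),
            "n_datasets": len(tables),
            "votes_up": votes["up"].to_dict(),
            "votes_down": votes["down"].to_dict(),
        },
    )
    return panel
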