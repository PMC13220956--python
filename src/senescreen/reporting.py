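"""Significance annotation, pathway-analysis export, and run records."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import DEGThresholds
from .errors import InputError

__all__ = ["star_annotation", "export_spia_input", "RunRecord"]


def star_annotation(p: float) -> str:
    """Asterisk code for a p value.

    ``*``: .01 <= p < .05; ``**``: .001 <= p < .01; ``***``: .0001 <= p <
    .001; ``****``: p < .0001; ``ns`` otherwise.
    """
    p = float(p)
    if not 0.0 < p <= 1.0 or not np.isfinite(p):
        raise InputError(f"p must be in (0, 1], got {p}")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


def export_spia_input(
    table: pd.DataFrame, thr: DEGThresholds = DEGThresholds()
) -> dict[str, float]:
    """Gene -> log2FC mapping for signalling-pathway impact analysis.

    Keeps genes significant at ``thr.alpha`` (adjusted p) with
    ``|log2FC| > thr.lfc_cut_spia`` (strict).  The mapping is the input the
    external SPIA tooling consumes; the pathway analysis itself is out of
    scope here.
    """
    if "p_adj" not in table.columns:
        raise InputError("DE table lacks p_adj; run fit_moderated first")
    keep = (table["p_adj"] < thr.alpha) & (table["log2fc"].abs() > thr.lfc_cut_spia)
    sub = table.loc[keep]
    return dict(zip(sub["gene"], sub["log2fc"].astype(float)))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunRecord:
    """Provenance of one pipeline run: config, seed, timings, checksums."""

    seed: int | None = None
    config: dict = field(default_factory=dict)
    stage_timings: dict[str, float] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    def checksum_inputs(self, paths: dict[str, str | Path]) -> None:
        for name, path in paths.items():
            path = Path(path)
            if path.is_file():
                self.input_checksums[name] = _checksum(path)

    def time_stage(self, name: str):
        """Context manager recording a stage's wall time."""
        record = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                record.stage_timings[name] = round(time.perf_counter() - self.t0, 4)
                return False

        return _Timer()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")
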