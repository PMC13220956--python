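"""Structured configuration for orchestrated pipeline runs.

One YAML document collects every threshold in the pipeline: DEG calling,
consensus rules, the single-cell caller, the communication test and the
concordance settings, plus input paths, the global seed and the output
directory.  Unknown keys are rejected so typos fail instead of silently
reverting to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .consensus import ConsensusRules
from .diffexpr import DEGThresholds
from .errors import ConfigurationError
from .sc_calls import CallerThresholds

__all__ = ["LigrecSettings", "ConcordanceSettings", "AnalysisConfig"]


@dataclass(frozen=True)
class LigrecSettings:
    n_perm: int = 1000
    alpha: float = 0.05
    min_cells: int = 3

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigurationError(f"n_perm must be >= 1, got {self.n_perm}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass(frozen=True)
class ConcordanceSettings:
    alpha: float = 0.05
    min_pairs: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_pairs < 3:
            raise ConfigurationError(f"min_pairs must be >= 3, got {self.min_pairs}")


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class AnalysisConfig:
    """Full pipeline configuration.

    ``inputs`` maps logical input names (e.g. ``bulk_matrices``,
    ``sc_matrix``, ``panel_gmt``) to paths; stages look up what they need
    and fail with the missing artifact's name.
    """

    inputs: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    deg: DEGThresholds = field(default_factory=DEGThresholds)
    consensus: ConsensusRules = field(default_factory=ConsensusRules)
    caller: CallerThresholds = field(default_factory=CallerThresholds)
    ligrec: LigrecSettings = field(default_factory=LigrecSettings)
    concordance: ConcordanceSettings = field(default_factory=ConcordanceSettings)
    seed: int = 0
    outdir: str = "senescreen_out"

    _SECTIONS = {
        "deg": DEGThresholds,
        "consensus": ConsensusRules,
        "caller": CallerThresholds,
        "ligrec": LigrecSettings,
        "concordance": ConcordanceSettings,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data or {})
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _build(section_cls, data.pop(name) or {})
        kwargs.update(data)
        sim_keys = set((data.get("simulate") or {}))
        unknown_sim = sim_keys - {"bulk", "single_cell", "n_regions", "paired"}
        if unknown_sim:
            raise ConfigurationError(f"unknown simulate keys: {sorted(unknown_sim)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def require_input(self, name: str) -> str:
        if name not in self.inputs:
            raise ConfigurationError(f"missing required input {name!r} in config.inputs")
        return self.inputs[name]
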