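"""Frozen default configuration and YAML loading for the simulation CLI.

Every constant of the model instance lives here: the learning-loop
parameters, the test-time mapping/inference constants, and the group
protocol.  The defaults are the package's calibrated model instance; a YAML
file with any subset of the keys overrides them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .experiment import GROUPS, GroupConfig, SolverParams
from .learning import LearningConfig

__all__ = ["SimulationConfig", "load_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameterization of a simulation run."""

    learning: LearningConfig = field(default_factory=LearningConfig)
    solver: SolverParams = field(default_factory=SolverParams)
    n_sims: int | None = None  # None = each group's own default (100)

    def group(self, name: str) -> GroupConfig:
        cfg = GROUPS[name.replace("-", "_")]
        return cfg

    def to_dict(self) -> dict:
        return {
            "learning": asdict(self.learning),
            "solver": asdict(self.solver),
            "n_sims": self.n_sims,
        }


def load_config(path: str | Path | None) -> SimulationConfig:
    """Load a configuration file; missing keys fall back to the defaults."""
    if path is None:
        return SimulationConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    learning = LearningConfig(**data.get("learning", {}))
    solver = SolverParams(**data.get("solver", {}))
    return SimulationConfig(learning, solver, data.get("n_sims"))
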