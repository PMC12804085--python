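"""Pipeline configuration: one dataclass, YAML round-trip, shared defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import footprints, positional
from .enrichment import DEFAULT_ALPHA, DEFAULT_MIN_INPUT_READS
from .simulate import EngagementTarget, SimulationConfig


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def _listify(obj):
    """Recursively turn tuples into lists so YAML round-trips cleanly."""
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


@dataclass
class PipelineConfig:
    """All stage parameters with their package defaults.

    ``alpha`` is the TPM pseudocount; ``beta`` the codon-rate pseudocount
    (None = ``0.5 / min(N_IP, N_input)``); ``window``/``theta``/
    ``persistence``/``baseline_window``/``min_effect`` drive onset
    detection; ``buried_offset`` is the nascent-chain length hidden in the
    exit tunnel and SEC61 channel.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alpha: float = DEFAULT_ALPHA
    beta: float | None = None
    min_input_reads: int = DEFAULT_MIN_INPUT_READS
    window: int = positional.DEFAULT_WINDOW
    theta: float = positional.DEFAULT_THETA
    persistence: int = positional.DEFAULT_PERSISTENCE
    baseline_window: int = positional.DEFAULT_BASELINE_WINDOW
    min_effect: float = positional.DEFAULT_MIN_EFFECT
    buried_offset: int = positional.DEFAULT_BURIED_OFFSET
    periodicity_min: float = footprints.DEFAULT_PERIODICITY_MIN
    search_range: tuple[int, int] = footprints.DEFAULT_SEARCH_RANGE
    q_threshold: float = 0.05
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.search_range = tuple(self.search_range)  # type: ignore[assignment]
        if not (0 <= self.theta <= 1):
            raise ConfigError("theta must lie in [0, 1]")
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigError("window must be odd and >= 1")
        if self.buried_offset < 0:
            raise ConfigError("buried_offset must be >= 0")
        # keep the simulation seed slaved to the pipeline seed
        self.simulation.seed = self.seed

    def to_dict(self) -> dict:
        return _listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            targets = sim.pop("engagement_targets", None)
            sim_cfg = SimulationConfig(**sim)
            if targets is not None:
                sim_cfg.engagement_targets = [
                    t if isinstance(t, EngagementTarget) else EngagementTarget(**t)
                    for t in targets
                ]
        else:
            sim_cfg = sim
        try:
            return cls(simulation=sim_cfg, **data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)
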