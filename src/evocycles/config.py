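"""Run configuration: a single JSON-serializable object per CLI run."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .attractor import SolverOptions
from .params import EpiParams, TradeoffParams, n_resident_states
from .presets import load_preset

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run.

    ``task_settings`` holds task-specific knobs (grid sizes, brackets,
    sweep values, evo-sim lattice); ``solver`` the shared ODE settings.
    Round-trips losslessly through JSON.
    """

    variant: str
    epi: EpiParams
    tradeoff: TradeoffParams | None = None
    trait_range: tuple[float, float] = (0.05, 0.5)
    solver: dict = field(default_factory=lambda: {"method": "Radau", "rtol": 1e-10, "atol": 1e-12})
    burn_in: float = 500.0
    samples_per_period: int = 400
    task_settings: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self):
        n_resident_states(self.variant)  # validates the tag
        self.trait_range = tuple(float(x) for x in self.trait_range)
        if not self.trait_range[0] < self.trait_range[1]:
            raise ValueError("trait_range must be an increasing (lo, hi) pair")
        if self.burn_in <= 0:
            raise ValueError("burn_in must be positive")

    def solver_options(self) -> SolverOptions:
        return SolverOptions(**self.solver)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["epi"] = self.epi.to_dict()
        d["tradeoff"] = self.tradeoff.to_dict() if self.tradeoff else None
        d["trait_range"] = list(self.trait_range)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["epi"] = EpiParams.from_dict(d["epi"])
        if d.get("tradeoff"):
            d["tradeoff"] = TradeoffParams.from_dict(d["tradeoff"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "RunConfig":
        pre = load_preset(name)
        cfg = cls(variant=pre.variant, epi=pre.epi, tradeoff=pre.tradeoff,
                  trait_range=pre.trait_range)
        if pre.sweep:
            cfg.task_settings["sweep"] = dict(pre.sweep)
        for k, v in overrides.items():
            if v is not None:
                setattr(cfg, k, v)
        return cfg
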