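"""Named parameter presets for the worked examples.

Each preset bundles a model variant, the epidemiological rates, the
(optional) defence trade-off and a trait range, serialized in
``presets.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .params import EpiParams, TradeoffParams

__all__ = ["Preset", "load_preset", "preset_names"]


@dataclass(frozen=True)
class Preset:
    name: str
    variant: str
    epi: EpiParams
    tradeoff: TradeoffParams | None
    trait_range: tuple[float, float]
    sweep: dict | None
    note: str


def _raw() -> dict:
    with resources.files(__package__).joinpath("presets.json").open() as fh:
        return json.load(fh)


def preset_names() -> list[str]:
    return sorted(_raw())


def load_preset(name: str) -> Preset:
    raw = _raw()
    if name not in raw:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(sorted(raw))}")
    d = raw[name]
    return Preset(
        name=name,
        variant=d["variant"],
        epi=EpiParams.from_dict(d["epi"]),
        tradeoff=TradeoffParams.from_dict(d["tradeoff"]) if d["tradeoff"] else None,
        trait_range=tuple(d["trait_range"]),
        sweep=d.get("sweep"),
        note=d.get("note", ""),
    )
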