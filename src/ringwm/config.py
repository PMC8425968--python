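"""Structured configuration: nested key-value sections mapped to dataclasses.

``default_config()`` reproduces the wild-type condition; a YAML file with
the same section names overrides any subset of fields.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from importlib import resources
from typing import Any, Mapping

import yaml

from ringwm.behavior import MarkovParams
from ringwm.network import (
    CalibrationParams,
    LIFParams,
    StimulationParams,
    SynapseKinetics,
    Topology,
    WeightTable,
)
from ringwm.protocol import ProtocolSpec

__all__ = ["SimulationConfig", "default_config", "load_config", "dump_config"]


@dataclass(frozen=True)
class SimulationConfig:
    lif: LIFParams = field(default_factory=LIFParams)
    nmda: SynapseKinetics = field(default_factory=lambda: SynapseKinetics("NMDA", 100.0, 0.0))
    gaba: SynapseKinetics = field(default_factory=lambda: SynapseKinetics("GABA", 10.0, -70.0))
    topology: Topology = field(default_factory=Topology)
    stimulation: StimulationParams = field(default_factory=StimulationParams)
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    markov: MarkovParams = field(default_factory=MarkovParams)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    weights: Mapping[str, float] | None = None  # "EIP->PEI:uniform" -> weight overrides

    @property
    def kinetics(self) -> dict[str, SynapseKinetics]:
        return {"NMDA": self.nmda, "GABA": self.gaba}

    def weight_table(self) -> WeightTable:
        if not self.weights:
            return WeightTable()
        entries = dict(WeightTable().entries)
        for key, w in self.weights.items():
            src_dst, cls = key.split(":")
            src, dst = src_dst.split("->")
            entries[(src.strip(), dst.strip(), cls.strip())] = float(w)
        return WeightTable(entries)

    def build_network(self, seed: int = 0):
        from ringwm.network import build_network

        return build_network(
            self.weight_table(), self.topology, self.lif, self.kinetics, self.calibration, seed
        )


def default_config() -> SimulationConfig:
    return SimulationConfig()


_SECTIONS = {
    "lif": LIFParams,
    "nmda": SynapseKinetics,
    "gaba": SynapseKinetics,
    "topology": Topology,
    "stimulation": StimulationParams,
    "calibration": CalibrationParams,
    "markov": MarkovParams,
    "protocol": ProtocolSpec,
}


def _coerce(cls, data: Mapping[str, Any]):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} for section {cls.__name__}")
    coerced = {}
    for k, v in data.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return coerced


def load_config(path=None) -> SimulationConfig:
    """Load a YAML config; missing sections/fields fall back to defaults."""
    if path is None:
        text = resources.files("ringwm").joinpath("data/default.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or {}
    cfg = default_config()
    updates: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        if name in raw and raw[name]:
            base = getattr(cfg, name)
            updates[name] = replace(base, **_coerce(cls, raw[name]))
    if raw.get("weights"):
        updates["weights"] = dict(raw["weights"])
    return replace(cfg, **updates)


def dump_config(cfg: SimulationConfig) -> str:
    out: dict[str, Any] = {}
    for name in _SECTIONS:
        out[name] = asdict(getattr(cfg, name))
    if cfg.weights:
        out["weights"] = dict(cfg.weights)
    return yaml.safe_dump(out, sort_keys=False)
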