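"""Declarative YAML configuration for simulations.

One YAML document configures the pendulum, the end-effector admittance, the
three controllers, the participant and the protocol.  Any omitted key falls
back to the package default, so a minimal file only states deviations.
``dump_default_config`` writes a fully commented reference file.
"""

from __future__ import annotations

from dataclasses import asdict, fields, replace
from pathlib import Path

import yaml

from .assistance import HgConfig, MpcConfig
from .dynamics import AssistPoint, EndEffectorModel, PendulumParams
from .participant import PRESETS, ParticipantParams
from .protocol import Group, ProtocolConfig

__all__ = ["SimulationConfig", "load_config", "dump_default_config"]


class SimulationConfig:
    """Bundle of all configurable objects for a run."""

    def __init__(self,
                 pendulum: PendulumParams | None = None,
                 ee_model: EndEffectorModel | None = None,
                 ee_mpc: MpcConfig | None = None,
                 ball_mpc: MpcConfig | None = None,
                 hg: HgConfig | None = None,
                 participant: ParticipantParams | None = None,
                 protocol: ProtocolConfig | None = None):
        self.pendulum = pendulum or PendulumParams()
        self.ee_model = ee_model or EndEffectorModel()
        self.ee_mpc = ee_mpc or MpcConfig.for_end_effector()
        self.ball_mpc = ball_mpc or MpcConfig.for_ball()
        self.hg = hg or HgConfig()
        self.participant = participant or PRESETS["novice"]
        self.protocol = protocol or ProtocolConfig()

    def to_dict(self) -> dict:
        d = {
            "pendulum": asdict(self.pendulum),
            "ee_model": asdict(self.ee_model),
            "ee_mpc": asdict(self.ee_mpc),
            "ball_mpc": asdict(self.ball_mpc),
            "hg": asdict(self.hg),
            "participant": asdict(self.participant),
            "protocol": asdict(self.protocol),
        }
        d["ee_mpc"]["application_point"] = self.ee_mpc.application_point.value
        d["ball_mpc"]["application_point"] = self.ball_mpc.application_point.value
        d["protocol"]["group"] = self.protocol.group.value
        return d


def _build(cls, defaults, data: dict, converters=None):
    converters = converters or {}
    kwargs = {f.name: getattr(defaults, f.name) for f in fields(cls)}
    for key, val in (data or {}).items():
        if key not in kwargs:
            raise KeyError(f"unknown {cls.__name__} key: {key}")
        kwargs[key] = converters.get(key, lambda v: v)(val)
    return cls(**kwargs)


def load_config(path) -> SimulationConfig:
    """Load a (possibly partial) YAML configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    participant_raw = raw.get("participant")
    if isinstance(participant_raw, str):
        participant = PRESETS[participant_raw]
    else:
        participant = _build(ParticipantParams, ParticipantParams(),
                             participant_raw)
    point = {"application_point": AssistPoint}
    return SimulationConfig(
        pendulum=_build(PendulumParams, PendulumParams(), raw.get("pendulum")),
        ee_model=_build(EndEffectorModel, EndEffectorModel(), raw.get("ee_model")),
        ee_mpc=_build(MpcConfig, MpcConfig.for_end_effector(), raw.get("ee_mpc"),
                      {"application_point": AssistPoint}),
        ball_mpc=_build(MpcConfig, MpcConfig.for_ball(), raw.get("ball_mpc"),
                        {"application_point": AssistPoint}),
        hg=_build(HgConfig, HgConfig(), raw.get("hg")),
        participant=participant,
        protocol=_build(ProtocolConfig, ProtocolConfig(), raw.get("protocol"),
                        {"group": Group}),
    )


def dump_default_config(path) -> None:
    """Write the full default configuration as a reference YAML file."""
    cfg = SimulationConfig()
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
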