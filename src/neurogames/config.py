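"""Flat YAML configuration: one section per game or agent block.

Every field has a default (the dataclass defaults); unknown sections or
keys are an error, so typos fail loudly instead of silently running the
wrong experiment.
"""

from __future__ import annotations

import dataclasses

import yaml

from .actor_critic import ACParams
from .cognitive_model import MixtureSpec
from .experiments import AgentSpec, ExperimentConfig
from .games import ChickenConfig, HawkDoveConfig, StagHuntConfig
from .neural_agent import NetworkParams

_SECTIONS = {
    "hawk_dove": HawkDoveConfig,
    "chicken": ChickenConfig,
    "stag_hunt": StagHuntConfig,
    "network": NetworkParams,
    "actor_critic": ACParams,
    "mixture": MixtureSpec,
    "agent1": AgentSpec,
    "agent2": AgentSpec,
}

_EXPERIMENT_KEYS = ("game", "n_rounds", "seed")


def _build(cls, section: str, values: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - fields
    if unknown:
        raise ValueError(
            f"unknown keys in section {section!r}: {sorted(unknown)}"
        )
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in values:
            continue
        v = values[f.name]
        coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path) -> ExperimentConfig:
    """Read an experiment configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS) - set(_EXPERIMENT_KEYS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs: dict = {}
    for key in _EXPERIMENT_KEYS:
        if key in raw:
            kwargs[key] = raw[key]
    for section, cls in _SECTIONS.items():
        if section in raw:
            values = raw[section]
            if isinstance(values, str):  # shorthand: agent1: wsls
                values = {"kind": values}
            if not isinstance(values, dict):
                raise ValueError(f"section {section!r} must be a mapping")
            kwargs[section] = _build(cls, section, values)
    kwargs.pop("mixture", None)  # fit-time option, not part of a session
    if "game" not in kwargs:
        raise ValueError("config must name a game")
    if "agent1" not in kwargs or "agent2" not in kwargs:
        raise ValueError("config must define agent1 and agent2")
    return ExperimentConfig(**kwargs)


def load_mixture_spec(path) -> MixtureSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    section = raw.get("mixture", {})
    return _build(MixtureSpec, "mixture", section)
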