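"""Shared YAML/JSON configuration schema.

A config file may carry any of the blocks below; each loader returns the
corresponding domain object with unspecified fields at their defaults.

```yaml
theory:            # K, n, S, dLV, dLA, dN, sigma, epsilon
  K: 2
  n: 2
  S: 2
  dLV: 1.0
  dN: 0.8
  sigma: 0.5
task:              # TaskConfig fields
  n_trials: 2000
agent:             # SubjectiveValueModel fields
  temperature: 33.0
session:           # GenerativeSession fields (task/agent blocks nest inside)
  n_neurons: 100
```
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .behavior_model import SubjectiveValueModel
from .synthetic_data import GenerativeSession, TaskConfig
from .theory import CodeParams, StimulusSpec

__all__ = [
    "load_config",
    "theory_from_config",
    "task_from_config",
    "agent_from_config",
    "session_from_config",
]


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def theory_from_config(cfg: dict) -> tuple[StimulusSpec, CodeParams]:
    block = cfg.get("theory", {})
    spec = StimulusSpec(
        K=int(block.get("K", 2)), n=int(block.get("n", 2)), S=int(block.get("S", 1))
    )
    params = CodeParams(
        dLV=float(block.get("dLV", 1.0)),
        dLA=float(block.get("dLA", block.get("dLV", 1.0))),
        dN=float(block.get("dN", 1.0)),
        sigma=float(block.get("sigma", 0.5)),
        epsilon=float(block.get("epsilon", 0.0)),
    )
    return spec, params


def task_from_config(cfg: dict) -> TaskConfig:
    block = dict(cfg.get("task", {}))
    if "type_probs" in block:
        block["type_probs"] = tuple(block["type_probs"])
    return TaskConfig(**block)


def agent_from_config(cfg: dict) -> SubjectiveValueModel:
    return SubjectiveValueModel(**cfg.get("agent", {}))


def session_from_config(cfg: dict) -> GenerativeSession:
    block = dict(cfg.get("session", {}))
    block["task"] = task_from_config(cfg)
    block["agent"] = agent_from_config(cfg)
    return GenerativeSession(**block)
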