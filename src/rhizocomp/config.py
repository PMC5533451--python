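"""YAML configuration loading for scenario sweeps.

Schema::

    model:                 # optional ModelParams overrides
      grid_shape: [51, 51]
      max_biomass: 200.0
    scenarios:
      - annual_precip_mm: 350
        interval_days: 7
        trait_on: true
        n_steps: 1825
        n_reps: 10
        base_seed: 1
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .ibm import ModelParams
from .scenarios import Scenario

__all__ = ["load_config"]

_MODEL_FIELDS = {f.name for f in fields(ModelParams)}
_SCENARIO_FIELDS = {"annual_precip_mm", "interval_days", "trait_on",
                    "n_steps", "n_reps", "base_seed"}


def load_config(path) -> list[Scenario]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    model_block = doc.get("model", {})
    unknown = set(model_block) - _MODEL_FIELDS
    if unknown:
        raise ValueError(f"unknown model parameters: {sorted(unknown)}")
    if "grid_shape" in model_block:
        model_block["grid_shape"] = tuple(model_block["grid_shape"])
    model = ModelParams(**model_block)

    scenarios = []
    for block in doc.get("scenarios", []):
        unknown = set(block) - _SCENARIO_FIELDS
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        scenarios.append(Scenario(model=model, **block))
    if not scenarios:
        raise ValueError("configuration lists no scenarios")
    return scenarios
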