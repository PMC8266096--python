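"""Run configuration: YAML loading, validation and echo.

A configuration file is a flat YAML mapping. Keys are either model
parameter names (any field of :class:`~angiosim.parameters.Parameters`)
or run-control keys (``seed``, ``seeds``, ``n_steps``, ``output_dir``,
``snapshot_interval``). Unknown keys are rejected by name, so typos
cannot silently fall back to defaults. An empty file yields the
reference parameter set.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .parameters import Parameters

__all__ = ["RunConfig", "load_config", "save_config"]

_RUN_KEYS = ("seed", "seeds", "n_steps", "output_dir", "snapshot_interval")


@dataclass
class RunConfig:
    params: Parameters = field(default_factory=Parameters)
    seed: int = 1
    seeds: list[int] = field(default_factory=list)
    n_steps: int | None = None
    output_dir: str = "out"
    snapshot_interval: int = 20

    def seed_list(self) -> list[int]:
        return list(self.seeds) if self.seeds else [self.seed]

    def to_dict(self) -> dict:
        d = dict(asdict(self.params))
        d.update(seed=self.seed, seeds=list(self.seeds),
                 n_steps=self.n_steps, output_dir=self.output_dir,
                 snapshot_interval=self.snapshot_interval)
        return d


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; missing keys default to the reference values.

    Raises ValueError naming the first unknown key encountered.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a mapping")
        raw.update(loaded)
    if overrides:
        raw.update(overrides)
    known_params = set(Parameters.field_names())
    param_kwargs, run_kwargs = {}, {}
    for key, value in raw.items():
        if key in known_params:
            param_kwargs[key] = value
        elif key in _RUN_KEYS:
            run_kwargs[key] = value
        else:
            raise ValueError(f"unknown configuration key: {key!r}")
    return RunConfig(params=Parameters(**param_kwargs), **run_kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write the full (defaulted) configuration as YAML."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def echo_run_json(config: RunConfig, path: str | Path, seed: int) -> None:
    """Write the config echo (run.json) sufficient to reproduce a run."""
    d = config.to_dict()
    d["seed"] = seed
    Path(path).write_text(json.dumps(d, indent=2, default=str))
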