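"""Run configuration: seeded, validated, file-round-trippable experiment specs.

A run config is a YAML document with an experiment name, a master seed, and
per-module parameter blocks::

    experiment: table1-strains
    seed: 17
    out_dir: results
    switch:
      n_colonies: 200000
      n_replicates: 3
      defaults: {generations: 14}
      strains:
        wild_type: {p_div: 0.00158}
        sir1_null: {p_div: 0.055}
    fish:
      n_stacks: 3
      stack: {n_cells: 30}
      strains:
        sir4_null:
          channel_a: {family: negbin, mean: 12, variance: 53}
          channel_b: {family: poisson, mean: 7.3}
    caller: {k_mad: 8.0, min_size: 4, max_size: 200}

Validation errors carry the path of the offending field. Identical configs
produce byte-identical outputs: all per-stage generators derive from the
master seed, and every output CSV records the config hash in a header comment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "config_hash", "write_csv"]


@dataclass
class RunConfig:
    experiment: str
    seed: int
    out_dir: str = "results"
    switch: dict = field(default_factory=dict)
    fish: dict = field(default_factory=dict)
    caller: dict = field(default_factory=dict)
    plate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.experiment:
            raise ConfigError("experiment: a name is required")
        if self.seed is None or int(self.seed) != self.seed:
            raise ConfigError("seed: an explicit integer seed is required")
        for block in ("switch", "fish", "caller", "plate"):
            v = getattr(self, block)
            if v is None:
                setattr(self, block, {})
            elif not isinstance(v, dict):
                raise ConfigError(f"{block}: must be a mapping")
        self._validate_switch()
        self._validate_fish()

    def _validate_switch(self) -> None:
        from .colony import SwitchParams

        blk = self.switch
        if not blk:
            return
        strains = blk.get("strains", {})
        if not isinstance(strains, dict):
            raise ConfigError("switch.strains: must be a mapping of name -> parameters")
        defaults = blk.get("defaults", {})
        for name, params in strains.items():
            if not isinstance(params, dict) or "p_div" not in params:
                raise ConfigError(f"switch.strains.{name}.p_div: required")
            try:
                SwitchParams.from_dict({**defaults, **params})
            except ValueError as exc:
                raise ConfigError(f"switch.strains.{name}: {exc}") from exc
        for key, lo in (("n_colonies", 1), ("n_replicates", 1)):
            v = blk.get(key)
            if v is not None and (int(v) != v or v < lo):
                raise ConfigError(f"switch.{key}: must be an integer >= {lo}")

    def _validate_fish(self) -> None:
        from .fish_synth import CountModel, StackSpec

        blk = self.fish
        if not blk:
            return
        stack = blk.get("stack", {})
        try:
            spec = StackSpec(**{**{}, **stack})
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"fish.stack: {exc}") from exc
        if spec.n_cells < 1:
            raise ConfigError("fish.stack.n_cells: must be >= 1")
        for name, channels in blk.get("strains", {}).items():
            for ch in ("channel_a", "channel_b"):
                if ch not in channels:
                    raise ConfigError(f"fish.strains.{name}.{ch}: required")
                try:
                    CountModel.from_dict(channels[ch])
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"fish.strains.{name}.{ch}: {exc}") from exc

    def switch_params(self, strain: str):
        """Materialize SwitchParams for one configured strain."""
        from .colony import SwitchParams

        blk = self.switch
        return SwitchParams.from_dict({**blk.get("defaults", {}), **blk["strains"][strain]})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        if "experiment" not in d:
            raise ConfigError("experiment: required")
        if "seed" not in d:
            raise ConfigError("seed: an explicit seed is required")
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return RunConfig.from_dict(data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonicalized config."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df, path, config: RunConfig | None = None) -> None:
    """Write a CSV, prefixed with a config-hash header comment when available."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# experiment={config.experiment} seed={config.seed} config_hash={config_hash(config)}\n")
        df.to_csv(fh, index=False)
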