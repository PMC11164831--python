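"""Run configuration: defaults, file/override resolution, hashing.

Defaults reproduce the published operating point — embedding width 512,
learning rate 0.1, 8 attention heads, 3 GCN layers, 3 interactive attention
layers, 3 MLP layers — with every toggle (view attention, interactive
attention, the three network types, fusion strategy, literal-mode flags)
exposed as a config key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

FUSION_STRATEGIES = ("attention", "ave", "pro")


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass
class RunConfig:
    # model shape
    embed_dim: int = 512          # F_m
    heads: int = 8
    gcn_layers: int = 3
    ia_layers: int = 3
    mlp_layers: int = 3
    dropout: float = 0.1
    # optimisation
    lr: float = 0.1
    epochs: int = 1000
    lr_decay: bool = True         # 10x decay when the training loss plateaus
    patience: int = 25
    # fusion stage
    fusion_strategy: str = "attention"
    fusion_dim: int | None = None  # defaults to embed_dim
    fusion_epochs: int = 500
    fusion_lr: float = 0.01
    # evaluation protocol
    ratio: int = 1
    n_folds: int = 5
    threshold: float = 0.5
    seed: int = 0
    # toggles
    va: bool = True
    ia: bool = True
    use_homo: bool = True
    use_bi: bool = True
    use_hete: bool = True
    mask_test_edges: bool = True
    # literal-mode escape hatches
    literal_pro: bool = False
    literal_tanh: bool = False
    attn_wrap: str = "literal"

    def __post_init__(self):
        if self.embed_dim % self.heads != 0:
            raise ConfigError(
                f"embed_dim={self.embed_dim} not divisible by heads={self.heads}")
        if self.fusion_strategy not in FUSION_STRATEGIES:
            raise ConfigError(
                f"fusion_strategy must be one of {FUSION_STRATEGIES}")
        if self.attn_wrap not in ("literal", "standard"):
            raise ConfigError("attn_wrap must be 'literal' or 'standard'")
        if self.ratio < 1 or self.gcn_layers < 1 or self.ia_layers < 0:
            raise ConfigError("ratio/gcn_layers must be >= 1, ia_layers >= 0")
        if not (self.use_homo or self.use_bi or self.use_hete):
            raise ConfigError(
                "degenerate configuration: enable at least one of "
                "use_homo/use_bi/use_hete")
        if self.fusion_dim is None:
            self.fusion_dim = self.embed_dim

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kw) -> "RunConfig":
        return resolve_config(overrides={**self.to_dict(), **kw})


def _valid_keys() -> set[str]:
    return {f.name for f in dataclasses.fields(RunConfig)}


def resolve_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Defaults ← YAML file ← explicit overrides, with unknown keys a hard
    error naming the valid ones."""
    merged: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config file must be a mapping")
        merged.update(loaded)
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})
    valid = _valid_keys()
    unknown = sorted(set(merged) - valid)
    if unknown:
        raise ConfigError(
            f"unknown config keys {unknown}; valid keys: {sorted(valid)}")
    return RunConfig(**merged)


def save_config(config: RunConfig, path) -> None:
    """Echo the resolved config (plus its hash) beside the outputs."""
    doc = config.to_dict()
    doc["config_hash"] = config.config_hash
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
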