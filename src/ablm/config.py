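"""Run configuration: nested YAML sections mapped onto module configs.

Unknown keys are rejected with the full key path; values are validated by
the target config dataclasses.  The resolved config is echo-written into
every run directory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .encoder import EncoderConfig
from .heads import BindingHeadConfig, PairingHeadConfig
from .masking import MaskingConfig
from .pretrain import TrainConfig
from .synth import GrammarConfig

__all__ = ["RunConfig", "parse_config", "write_config"]


@dataclass(frozen=True)
class RunConfig:
    grammar: GrammarConfig = field(default_factory=GrammarConfig)
    masking: MaskingConfig = field(default_factory=MaskingConfig)
    model: EncoderConfig = field(default_factory=EncoderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    pairing: PairingHeadConfig = field(default_factory=PairingHeadConfig)
    binding: BindingHeadConfig = field(default_factory=BindingHeadConfig)
    seed: int = 0
    out_dir: str = "runs/run"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        out: dict = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                out[f.name] = {
                    sf.name: _plain(getattr(v, sf.name)) for sf in dataclasses.fields(v)
                }
            else:
                out[f.name] = _plain(v)
        return out


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    return v


def _coerce(value, path: str):
    # YAML has no tuple; every sequence-valued config field is a tuple
    if isinstance(value, list):
        return tuple(_coerce(v, path) for v in value)
    return value


def _build(cls, section: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in section.items():
        if key not in fields:
            raise ValueError(f"unknown config key {path}.{key}")
        kwargs[key] = _coerce(value, f"{path}.{key}")
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid value under {path}: {exc}") from exc


def parse_config(path) -> RunConfig:
    """Load a YAML/JSON run config; an empty file yields all defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    sections = {
        "grammar": GrammarConfig,
        "masking": MaskingConfig,
        "model": EncoderConfig,
        "train": TrainConfig,
        "pairing": PairingHeadConfig,
        "binding": BindingHeadConfig,
    }
    kwargs: dict = {}
    for key, value in raw.items():
        if key in sections:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key} must be a mapping")
            kwargs[key] = _build(sections[key], value, key)
        elif key in ("seed", "out_dir", "log_level"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key {key}")
    return RunConfig(**kwargs)


def write_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
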