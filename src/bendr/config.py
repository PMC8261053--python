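"""Declarative run configuration and run manifests.

A run is described by a single YAML file with sections
{data, encoder, contextualizer, pretrain, finetune, eval}; unknown sections
or keys are hard errors (silent hyperparameter typos are the chief
reproducibility hazard).  Every command writes exactly one JSON manifest
recording the resolved configuration, seed, package version and output
paths, from which evaluation-mode outputs are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path

import yaml

from .contextualizer import ContextualizerConfig
from .encoder import EncoderConfig
from .evaluation import DownstreamRegConfig, FinetuneConfig
from .pretraining import PretrainConfig
from .synthetic import ClassEffect, Oscillation, SynthConfig

__all__ = ["RunConfig", "load_config", "write_manifest", "setup_logging"]

_SECTION_TYPES = {
    "data": SynthConfig,
    "encoder": EncoderConfig,
    "contextualizer": ContextualizerConfig,
    "pretrain": PretrainConfig,
    "finetune": FinetuneConfig,
    "eval": None,  # free-form: lengths_s, n_windows, ...
    "effect": ClassEffect,
    "regularization": DownstreamRegConfig,
}

_EVAL_KEYS = {"lengths_s", "variant", "n_folds", "n_windows", "window_s"}


@dataclasses.dataclass
class RunConfig:
    data: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    encoder: EncoderConfig = dataclasses.field(default_factory=EncoderConfig)
    contextualizer: ContextualizerConfig = dataclasses.field(
        default_factory=ContextualizerConfig)
    pretrain: PretrainConfig = dataclasses.field(default_factory=PretrainConfig)
    finetune: FinetuneConfig = dataclasses.field(default_factory=FinetuneConfig)
    effect: ClassEffect = dataclasses.field(default_factory=ClassEffect)
    regularization: DownstreamRegConfig = dataclasses.field(
        default_factory=DownstreamRegConfig)
    eval: dict = dataclasses.field(default_factory=dict)


def _build_section(cls, payload: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ValueError(
            f"unknown keys in config section '{section}': {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in payload:
            continue
        val = payload[f.name]
        if isinstance(val, list):
            val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        coerced[f.name] = val
    if cls is SynthConfig and "oscillations" in coerced:
        coerced["oscillations"] = tuple(
            Oscillation(**dict(o)) if isinstance(o, dict) else Oscillation(*o)
            for o in payload["oscillations"])
    return cls(**coerced)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for section, payload in raw.items():
        if section == "eval":
            bad = set(payload) - _EVAL_KEYS
            if bad:
                raise ValueError(f"unknown keys in config section 'eval': "
                                 f"{sorted(bad)}")
            kwargs["eval"] = dict(payload)
        else:
            kwargs[section] = _build_section(_SECTION_TYPES[section], payload,
                                             section)
    return RunConfig(**kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_manifest(out_dir, command: str, cfg: RunConfig, seed: int,
                   outputs: dict) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": _jsonable(cfg),
        "outputs": _jsonable(outputs),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def setup_logging(out_dir=None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "run.log"))
    logging.basicConfig(
        level=level, handlers=handlers, force=True,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")
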