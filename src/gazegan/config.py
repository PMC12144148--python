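"""Run configuration: one place where all defaults live.

A run config is a nested mapping (YAML on disk) with sections mirroring the
simulator, architecture, training, HMM and evaluation settings plus a global
seed and output directory.  Unknown keys are rejected with a message naming
every offending key; command-line flag overrides are applied after the file.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .gan import ArchitectureSpec
from .simulate import ScanpathConfig
from .training import Hyperparameters


@dataclass(frozen=True)
class HMMSettings:
    n_states: int = 4
    candidates: tuple = (2, 3, 4, 5)
    tol: float = 1e-4
    max_iter: int = 500
    n_restarts: int = 5
    sample_length: int | None = None


@dataclass(frozen=True)
class EvalSettings:
    n_bins: int = 100
    max_lag: int = 50
    integral_start: int = 100
    integral_end: int = 500
    kurtosis_convention: str = "excess"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    simulate: ScanpathConfig = field(default_factory=ScanpathConfig)
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    train: Hyperparameters = field(default_factory=Hyperparameters)
    hmm: HMMSettings = field(default_factory=HMMSettings)
    evaluation: EvalSettings = field(default_factory=EvalSettings)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["architecture"]["cnn_channels"] = list(self.architecture.cnn_channels)
        d["hmm"]["candidates"] = list(self.hmm.candidates)
        return d


_SECTIONS = {
    "simulate": ScanpathConfig,
    "architecture": ArchitectureSpec,
    "train": Hyperparameters,
    "hmm": HMMSettings,
    "evaluation": EvalSettings,
}
_TUPLE_FIELDS = {("architecture", "cnn_channels"), ("hmm", "candidates")}


def _build_section(name: str, cls, values: dict, errors: list):
    known = {f.name for f in dataclasses.fields(cls)}
    clean = {}
    for key, val in values.items():
        if key not in known:
            errors.append(f"{name}.{key}")
            continue
        if (name, key) in _TUPLE_FIELDS and isinstance(val, list):
            val = tuple(val)
        clean[key] = val
    return clean


def parse_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a fully resolved RunConfig: package defaults, then the file,
    then flag overrides (`{"section.key": value}` or top-level `{"seed": 3}`)."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw = loaded
    for dotted, value in (overrides or {}).items():
        if value is None:
            continue
        if "." in dotted:
            section, key = dotted.split(".", 1)
            raw.setdefault(section, {})
            if not isinstance(raw[section], dict):
                raise ConfigError(f"section {section!r} is not a mapping")
            raw[section][key] = value
        else:
            raw[dotted] = value

    errors: list[str] = []
    kwargs = {}
    for name, value in raw.items():
        if name in ("seed", "out_dir"):
            kwargs[name] = value
        elif name in _SECTIONS:
            if not isinstance(value, dict):
                errors.append(name)
                continue
            kwargs[name] = _build_section(name, _SECTIONS[name], value, errors)
        else:
            errors.append(name)
    if errors:
        raise ConfigError(f"unknown configuration keys: {', '.join(sorted(errors))}")

    sections = {}
    for name, cls in _SECTIONS.items():
        sections[name] = cls(**kwargs.get(name, {}))
    return RunConfig(seed=int(kwargs.get("seed", 0)),
                     out_dir=str(kwargs.get("out_dir", "runs")), **sections)


def write_manifest(out_dir, command: str, cfg: RunConfig, extra: dict | None = None):
    """Echo the fully resolved config plus environment versions next to the
    artifacts a command produced."""
    import numpy
    import scipy

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": cfg.to_dict(),
        "versions": {"gazegan": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__, "python": platform.python_version()},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / f"manifest_{command}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
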