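"""Run configuration: YAML loading with strict key checking.

A run configuration names exactly one morphology source (an SWC path or
synthetic-generation parameters), optional overrides of the membrane and
efferent geometry defaults, a protocol, an output directory and a seed.
Defaults are the model's basal values (dt 0.025 ms, 300 ms settling, the
published density tables); unknown keys are rejected with the list of valid
ones so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .builder import EfferentSpec, RegionMembraneSpec
from .synth import SynthMorphParams

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Unknown key, type mismatch, or inconsistent morphology source."""


@dataclass
class RunConfig:
    """Validated configuration for one simulation run."""

    swc_path: str | None = None
    synth: SynthMorphParams | None = None
    efferent: EfferentSpec = field(default_factory=EfferentSpec)
    membrane: RegionMembraneSpec = field(default_factory=RegionMembraneSpec)
    dt: float = 0.025  # ms
    t_settle: float = 300.0  # ms
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self):
        if self.swc_path is not None and self.synth is not None:
            raise ConfigError("give either swc_path or synth, not both")
        if self.swc_path is None and self.synth is None:
            self.synth = SynthMorphParams(seed=self.seed)


_TOP_KEYS = {"swc_path", "synth", "efferent", "membrane", "dt", "t_settle",
             "outdir", "seed"}


def _build_dataclass(cls, data: dict, where: str):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in valid:
            raise ConfigError(
                f"unknown key {key!r} in {where}; valid keys: "
                f"{sorted(valid)}")
        f = valid[key]
        if f.type in ("float", float) and isinstance(val, (int, float)):
            val = float(val)
        elif f.type in ("int", int):
            if not isinstance(val, int):
                raise ConfigError(f"{where}.{key}: expected int, got "
                                  f"{type(val).__name__}")
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full default configuration.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    for key in doc:
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown key {key!r}; valid keys: "
                              f"{sorted(_TOP_KEYS)}")
    kwargs: dict = {}
    if "swc_path" in doc:
        kwargs["swc_path"] = str(doc["swc_path"])
    if "synth" in doc:
        kwargs["synth"] = _build_dataclass(SynthMorphParams, doc["synth"],
                                           "synth")
    if "efferent" in doc:
        kwargs["efferent"] = _build_dataclass(EfferentSpec, doc["efferent"],
                                              "efferent")
    if "membrane" in doc:
        mem = dict(doc["membrane"])
        simple = {}
        for key in list(mem):
            if key in ("ais_gna_mS", "soma_gna_mS"):
                simple[key] = float(mem.pop(key))
        base = _build_dataclass(RegionMembraneSpec, mem, "membrane")
        if "ais_gna_mS" in simple:
            base = base.with_ais_gna(simple["ais_gna_mS"])
        if "soma_gna_mS" in simple:
            base = base.with_soma_gna(simple["soma_gna_mS"])
        kwargs["membrane"] = base
    for key in ("dt", "t_settle"):
        if key in doc:
            kwargs[key] = float(doc[key])
    if "outdir" in doc:
        kwargs["outdir"] = str(doc["outdir"])
    if "seed" in doc:
        if not isinstance(doc["seed"], int):
            raise ConfigError("seed must be an integer")
        kwargs["seed"] = doc["seed"]
    return RunConfig(**kwargs)
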