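"""Strict pipeline configuration.

A single YAML document configures a full run: either a generator preset (with
parameter overrides) or input topology/trajectory paths, stage toggles, and
per-stage parameter blocks.  Validation is strict — unknown keys are errors
(with a nearest-key suggestion), invalid values fail fast naming the full key
path — so a typo can never silently fall back to a default.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import ConfigError

# schema: key -> (default, validator); validators raise ValueError
_POS = ("positive number", lambda v: isinstance(v, (int, float)) and v > 0)
_NONNEG = ("non-negative number",
           lambda v: isinstance(v, (int, float)) and v >= 0)
_BOOL = ("boolean", lambda v: isinstance(v, bool))
_INT = ("integer", lambda v: isinstance(v, int) and not isinstance(v, bool))
_STR = ("string", lambda v: isinstance(v, str))


def _choice(*opts):
    return (f"one of {opts}", lambda v: v in opts)


_FRACTION = ("number in [0, 1]",
             lambda v: isinstance(v, (int, float)) and 0 <= v <= 1)

SCHEMA: dict[str, dict[str, tuple]] = {
    "": {
        "preset": (None, _choice("desk", "paper_scale", None)),
        "seed": (0, _INT),
        "out_dir": ("lipidring_out", _STR),
        "log_level": ("INFO", _choice("DEBUG", "INFO", "WARNING", "ERROR")),
    },
    "input": {
        "topology": (None, _STR),
        "trajectory": (None, _STR),
    },
    "stages": {
        "leaflets": (True, _BOOL),
        "rdf": (True, _BOOL),
        "density": (True, _BOOL),
        "contacts": (True, _BOOL),
        "enrichment": (True, _BOOL),
        "curvature": (True, _BOOL),
    },
    "generator": {
        "cl_attraction_depth": (4.0, _NONNEG),
        "cl_attraction_width": (2.0, _POS),
        "invagination_amplitude": (0.7, _NONNEG),
        "invagination_width": (5.0, _POS),
        "ramp": (0.5, _FRACTION),
        "bound_fraction": (0.0, _FRACTION),
        "bound_distance": (0.5, _NONNEG),
        "n_frames": (None, _INT),
        "stride": (None, _POS),
        "z_noise": (0.1, _NONNEG),
    },
    "leaflets": {
        "radius": (3.0, _POS),
        "min_neighbors": (10, _INT),
    },
    "rdf": {
        "r_max": (1.5, _POS),
        "bin_width": (0.02, _POS),
        "leaflet": ("both", _choice("upper", "lower", "both")),
        "shell_normalization": ("exact_shell",
                                _choice("exact_shell", "midpoint_4pir2")),
        "cl_single_bead": (False, _BOOL),
    },
    "density": {
        "cell": (0.5, _POS),
        "leaflet": ("upper", _choice("upper", "lower")),
        "species": ("CL", _choice("CL", "POPC", "POPE", "PC+PE")),
    },
    "contacts": {
        "cutoff": (0.6, _POS),
        "sample_stride": (1.0, _POS),
    },
    "enrichment": {
        "margin": (0.0, _NONNEG),
    },
    "curvature": {
        "cell": (0.5, _POS),
        "leaflet": ("upper", _choice("upper", "lower")),
        "smooth": (False, _BOOL),
    },
}


@dataclass
class PipelineConfig:
    """Fully resolved configuration; ``blocks`` mirrors the schema sections."""

    blocks: dict[str, dict]

    def __getitem__(self, section: str) -> dict:
        return self.blocks[section]

    @property
    def seed(self) -> int:
        return self.blocks[""]["seed"]

    @property
    def preset(self) -> str | None:
        return self.blocks[""]["preset"]

    @property
    def out_dir(self) -> Path:
        return Path(self.blocks[""]["out_dir"])


def _suggest(key: str, candidates) -> str:
    near = difflib.get_close_matches(key, list(candidates), n=1)
    return f"; did you mean {near[0]!r}?" if near else ""


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse + validate YAML text (or a pre-parsed mapping).

    Returns a config with every default filled in.  Raises
    :class:`ConfigError` naming the offending key path on any problem.
    """
    if isinstance(raw, str):
        try:
            doc = yaml.safe_load(raw) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"config is not valid YAML: {e}") from e
    else:
        doc = dict(raw)
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")

    blocks: dict[str, dict] = {sec: {} for sec in SCHEMA}
    top_keys = set(SCHEMA[""]) | {s for s in SCHEMA if s}
    for key, val in doc.items():
        if key in SCHEMA[""]:
            blocks[""][key] = val
        elif key in SCHEMA and key != "":
            if not isinstance(val, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for sub, sval in val.items():
                if sub not in SCHEMA[key]:
                    raise ConfigError(
                        f"unknown key {key}.{sub}"
                        f"{_suggest(sub, SCHEMA[key])}")
                blocks[key][sub] = sval
        else:
            raise ConfigError(f"unknown key {key!r}{_suggest(key, top_keys)}")

    for sec, keys in SCHEMA.items():
        for sub, (default, (desc, check)) in keys.items():
            path = f"{sec}.{sub}" if sec else sub
            if sub not in blocks[sec]:
                blocks[sec][sub] = default
            val = blocks[sec][sub]
            if val is None and default is None:
                continue
            if not check(val):
                raise ConfigError(f"invalid value for {path}: {val!r} "
                                  f"(expected {desc})")

    has_input = any(blocks["input"].values())
    has_preset = blocks[""]["preset"] is not None
    if has_input and has_preset:
        raise ConfigError(
            "config must specify exactly one of input.* or preset, not both")
    if not has_input and not has_preset:
        raise ConfigError(
            "config must specify an input trajectory or a generator preset")
    if has_input:
        for k in ("topology", "trajectory"):
            p = blocks["input"][k]
            if p is None:
                raise ConfigError(f"input.{k} is required when preset is unset")
            if not Path(p).exists():
                raise ConfigError(f"input.{k}: path {p!r} does not exist")
    return PipelineConfig(blocks=blocks)
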