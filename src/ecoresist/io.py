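"""Configuration, manifests and delimited-text writers shared by the CLI.

Every run writes a ``manifest.json`` echoing the fully resolved
configuration (including defaults and the seed) plus the package version;
feeding a manifest's ``config`` block back through :func:`read_config`
reproduces the run exactly.  Tables are tab-separated with a header row,
"." decimals and >= 12 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigurationError",
    "RunConfig",
    "read_config",
    "resolve_config",
    "write_manifest",
    "write_table",
    "write_json",
    "child_seeds",
]


class ConfigurationError(ValueError):
    """Invalid, unknown or missing configuration key."""


# per-subcommand schema: key -> (type, default); REQUIRED means no default
REQUIRED = object()

SCHEMAS: dict[str, dict[str, tuple[type, object]]] = {
    "moran": {
        "N": (int, REQUIRED),
        "fc": (float, 0.25),
        "fe": (float, REQUIRED),
        "s0": (int, 1),
        "horizon": (int, 100_000),
        "conditioned": (bool, True),
    },
    "wf": {
        "N": (int, REQUIRED),
        "mu": (float, REQUIRED),
        "generations": (int, REQUIRED),
        "fc": (float, 0.0),
        "fmax": (float, 0.999),
        "dee_kind": (str, "uniform"),
        "dee_center": (float, 0.5),
        "dee_sd": (float, 0.15),
        "dee_path": (str, ""),
        "burn_in": (int, 0),
        "replicates": (int, 1),
        "ecology": (bool, True),
        "record_trajectories": (bool, False),
        "curve_bins": (int, 50),
    },
    "analytics": {
        "formula": (str, REQUIRED),
        "grid_lo": (float, REQUIRED),
        "grid_hi": (float, REQUIRED),
        "grid_n": (int, 50),
        "log_grid": (bool, False),
        "N": (float, 1.0e4),
        "mu": (float, 1.0e-4),
        "fc": (float, 0.25),
        "fmax": (float, 0.99),
    },
    "regime-map": {
        "N": (float, 1.0e4),
        "mu_lo": (float, 1.0e-8),
        "mu_hi": (float, 1.0e-4),
        "mu_n": (int, 25),
        "axis": (str, "fc"),  # "fc" or "fmax"
        "axis_lo": (float, 0.05),
        "axis_hi": (float, 0.95),
        "axis_n": (int, 19),
        "fc": (float, 0.25),
        "fmax": (float, 0.99),
    },
    "game-fit": {
        "input": (str, REQUIRED),
        "window_lo": (float, -1.0),  # negative pair disables the window
        "window_hi": (float, -1.0),
        "n_boot": (int, 1000),
        "alpha": (float, 0.05),
    },
    "assay-sim": {
        "fi": (float, REQUIRED),
        "fe": (float, REQUIRED),
        "n_fractions": (int, 9),
        "replicates": (int, 3),
        "t_max_h": (float, 96.0),
        "dt_h": (float, 4.0),
        "seed_cells": (float, 1500.0),
        "ancestor_rate": (float, 0.035),
        "noise_sd": (float, 0.05),
    },
}

_GLOBAL_KEYS = ("subcommand", "seed", "outdir", "verbosity")


@dataclass
class RunConfig:
    """Fully resolved run configuration (subcommand + flat typed params)."""

    subcommand: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"
    verbosity: int = 1

    def as_flat_dict(self) -> dict:
        return {
            "subcommand": self.subcommand,
            "seed": self.seed,
            "outdir": self.outdir,
            "verbosity": self.verbosity,
            **self.params,
        }


def _coerce(key: str, typ: type, value):
    if typ is bool:
        if isinstance(value, bool):
            return value
        raise ConfigurationError(f"key {key!r}: expected a boolean, got {value!r}")
    if typ is int:
        if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
            raise ConfigurationError(f"key {key!r}: expected an integer, got {value!r}")
        return int(value)
    if typ is float:
        if isinstance(value, bool) or not isinstance(value, (int, float, np.floating)):
            raise ConfigurationError(f"key {key!r}: expected a number, got {value!r}")
        return float(value)
    if typ is str:
        if not isinstance(value, str):
            raise ConfigurationError(f"key {key!r}: expected a string, got {value!r}")
        return value
    raise ConfigurationError(f"key {key!r}: unsupported type {typ}")  # pragma: no cover


def resolve_config(subcommand: str, raw: dict) -> RunConfig:
    """Validate a flat key-value mapping against a subcommand schema.

    Unknown keys are rejected by name; missing required keys raise; defaults
    fill the rest.
    """
    if subcommand not in SCHEMAS:
        raise ConfigurationError(f"unknown subcommand {subcommand!r}")
    schema = SCHEMAS[subcommand]
    raw = dict(raw)
    seed = raw.pop("seed", 0)
    outdir = raw.pop("outdir", "results")
    verbosity = raw.pop("verbosity", 1)
    raw.pop("subcommand", None)
    unknown = sorted(set(raw) - set(schema))
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s) for {subcommand!r}: {', '.join(map(repr, unknown))}"
        )
    params = {}
    for key, (typ, default) in schema.items():
        if key in raw:
            params[key] = _coerce(key, typ, raw[key])
        elif default is REQUIRED:
            raise ConfigurationError(f"missing required key {key!r} for {subcommand!r}")
        else:
            params[key] = default
    return RunConfig(
        subcommand=subcommand,
        params=params,
        seed=_coerce("seed", int, seed),
        outdir=str(outdir),
        verbosity=_coerce("verbosity", int, verbosity),
    )


def read_config(path) -> RunConfig:
    """Read a YAML (or JSON) config file into a validated :class:`RunConfig`.

    The file is a flat mapping with a ``subcommand`` key plus that
    subcommand's parameters; ``seed``, ``outdir`` and ``verbosity`` are
    global.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a key-value mapping")
    if "subcommand" not in raw:
        raise ConfigurationError(f"{path}: missing required key 'subcommand'")
    return resolve_config(raw["subcommand"], raw)


def _package_version() -> str:
    from . import __version__

    return __version__


def write_manifest(config: RunConfig, outdir) -> Path:
    """Write ``manifest.json`` with the package version and resolved config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    doc = {"package": "ecoresist", "version": _package_version(),
           "config": config.as_flat_dict()}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest_config(path) -> RunConfig:
    """Rebuild the :class:`RunConfig` recorded in a manifest."""
    doc = json.loads(Path(path).read_text())
    cfg = doc["config"]
    return resolve_config(cfg["subcommand"], cfg)


def write_table(df: pd.DataFrame, path) -> Path:
    """Tab-separated table with header; >= 12 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def write_json(doc: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=default) + "\n")
    return path


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministically expand one global seed into ``n`` child seeds.

    Uses ``numpy.random.SeedSequence(seed).spawn`` so adding streams never
    perturbs existing ones; each child is reduced to a 31-bit integer.
    """
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]
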