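"""Configuration files and shipped defaults.

A run is configured by a TOML or YAML file with either a ``[physical]`` or a
``[dimensionless]`` block (exactly one), a ``[numerics]`` block, and an
optional ``degradation = {kind, kmax}`` entry (``kmax`` in chamber units;
omitted means no degradation).  Unknown keys warn, missing required keys
raise.  The packaged ``data/example.toml`` carries the repository default
parameter set and ``data/regimes.toml`` the three canned secretion /
degradation presets used throughout the tests.
"""

from __future__ import annotations

import tomllib
import warnings
from importlib import resources
from pathlib import Path

import yaml

from .params import DimensionlessParams, PhysicalParams, nondimensionalize

__all__ = ["load_config", "parse_config", "example_params", "regime_params",
           "REGIME_NAMES"]

REGIME_NAMES = ("uncorrelated", "streaming", "clumping")

_PHYSICAL_KEYS = {"cell_radius", "speed", "diffusivity", "response_time",
                  "noise", "repulsion", "secretion", "kdeg_max", "c0",
                  "injection_flux", "length", "width"}
_DIMLESS_REQUIRED = {"D", "beta", "sigma", "T", "f0", "J", "W", "R"}
_NUMERICS_REQUIRED = {"h", "dt", "t_end"}
_NUMERICS_OPTIONAL = {"n_snapshots", "record_stride", "seed",
                      "init_angle_halfwidth"}
_DEGRADATION_KEYS = {"kind", "kmax"}


def _warn_unknown(block: str, given: dict, known: set) -> None:
    unknown = set(given) - known
    if unknown:
        warnings.warn(f"ignoring unknown key(s) in [{block}]: "
                      f"{sorted(unknown)}", stacklevel=3)


def _need(block: str, given: dict, required: set) -> None:
    missing = required - set(given)
    if missing:
        raise ValueError(f"[{block}] missing required key(s): "
                         f"{sorted(missing)}")


def parse_config(raw: dict) -> tuple[DimensionlessParams, int]:
    """Build the dimensionless parameter set from a parsed config mapping.

    Returns ``(params, seed)``.
    """
    _warn_unknown("top level", raw,
                  {"physical", "dimensionless", "numerics", "degradation"})
    has_phys = "physical" in raw
    has_dim = "dimensionless" in raw
    if has_phys == has_dim:
        raise ValueError("config needs exactly one of [physical] or "
                         "[dimensionless]")
    num = raw.get("numerics")
    if num is None:
        raise ValueError("config missing [numerics] block")
    _need("numerics", num, _NUMERICS_REQUIRED)
    _warn_unknown("numerics", num, _NUMERICS_REQUIRED | _NUMERICS_OPTIONAL)
    seed = int(num.get("seed", 0))
    numerics = {k: num[k] for k in
                ("h", "dt", "t_end", "n_snapshots", "record_stride",
                 "init_angle_halfwidth") if k in num}

    deg = raw.get("degradation", {"kind": "zero", "kmax": 0.0})
    _warn_unknown("degradation", deg, _DEGRADATION_KEYS)
    _need("degradation", deg, {"kind"})
    kind = deg["kind"]
    kmax = float(deg.get("kmax", 0.0))

    if has_dim:
        block = raw["dimensionless"]
        _need("dimensionless", block, _DIMLESS_REQUIRED)
        _warn_unknown("dimensionless", block, _DIMLESS_REQUIRED)
        dp = DimensionlessParams(
            D=float(block["D"]), beta=float(block["beta"]), kmax=kmax,
            sigma=float(block["sigma"]), T=float(block["T"]),
            f0=float(block["f0"]), J=float(block["J"]),
            W=float(block["W"]), R=float(block["R"]),
            deg_kind=kind, **numerics)
    else:
        block = raw["physical"]
        _need("physical", block, _PHYSICAL_KEYS)
        _warn_unknown("physical", block, _PHYSICAL_KEYS)
        pp = PhysicalParams(**{k: float(block[k]) for k in _PHYSICAL_KEYS})
        dp = nondimensionalize(pp, deg_kind=kind, **numerics)
        if "kmax" in deg:
            raise ValueError("degradation.kmax conflicts with [physical] "
                             "kdeg_max; give one of them")
    return dp, seed


def load_config(path) -> tuple[DimensionlessParams, int]:
    """Read a TOML (``.toml``) or YAML (``.yaml``/``.yml``) config file."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as f:
            raw = tomllib.load(f)
    elif path.suffix in (".yaml", ".yml"):
        with open(path) as f:
            raw = yaml.safe_load(f)
    else:
        raise ValueError(f"{path}: unsupported config extension "
                         f"{path.suffix!r} (use .toml or .yaml)")
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return parse_config(raw)


def _data_file(name: str):
    return resources.files("streamrelay").joinpath("data", name)


def example_params() -> tuple[DimensionlessParams, int]:
    """The repository default parameter set (chamber units)."""
    with _data_file("example.toml").open("rb") as f:
        return parse_config(tomllib.load(f))


def regime_params(name: str) -> DimensionlessParams:
    """Canned (beta, kmax) preset producing the named migration regime."""
    import dataclasses
    if name not in REGIME_NAMES:
        raise ValueError(f"unknown regime {name!r}; choose from "
                         f"{REGIME_NAMES}")
    with _data_file("regimes.toml").open("rb") as f:
        presets = tomllib.load(f)
    dp, _ = example_params()
    return dataclasses.replace(dp, beta=float(presets[name]["beta"]),
                               kmax=float(presets[name]["kmax"]))
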