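"""YAML configuration loading/dumping for :class:`SimConfig`.

The file mirrors the SimConfig structure; every field is optional and
missing values fall back to the baseline defaults.  Validation problems are
aggregated and reported together.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Any

import yaml

from .ecology import EcoParams
from .evolution import EvoParams
from .simulator import InitialStrain, SimConfig
from .strain_space import MolecularParams

__all__ = ["load_config", "dump_config", "config_to_dict", "config_from_dict"]

_SECTION_KEYS = {
    "eco": {"r", "K", "beta", "phi", "m"},
    "mol": {"p", "q"},
    "evo": {"mu", "rho_c", "seed_factor"},
}
_TOP_KEYS = {
    "eco",
    "mol",
    "evo",
    "u_max",
    "v",
    "t_max",
    "output_interval",
    "init_hosts",
    "init_viruses",
    "init_host_density",
    "init_virus_density",
    "rtol",
    "atol",
    "method",
    "seed",
}


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


def _strains(entries, errors, label) -> list[InitialStrain] | None:
    if entries is None:
        return None
    out = []
    for k, e in enumerate(entries):
        try:
            out.append(
                InitialStrain(
                    alleles=tuple(int(a) for a in e.get("alleles", ())),
                    density=float(e["density"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"{label}[{k}]: {exc}")
    return out


def config_from_dict(data: dict[str, Any]) -> SimConfig:
    """Build a validated SimConfig from a plain dict (YAML content)."""
    errors: list[str] = []
    unknown = set(data) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    for section, keys in _SECTION_KEYS.items():
        extra = set(data.get(section) or {}) - keys
        if extra:
            errors.append(f"unknown keys in '{section}': {sorted(extra)}")

    def build(cls, section):
        try:
            return cls(**{k: v for k, v in (data.get(section) or {}).items() if k in _SECTION_KEYS[section]})
        except (TypeError, ValueError) as exc:
            errors.append(f"{section}: {exc}")
            return cls()

    eco = build(EcoParams, "eco")
    mol = build(MolecularParams, "mol")
    evo = build(EvoParams, "evo")
    kwargs: dict[str, Any] = {}
    for key in _TOP_KEYS - {"eco", "mol", "evo", "init_hosts", "init_viruses"}:
        if key in data:
            kwargs[key] = data[key]
    init_hosts = _strains(data.get("init_hosts"), errors, "init_hosts")
    init_viruses = _strains(data.get("init_viruses"), errors, "init_viruses")
    try:
        cfg = SimConfig(
            eco=eco,
            mol=mol,
            evo=evo,
            init_hosts=init_hosts,
            init_viruses=init_viruses,
            **kwargs,
        )
    except (TypeError, ValueError) as exc:
        errors.append(str(exc))
        cfg = None
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def config_to_dict(config: SimConfig) -> dict[str, Any]:
    data: dict[str, Any] = {
        "eco": asdict(config.eco),
        "mol": asdict(config.mol),
        "evo": asdict(config.evo),
        "u_max": config.u_max,
        "v": config.v,
        "t_max": config.t_max,
        "output_interval": config.output_interval,
        "init_host_density": config.init_host_density,
        "init_virus_density": config.init_virus_density,
        "rtol": config.rtol,
        "atol": config.atol,
        "method": config.method,
        "seed": config.seed,
    }
    for key, group in (("init_hosts", config.init_hosts), ("init_viruses", config.init_viruses)):
        if group is not None:
            data[key] = [{"alleles": list(s.alleles), "density": s.density} for s in group]
    return data


def load_config(path: str | Path) -> SimConfig:
    """Load and validate a YAML config; missing fields use defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def dump_config(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
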