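"""Plain-text run configuration (``key = value`` lines).

Unknown keys are rejected so typos fail loudly; the write -> read round
trip is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["RunConfig", "read_config", "write_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    input: str = ""
    chirality: str = ""
    selection: str = "backbone:1-6"
    tol_main: float = 30.0
    tol_one: float = 45.0
    dmax: float = 7.0
    hbond_dmax: float = 3.5
    hbond_angle: float = 120.0
    hydration_radius: float = 3.8
    rdf_dr: float = 0.1
    rdf_rmax: float = 12.0
    seed: int = 0
    outdir: str = "."

    def __post_init__(self):
        for name in ("tol_main", "tol_one", "dmax", "hbond_dmax", "hbond_angle",
                     "hydration_radius", "rdf_dr", "rdf_rmax"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"threshold {name} must be positive")


def read_config(path) -> RunConfig:
    known = {f.name: f.type for f in fields(RunConfig)}
    kwargs = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{ln}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ConfigError(f"{path}:{ln}: unknown key {key!r}")
        default = getattr(RunConfig(), key)
        if isinstance(default, float):
            kwargs[key] = float(val)
        elif isinstance(default, int):
            kwargs[key] = int(val)
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def write_config(cfg: RunConfig, path) -> None:
    lines = [f"{f.name} = {getattr(cfg, f.name)}" for f in fields(RunConfig)]
    Path(path).write_text("\n".join(lines) + "\n")
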