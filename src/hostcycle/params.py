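"""Parameter containers for the single-cycle host-association model.

Units convention (documented, not enforced beyond sign constraints):

* rates ``r``, ``delta``, ``f``, ``g`` are per day (d^-1);
* worm biomass ``W`` is in larval-equivalent units (the default ``W0 = 10``
  matches ten L4 larvae seeded per plate);
* bacterial load ``n`` is in cells; ``K`` is cells per unit worm biomass;
* times are in days.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "WormGrowthParams",
    "LifeCycleTraits",
    "SimulationSettings",
    "DEFAULT_TRAIT_BOUNDS",
    "load_config",
]

#: Printed log10 bounds of the biologically plausible trait space.
DEFAULT_TRAIT_BOUNDS: dict[str, tuple[float, float]] = {
    "r": (-1.0, 1.25),
    "delta": (-0.5, 4.0),
    "K": (4.0, 6.25),
    "f": (3.0, 7.5),
}


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class WormGrowthParams:
    """Linear worm biomass growth W(t) = g*t + W0.

    W0 is the biomass at the start of the cycle (larval-equivalent units);
    g is the biomass growth rate per day, encompassing both reproduction
    and development of the worm population on the plate.
    """

    W0: float = 10.0
    g: float = 711.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "W0", _require_finite("W0", self.W0))
        object.__setattr__(self, "g", _require_finite("g", self.g))
        if self.W0 <= 0:
            raise ValueError(f"W0 must be > 0, got {self.W0}")
        if self.g < 0:
            raise ValueError(f"g must be >= 0, got {self.g}")


@dataclass(frozen=True)
class LifeCycleTraits:
    """The evolvable trait vector of the bacterial life cycle.

    r      maximal within-host growth rate (d^-1)
    delta  removal rate: death plus expulsion from the host (d^-1)
    f      immigration rate per unit worm biomass (cells d^-1 per biomass unit)
    K      carrying capacity per unit worm biomass (cells per biomass unit)
    """

    r: float
    delta: float
    f: float
    K: float

    _AXES = ("r", "delta", "f", "K")

    def __post_init__(self) -> None:
        for name in self._AXES:
            value = _require_finite(name, getattr(self, name))
            object.__setattr__(self, name, value)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        # K = 0 would put the logistic bracket at -inf for any n > 0
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")

    def replace_axis(self, axis: str, value: float) -> "LifeCycleTraits":
        if axis not in self._AXES:
            raise ValueError(f"unknown trait axis {axis!r}; expected one of {self._AXES}")
        kwargs = {name: getattr(self, name) for name in self._AXES}
        kwargs[axis] = value
        return LifeCycleTraits(**kwargs)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self._AXES}


@dataclass(frozen=True)
class SimulationSettings:
    """Run controls for the numerical integration of one passage cycle."""

    t_f: float = 3.5
    n0: float = 0.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-6
    max_step: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_f", _require_finite("t_f", self.t_f))
        object.__setattr__(self, "n0", _require_finite("n0", self.n0))
        object.__setattr__(self, "rel_tol", _require_finite("rel_tol", self.rel_tol))
        object.__setattr__(self, "abs_tol", _require_finite("abs_tol", self.abs_tol))
        if self.t_f <= 0:
            raise ValueError(f"t_f must be > 0, got {self.t_f}")
        if self.n0 < 0:
            raise ValueError(f"n0 must be >= 0, got {self.n0}")
        if not 0 < self.rel_tol < 1:
            raise ValueError(f"rel_tol must be in (0, 1), got {self.rel_tol}")
        if self.abs_tol <= 0:
            raise ValueError(f"abs_tol must be > 0, got {self.abs_tol}")
        if self.max_step is not None and self.max_step <= 0:
            raise ValueError(f"max_step must be > 0 or None, got {self.max_step}")


_CONFIG_KEYS = {
    "W0", "g", "t_f", "n0", "rel_tol", "abs_tol", "max_step", "traits",
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a JSON or YAML model config into validated parameter objects.

    Recognised top-level keys: W0, g, t_f, n0, rel_tol, abs_tol, max_step
    and a ``traits`` block with r, delta, f, K.  Unknown keys are rejected
    so typos never silently fall back to defaults.

    Returns a dict with entries ``wg`` (WormGrowthParams), ``settings``
    (SimulationSettings) and, when a traits block is present, ``traits``
    (LifeCycleTraits).
    """
    path = Path(path)
    text = path.read_text()
    raw: Mapping[str, Any]
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    wg = WormGrowthParams(W0=raw.get("W0", 10.0), g=raw.get("g", 711.0))
    settings = SimulationSettings(
        t_f=raw.get("t_f", 3.5),
        n0=raw.get("n0", 0.0),
        rel_tol=raw.get("rel_tol", 1e-8),
        abs_tol=raw.get("abs_tol", 1e-6),
        max_step=raw.get("max_step"),
    )
    out: dict[str, Any] = {"wg": wg, "settings": settings}
    if "traits" in raw:
        traits_raw = raw["traits"]
        extra = set(traits_raw) - set(LifeCycleTraits._AXES)
        if extra:
            raise ValueError(f"unknown trait keys: {sorted(extra)}")
        out["traits"] = LifeCycleTraits(**traits_raw)
    return out


def config_echo(wg: WormGrowthParams, settings: SimulationSettings,
                traits: LifeCycleTraits | None = None) -> dict[str, Any]:
    """Flatten parameters back into the config-file schema (for manifests)."""
    echo: dict[str, Any] = {**asdict(wg), **asdict(settings)}
    if traits is not None:
        echo["traits"] = traits.as_dict()
    return echo
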