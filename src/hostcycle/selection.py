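"""Elasticity analysis of the final load over the life-cycle trait space.

The elasticity of the final load with respect to a trait x is the
dimensionless log-log derivative d ln n_f / d ln x: the relative change in
final within-host load per small relative change in the trait.  The vector
of the four elasticities (over r, delta, f, K) is read as the selection
gradient on the life-cycle traits, and the dominant element — the trait
with the largest absolute elasticity — defines the locally optimal
evolution strategy: which trait selection pushes hardest, and in which
direction.

Elasticities are computed by central finite differences in log space with
a Richardson half-step comparison as the per-component error estimate.
A sweep over a log-spaced grid of the biologically plausible trait box
classifies the strategy at every grid point.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .lifecycle import IntegrationError, final_load
from .params import (DEFAULT_TRAIT_BOUNDS, LifeCycleTraits, SimulationSettings,
                     WormGrowthParams)

__all__ = [
    "AXIS_ORDER",
    "TraitAxis",
    "TraitGrid",
    "ElasticityVector",
    "StrategyRecord",
    "StrategyMap",
    "UndefinedElasticityError",
    "elasticity",
    "selection_gradient_vec",
    "dominant_strategy",
    "sweep_trait_space",
    "summarize_strategy_regions",
    "strategy_region_count",
]

#: Fixed trait-axis order, also the deterministic tie-break order.
AXIS_ORDER: tuple[str, ...] = ("r", "delta", "f", "K")

CSV_COLUMNS = ["r", "delta", "f", "K", "n_f", "E_r", "E_delta", "E_f", "E_K",
               "dominant_trait", "direction", "est_error_max", "failed"]


class UndefinedElasticityError(ValueError):
    """The log-derivative is undefined (zero final load at a stencil point)."""


@dataclass(frozen=True)
class TraitAxis:
    """One log10-bounded axis of the trait space."""

    name: str
    log10_min: float
    log10_max: float
    n_points: int = 12

    def __post_init__(self) -> None:
        if self.name not in AXIS_ORDER:
            raise ValueError(f"unknown axis {self.name!r}")
        if not self.log10_min < self.log10_max:
            raise ValueError(f"{self.name}: log10_min must be < log10_max")
        if self.n_points < 2:
            raise ValueError(f"{self.name}: n_points must be >= 2")

    @property
    def values(self) -> np.ndarray:
        """Log-uniform grid values including both bounds."""
        return np.logspace(self.log10_min, self.log10_max, self.n_points)

    @classmethod
    def default(cls, name: str, n_points: int = 12) -> "TraitAxis":
        lo, hi = DEFAULT_TRAIT_BOUNDS[name]
        return cls(name, lo, hi, n_points)


@dataclass(frozen=True)
class TraitGrid:
    """Cartesian product of the four trait axes, enumerated lazily."""

    axes: tuple[TraitAxis, TraitAxis, TraitAxis, TraitAxis]

    def __post_init__(self) -> None:
        names = tuple(a.name for a in self.axes)
        if names != AXIS_ORDER:
            raise ValueError(f"axes must be ordered {AXIS_ORDER}, got {names}")

    @classmethod
    def default(cls, n_points: int = 12) -> "TraitGrid":
        return cls(tuple(TraitAxis.default(name, n_points) for name in AXIS_ORDER))

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(a.n_points for a in self.axes)

    def __len__(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> Iterator[LifeCycleTraits]:
        """Grid points in row-major order over (r, delta, f, K)."""
        value_lists = [a.values for a in self.axes]
        for combo in itertools.product(*value_lists):
            yield LifeCycleTraits(**dict(zip(AXIS_ORDER, combo)))


@dataclass(frozen=True)
class ElasticityVector:
    """Selection gradient at one trait point: elasticities over (r, delta, f, K)."""

    E_r: float
    E_delta: float
    E_f: float
    E_K: float
    step_used: float
    est_error: tuple[float, float, float, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.E_r, self.E_delta, self.E_f, self.E_K])

    def component(self, axis: str) -> float:
        return getattr(self, f"E_{axis}")

    @property
    def est_error_max(self) -> float:
        return max(self.est_error)


@dataclass(frozen=True)
class StrategyRecord:
    """Classified selection gradient at one trait point."""

    trait_point: LifeCycleTraits
    n_f: float
    elasticities: ElasticityVector | None
    dominant_trait: str | None
    direction: str | None
    failed: bool = False
    error: str | None = None


@dataclass(frozen=True)
class StrategyMap:
    """One StrategyRecord per point of a TraitGrid, plus run metadata."""

    records: tuple[StrategyRecord, ...]
    grid: TraitGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) != len(self.grid):
            raise ValueError(
                f"expected {len(self.grid)} records, got {len(self.records)}")

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def to_csv(self, path) -> None:
        """Write the fixed-schema CSV with round-trip float precision."""
        write_records_csv(self.records, path)


def records_to_frame(records: Sequence[StrategyRecord]) -> pd.DataFrame:
    """Flatten strategy records into the fixed CSV column schema."""
    rows = []
    for rec in records:
        t = rec.trait_point
        ev = rec.elasticities
        rows.append({
            "r": t.r, "delta": t.delta, "f": t.f, "K": t.K,
            "n_f": rec.n_f,
            "E_r": ev.E_r if ev else math.nan,
            "E_delta": ev.E_delta if ev else math.nan,
            "E_f": ev.E_f if ev else math.nan,
            "E_K": ev.E_K if ev else math.nan,
            "dominant_trait": rec.dominant_trait or "",
            "direction": rec.direction or "",
            "est_error_max": ev.est_error_max if ev else math.nan,
            "failed": rec.failed,
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_records_csv(records: Sequence[StrategyRecord], path,
                      append: bool = False) -> None:
    """Write records in the fixed CSV dialect (repr round-trip floats)."""
    df = records_to_frame(records)
    for col in df.columns:
        if df[col].dtype == float:
            df[col] = df[col].map(repr)
    if append:
        df.to_csv(path, mode="a", header=False, index=False)
    else:
        df.to_csv(path, index=False)


def _log_nf(traits: LifeCycleTraits, wg: WormGrowthParams,
            s: SimulationSettings) -> float:
    nf = final_load(traits, wg, s)
    if nf <= 0:
        raise UndefinedElasticityError(
            f"n_f = {nf} at {traits.as_dict()}: elasticity undefined (log of zero)")
    return math.log(nf)


def elasticity(traits: LifeCycleTraits, wg: WormGrowthParams,
               s: SimulationSettings, axis_name: str,
               h: float = 1e-3) -> tuple[float, float]:
    """Elasticity of n_f with respect to one trait, with an error estimate.

    Central difference in log-log space at step ``h`` (natural log):

        E = [ln n_f(x e^h) - ln n_f(x e^-h)] / (2 h).

    A second central difference at step h/2 provides the Richardson error
    estimate; the returned tuple is ``(E_h, |E_h - E_{h/2}|)``.
    Grid-boundary points are handled like any other: the stencil simply
    perturbs beyond the nominal trait range.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    if axis_name not in AXIS_ORDER:
        raise ValueError(f"unknown axis {axis_name!r}")
    x = getattr(traits, axis_name)
    if x == 0:
        # a multiplicative perturbation of a zero trait is a no-op, so the
        # log-log derivative is exactly zero
        return 0.0, 0.0
    if x < 0:
        raise ValueError(f"{axis_name} must be >= 0 for a log-space stencil")

    def central(step: float) -> float:
        up = _log_nf(traits.replace_axis(axis_name, x * math.exp(step)), wg, s)
        dn = _log_nf(traits.replace_axis(axis_name, x * math.exp(-step)), wg, s)
        return (up - dn) / (2.0 * step)

    e_h = central(h)
    e_half = central(h / 2.0)
    return e_h, abs(e_h - e_half)


def selection_gradient_vec(traits: LifeCycleTraits, wg: WormGrowthParams,
                           s: SimulationSettings, h: float = 1e-3) -> ElasticityVector:
    """All four elasticities at one trait point, ordered (r, delta, f, K)."""
    values, errors = [], []
    for axis in AXIS_ORDER:
        try:
            e, err = elasticity(traits, wg, s, axis, h)
        except (IntegrationError, UndefinedElasticityError) as exc:
            raise type(exc)(f"axis {axis!r}: {exc}") from exc
        values.append(e)
        errors.append(err)
    return ElasticityVector(*values, step_used=h, est_error=tuple(errors))


def dominant_strategy(ev: ElasticityVector) -> tuple[str, str]:
    """Trait with the maximum absolute elasticity and the favoured direction.

    Direction is "increase" for a positive dominant elasticity, "decrease"
    otherwise.  Ties in |E| break deterministically in the fixed axis order
    (r, delta, f, K).
    """
    arr = ev.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite elasticity component(s): {arr}")
    idx = int(np.argmax(np.abs(arr)))  # argmax takes the first maximum: tie-break
    axis = AXIS_ORDER[idx]
    direction = "increase" if arr[idx] > 0 else "decrease"
    return axis, direction


def _classify_point(traits: LifeCycleTraits, wg: WormGrowthParams,
                    s: SimulationSettings, h: float) -> StrategyRecord:
    try:
        nf = final_load(traits, wg, s)
        ev = selection_gradient_vec(traits, wg, s, h)
        axis, direction = dominant_strategy(ev)
        return StrategyRecord(traits, nf, ev, axis, direction)
    except (IntegrationError, UndefinedElasticityError, ValueError) as exc:
        return StrategyRecord(traits, math.nan, None, None, None,
                              failed=True, error=str(exc))


def sweep_trait_space(grid: TraitGrid, wg: WormGrowthParams,
                      s: SimulationSettings, h: float = 1e-3,
                      jobs: int = 1, start: int = 0,
                      stop: int | None = None,
                      progress: bool = False) -> StrategyMap | list[StrategyRecord]:
    """Classify the optimal evolution strategy at every grid point.

    Fully deterministic given the configuration; per-point failures are
    recorded with the ``failed`` flag rather than aborting the sweep.
    ``start``/``stop`` select a chunk of the row-major point enumeration
    (for resumable execution); a partial chunk returns a plain record list,
    the full sweep returns a :class:`StrategyMap`.  ``jobs > 1`` evaluates
    points in parallel with order-independent results.
    """
    pts = itertools.islice(grid.points(), start, stop)
    if jobs > 1:
        from joblib import Parallel, delayed

        records = Parallel(n_jobs=jobs)(
            delayed(_classify_point)(p, wg, s, h) for p in pts)
    else:
        iterator: Iterable[LifeCycleTraits] = pts
        if progress:
            try:
                from tqdm import tqdm

                total = len(grid) - start if stop is None else stop - start
                iterator = tqdm(iterator, total=total)
            except ImportError:
                pass
        records = [_classify_point(p, wg, s, h) for p in iterator]
    if start != 0 or (stop is not None and stop < len(grid)):
        return records
    from . import __version__

    return StrategyMap(
        records=tuple(records), grid=grid,
        metadata={"h": h, "wg": {"W0": wg.W0, "g": wg.g},
                  "settings": {"t_f": s.t_f, "n0": s.n0,
                               "rel_tol": s.rel_tol, "abs_tol": s.abs_tol},
                  "grid": [{"name": a.name, "log10_min": a.log10_min,
                            "log10_max": a.log10_max, "n_points": a.n_points}
                           for a in grid.axes],
                  "package_version": __version__})


def summarize_strategy_regions(smap: StrategyMap) -> pd.DataFrame:
    """Per-strategy counts and fractions over the non-failed grid points."""
    df = smap.to_frame()
    if df.empty:
        raise ValueError("empty strategy map")
    ok = df[~df["failed"]]
    if ok.empty:
        raise ValueError("no successful records in strategy map")
    out = (ok.groupby(["dominant_trait", "direction"], sort=True)
             .size().rename("count").reset_index())
    out["fraction"] = out["count"] / len(ok)
    return out


def marginal_slice(smap: StrategyMap, fixed: dict[str, float]) -> pd.DataFrame:
    """2-D slice of the strategy map with two axes held at fixed grid values.

    ``fixed`` maps two axis names to values; rows matching those values
    (nearest grid value) are returned for heatmap plotting.
    """
    if len(fixed) != 2:
        raise ValueError("exactly two axes must be fixed for a 2-D slice")
    df = smap.to_frame()
    for name, value in fixed.items():
        axis = smap.grid.axes[AXIS_ORDER.index(name)]
        nearest = axis.values[np.argmin(np.abs(np.log(axis.values) - np.log(value)))]
        df = df[np.isclose(df[name], nearest, rtol=1e-12)]
    return df.reset_index(drop=True)


def strategy_region_count(smap: StrategyMap, trait: str, direction: str) -> tuple[int, int]:
    """Size and connected-component count of one strategy region.

    The region is the set of grid points classified as (trait, direction);
    connectivity is face-adjacency on the 4-D grid lattice.  Returns
    ``(n_points_in_region, n_connected_components)`` — a contiguous region
    has exactly one component.
    """
    from scipy import ndimage

    df = smap.to_frame()
    mask = ((df["dominant_trait"] == trait) &
            (df["direction"] == direction)).to_numpy().reshape(smap.grid.shape)
    structure = ndimage.generate_binary_structure(4, 1)
    _, n_components = ndimage.label(mask, structure=structure)
    return int(mask.sum()), int(n_components)
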