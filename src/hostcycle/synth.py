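"""Seeded synthetic CFU assay observations.

Generates replicate-level colony-count tables with the statistical
structure the assay-metrics stage assumes, so that stage is testable
without experimental data.  The forward model is:

1. the true per-worm load is the model's final load n_f divided by the
   final worm biomass W(t_f) (c.f.u.s are reported per worm);
2. each replicate's true load is drawn lognormally around that truth
   (between-replicate variation, SD ``sigma_rep`` on the natural-log
   scale);
3. observation emulates serial dilution and plating: the dilution whose
   expected colony count falls in the countable window (30-300 colonies)
   is selected, the plate count is Poisson, and the recorded CFU value is
   the count scaled back by the dilution factor.

The two-strain competition generator extends the single-population
dynamics with a shared carrying capacity,

    dn_i/dt = f_i*W + r_i*n_i*(1 - (n_1+n_2)/(K*W)) - delta_i*n_i,

which is a minimal symmetric data-generating device for co-colonization
assays — it is used only to synthesize test data, not to draw any
biological conclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .lifecycle import IntegrationError, final_load, worm_biomass
from .params import LifeCycleTraits, SimulationSettings, WormGrowthParams

__all__ = [
    "NoiseModel",
    "AssayDesign",
    "SyntheticAssayTable",
    "simulate_mono_assay",
    "simulate_competition_assay",
    "competition_final_loads",
]

#: Standard countable-colony window for dilution plating.
COUNT_WINDOW = (30, 300)


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise for synthetic CFU tables.

    sigma_rep        lognormal SD of the between-replicate load (log-e scale)
    dilution_factors serial-dilution factors available for plating
    plate_count_law  "poisson" for Poisson plate counts, "exact" for the
                     infinite-count (noiseless counting) limit
    background_cfu   residual free-living cells per sample, present in both
                     the worm sample and the supernatant background sample
    """

    sigma_rep: float = 0.5
    dilution_factors: tuple[float, ...] = tuple(10.0 ** k for k in range(9))
    plate_count_law: Literal["poisson", "exact"] = "poisson"
    background_cfu: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_rep < 0:
            raise ValueError("sigma_rep must be >= 0")
        if not self.dilution_factors or any(d <= 0 for d in self.dilution_factors):
            raise ValueError("dilution_factors must be positive")
        if self.plate_count_law not in ("poisson", "exact"):
            raise ValueError("plate_count_law must be 'poisson' or 'exact'")
        if self.background_cfu < 0:
            raise ValueError("background_cfu must be >= 0")


@dataclass(frozen=True)
class AssayDesign:
    """Design of one synthetic colonization assay.

    ``true_params`` maps strain id to its LifeCycleTraits; the mono design
    carries exactly one strain, the competition design exactly two (with a
    common carrying capacity K).  ``release_fraction`` is the fraction of
    the per-worm load expelled during the release incubation (used when
    ``release`` is on to populate a second supernatant sample).
    """

    true_params: Mapping[str, LifeCycleTraits]
    seed: int
    design: Literal["mono", "competition"] = "mono"
    n_replicates: int = 6
    n_worms_per_replicate: int = 5
    wg: WormGrowthParams = field(default_factory=WormGrowthParams)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    noise: NoiseModel = field(default_factory=NoiseModel)
    release: bool = False
    release_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_worms_per_replicate < 1:
            raise ValueError("n_worms_per_replicate must be >= 1")
        expected = {"mono": 1, "competition": 2}.get(self.design)
        if expected is None:
            raise ValueError(f"unknown design {self.design!r}")
        if len(self.true_params) != expected:
            raise ValueError(
                f"{self.design} design requires exactly {expected} strain(s), "
                f"got {len(self.true_params)}")
        if self.design == "competition":
            ks = {t.K for t in self.true_params.values()}
            if len(ks) != 1:
                raise ValueError("competition design requires a common K")
        if not 0 <= self.release_fraction <= 1:
            raise ValueError("release_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticAssayTable:
    """Replicate-level synthetic CFU observations with recorded truths."""

    frame: pd.DataFrame
    design: AssayDesign

    def to_csv(self, path) -> None:
        df = self.frame.copy()
        for col in df.columns:
            if df[col].dtype == float:
                df[col] = df[col].map(repr)
        df.to_csv(path, index=False)


def _observe_cfu(true_value: float, noise: NoiseModel,
                 rng: np.random.Generator) -> tuple[float, str]:
    """Dilution plating: pick a countable dilution, Poisson count, rescale.

    Returns the back-calculated CFU estimate and a flag ("" or
    "zero_expected" when no dilution yields any expected colonies).
    """
    if noise.plate_count_law == "exact":
        return float(true_value), ""
    dilutions = sorted(noise.dilution_factors)
    expected = [true_value / d for d in dilutions]
    if max(expected) <= 0:
        return 0.0, "zero_expected"
    # smallest dilution keeping the plate countable (<= 300 colonies);
    # fall back to the most concentrated plate when everything is < 30
    chosen = dilutions[-1]
    for d, lam in zip(dilutions, expected):
        if lam <= COUNT_WINDOW[1]:
            chosen = d
            break
    count = rng.poisson(true_value / chosen)
    return float(count * chosen), ""


def simulate_mono_assay(design: AssayDesign) -> SyntheticAssayTable:
    """Synthetic mono-colonization assay table.

    Per replicate: the replicate's true per-worm load is the model endpoint
    n_f / W(t_f) times lognormal replicate noise; the worm sample contains
    that load times the number of worms plus background, the supernatant
    only background; both are observed through the counting model.
    Deterministic under a fixed seed.
    """
    if design.design != "mono":
        raise ValueError("simulate_mono_assay requires a mono design")
    (strain_id, traits), = design.true_params.items()
    nf = final_load(traits, design.wg, design.settings)
    per_worm_truth = nf / worm_biomass(design.settings.t_f, design.wg)
    return _simulate({strain_id: per_worm_truth}, design)


def competition_final_loads(traits_by_strain: Mapping[str, LifeCycleTraits],
                            wg: WormGrowthParams,
                            s: SimulationSettings) -> dict[str, float]:
    """Endpoint loads of the shared-capacity two-strain system."""
    (id_a, ta), (id_b, tb) = traits_by_strain.items()
    K = ta.K
    g, W0 = wg.g, wg.W0

    def rhs(t, y):
        W = g * t + W0
        crowd = 1.0 - (y[0] + y[1]) / (K * W)
        return (ta.f * W + ta.r * y[0] * crowd - ta.delta * y[0],
                tb.f * W + tb.r * y[1] * crowd - tb.delta * y[1])

    sol = solve_ivp(rhs, (0.0, s.t_f), [s.n0, s.n0], method="LSODA",
                    rtol=s.rel_tol, atol=s.abs_tol, t_eval=[s.t_f])
    if not sol.success:
        raise IntegrationError(f"competition integration failed: {sol.message}")
    na, nb = float(sol.y[0, -1]), float(sol.y[1, -1])
    if min(na, nb) < -s.abs_tol:
        raise IntegrationError("negative load in competition trajectory")
    return {id_a: max(na, 0.0), id_b: max(nb, 0.0)}


def simulate_competition_assay(design: AssayDesign) -> SyntheticAssayTable:
    """Synthetic two-strain competition assay table.

    The joint shared-capacity trajectory gives each strain's endpoint load;
    per-strain observations are then generated exactly as in the mono
    assay, with independent replicate noise per strain, so identical
    strains yield exchangeable outputs.
    """
    if design.design != "competition":
        raise ValueError("simulate_competition_assay requires a competition design")
    loads = competition_final_loads(design.true_params, design.wg, design.settings)
    W_f = worm_biomass(design.settings.t_f, design.wg)
    return _simulate({sid: nf / W_f for sid, nf in loads.items()}, design)


def _simulate(per_worm_truths: Mapping[str, float],
              design: AssayDesign) -> SyntheticAssayTable:
    rng = np.random.default_rng(design.seed)
    noise = design.noise
    nw = design.n_worms_per_replicate
    rows = []
    for rep in range(design.n_replicates):
        for strain_id, truth in per_worm_truths.items():
            load = truth * math.exp(noise.sigma_rep * rng.standard_normal()) \
                if noise.sigma_rep > 0 else truth
            worm_true = load * nw + noise.background_cfu
            sup1_true = noise.background_cfu
            worm_obs, flag_w = _observe_cfu(worm_true, noise, rng)
            sup1_obs, flag_s = _observe_cfu(sup1_true, noise, rng)
            row = {
                "replicate_id": rep,
                "strain_id": strain_id,
                "worm_sample_cfu": worm_obs,
                "supernatant1_cfu": sup1_obs,
                "n_worms": nw,
                "true_load_per_worm": load,
                "flag": flag_w or flag_s,
            }
            if design.release:
                released = design.release_fraction * load
                sup2_true = sup1_true + released * nw
                sup2_obs, flag2 = _observe_cfu(sup2_true, noise, rng)
                row["supernatant2_cfu"] = sup2_obs
                row["true_released_per_worm"] = released
                row["flag"] = row["flag"] or flag2
            rows.append(row)
    frame = pd.DataFrame(rows)
    return SyntheticAssayTable(frame=frame, design=design)
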