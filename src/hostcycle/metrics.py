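"""Assay-derived fitness metrics from replicate CFU tables.

Implements the colonization observables used to score bacterial fitness in
the worm host:

* **c.f.u.s per worm** — worm-sample CFU minus supernatant (background)
  CFU, divided by the number of worms in the sample;
* **released c.f.u.s per worm** — CFU difference between the
  post-incubation supernatant (supernatant 2) and the background
  supernatant (supernatant 1), per worm;
* **competitive index** — ratio of a mutant's c.f.u.s per worm to the
  ancestor's within one co-colonization replicate;
* one-sample t-tests of replicate ratios against 1 (no change relative to
  the ancestor) with Benjamini-Hochberg FDR correction across groups.

Negative CFU differences (background exceeding the worm sample) are floored
at zero and flagged — counts cannot be negative, and flooring keeps the
degenerate case visible instead of propagating negative loads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CfuResult",
    "cfu_per_worm",
    "released_per_worm",
    "competitive_index",
    "ratio_vs_one_test",
    "compute_assay_metrics",
    "competition_table_index",
]


@dataclass(frozen=True)
class CfuResult:
    """A per-worm CFU value with the negative-difference flag.

    Compares equal to its float value so the flag never gets in the way of
    arithmetic spot checks.
    """

    value: float
    negative_difference: bool = False

    def __float__(self) -> float:
        return self.value

    def __eq__(self, other) -> bool:
        if isinstance(other, CfuResult):
            return (self.value, self.negative_difference) == \
                   (other.value, other.negative_difference)
        return self.value == other


def _per_worm_difference(a: float, b: float, n_worms: int) -> CfuResult:
    if n_worms < 1:
        raise ValueError(f"n_worms must be >= 1, got {n_worms}")
    if a < 0 or b < 0:
        raise ValueError("CFU counts must be >= 0")
    diff = (a - b) / n_worms
    if diff < 0:
        return CfuResult(0.0, negative_difference=True)
    return CfuResult(diff)


def cfu_per_worm(worm_sample_cfu: float, supernatant_cfu: float,
                 n_worms: int) -> CfuResult:
    """(worm-sample CFU - supernatant CFU) / number of worms.

    The supernatant sample measures free-living background carried over
    with the worms; subtracting it isolates the worm-associated load.
    """
    return _per_worm_difference(worm_sample_cfu, supernatant_cfu, n_worms)


def released_per_worm(supernatant2_cfu: float, supernatant1_cfu: float,
                      n_worms: int) -> CfuResult:
    """(supernatant-2 CFU - supernatant-1 CFU) / number of worms.

    Supernatant 1 is the pre-incubation background; supernatant 2 is
    collected after the release incubation, so the difference counts
    bacteria expelled by the worms, reported per worm.
    """
    return _per_worm_difference(supernatant2_cfu, supernatant1_cfu, n_worms)


def competitive_index(mutant_cfu_per_worm: float,
                      ancestor_cfu_per_worm: float) -> float:
    """Ratio of mutant to ancestor c.f.u.s per worm in co-colonization."""
    if ancestor_cfu_per_worm <= 0:
        raise ZeroDivisionError(
            "competitive index undefined: ancestor c.f.u.s per worm must be > 0")
    if mutant_cfu_per_worm < 0:
        raise ValueError("mutant c.f.u.s per worm must be >= 0")
    return mutant_cfu_per_worm / ancestor_cfu_per_worm


def ratio_vs_one_test(ratios: Sequence[float], groups: Sequence[str],
                      alpha: float = 0.05, log_ratios: bool = False) -> pd.DataFrame:
    """Per-group one-sample t-tests of replicate ratios against mu = 1.

    Each group's replicate ratios (e.g. competitive indices, or evolved /
    ancestor phenotype ratios) are tested against the null value 1 with a
    standard two-sided one-sample t-test; p-values are Benjamini-Hochberg
    adjusted across groups.  ``log_ratios`` switches to testing log(ratio)
    against 0 (off by default).

    Returns a data frame with columns group, n, mean_ratio, t, p, q,
    reject (q <= alpha), sorted by group label.
    """
    if len(ratios) != len(groups):
        raise ValueError("ratios and groups must have equal length")
    df = pd.DataFrame({"ratio": np.asarray(ratios, dtype=float),
                       "group": list(groups)})
    rows = []
    for name, sub in df.groupby("group", sort=True):
        x = sub["ratio"].to_numpy()
        if len(x) < 2:
            raise ValueError(f"group {name!r}: need >= 2 replicates, got {len(x)}")
        sample, mu = (np.log(x), 0.0) if log_ratios else (x, 1.0)
        if np.ptp(sample) == 0:
            raise ValueError(f"group {name!r}: zero variance, t-test undefined")
        t, p = stats.ttest_1samp(sample, popmean=mu)
        rows.append({"group": name, "n": len(x), "mean_ratio": float(np.mean(x)),
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    reject, q, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["reject"] = reject
    return out


def compute_assay_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Row-wise per-worm metrics for a replicate CFU table.

    Expects the synthetic/assay schema: columns ``worm_sample_cfu``,
    ``supernatant1_cfu``, ``n_worms`` and optionally ``supernatant2_cfu``
    for release designs.  Appends ``cfu_per_worm`` (with
    ``negative_difference_flag``) and, when present, ``released_per_worm``.
    """
    required = {"worm_sample_cfu", "supernatant1_cfu", "n_worms"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = table.copy()
    res = [cfu_per_worm(w, s, n) for w, s, n in
           zip(out["worm_sample_cfu"], out["supernatant1_cfu"], out["n_worms"])]
    out["cfu_per_worm"] = [r.value for r in res]
    out["negative_difference_flag"] = [r.negative_difference for r in res]
    if "supernatant2_cfu" in out.columns:
        rel = [released_per_worm(s2, s1, n) for s2, s1, n in
               zip(out["supernatant2_cfu"], out["supernatant1_cfu"], out["n_worms"])]
        out["released_per_worm"] = [r.value for r in rel]
    return out


def competition_table_index(table: pd.DataFrame, mutant: str,
                            ancestor: str) -> pd.Series:
    """Per-replicate competitive index from a two-strain CFU table.

    Pairs the mutant and ancestor rows of each replicate, computes
    c.f.u.s per worm for both, and returns their ratio indexed by
    replicate id.
    """
    metrics = compute_assay_metrics(table)
    wide = metrics.pivot(index="replicate_id", columns="strain_id",
                         values="cfu_per_worm")
    for strain in (mutant, ancestor):
        if strain not in wide.columns:
            raise ValueError(f"strain {strain!r} not present in table")
    return pd.Series(
        [competitive_index(m, a) for m, a in zip(wide[mutant], wide[ancestor])],
        index=wide.index, name="competitive_index")
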