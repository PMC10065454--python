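"""Flock demography of the breeding cooperatives.

From a cluster census (households, ewes per household, litter size) and
the management rates, derive the steady-state flock structure: breeding
ewes, sires in service, young replacement rams needed per year, the
surviving lamb crop and the male lambs left over for meat.

All quantities are annual flows in head per year except ``ewes`` and
``sires`` which are standing stocks.  Heads are carried as real numbers;
integer rounding (half up) happens only in :func:`demography_report`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .params import ClusterProfile, InputError, ParameterError, RateConfig
from .utils import round_frame

__all__ = [
    "lambings_per_year",
    "FlockStructure",
    "flock_structure",
    "demography_table",
    "demography_report",
]

#: additive columns that get a totals row
_SUM_COLS = [
    "n_cbbps", "households", "ewes", "sires",
    "young_sires", "lamb_crop", "male_lambs", "culled_for_meat",
]


def lambings_per_year(lambing_interval: float) -> float:
    """Lambing frequency implied by the interval between lambings.

    Parameters
    ----------
    lambing_interval : months between consecutive lambings.

    An 8-month interval (three lamb crops in two years) gives 1.5.
    """
    if lambing_interval <= 0:
        raise ParameterError(f"lambing interval must be positive, got {lambing_interval}")
    return 12.0 / lambing_interval


@dataclass(frozen=True)
class FlockStructure:
    """Steady-state structure of one cluster's cooperative flocks (head)."""

    ewes: float
    sires: float
    replacement_rams_per_year: float
    lamb_crop_per_year: float       # both sexes, surviving to selection/culling age
    male_lambs_per_year: float
    culled_for_meat_per_year: float


def flock_structure(cluster: ClusterProfile, rates: RateConfig) -> FlockStructure:
    """Derive the flock structure of one cluster.

    * sires = ewes / mating ratio;
    * young replacement rams per year = sires / (serving period x ram
      survival) — the stream is inflated for ram mortality;
    * surviving lamb crop = ewes x conception x litter size x lamb
      survival x lambings per year;
    * male lambs not needed as replacements are culled for meat.
    """
    if rates.mating_ratio <= 0:
        raise ParameterError("mating ratio must be positive")
    ewes = cluster.ewes
    sires = ewes / rates.mating_ratio
    replacements = sires / (rates.serving_period * rates.ram_survival)
    crop = (
        ewes
        * rates.conception
        * cluster.litter_size
        * rates.lamb_survival
        * lambings_per_year(rates.lambing_interval)
    )
    males = rates.sex_ratio_male * crop
    return FlockStructure(
        ewes=ewes,
        sires=sires,
        replacement_rams_per_year=replacements,
        lamb_crop_per_year=crop,
        male_lambs_per_year=males,
        culled_for_meat_per_year=males - replacements,
    )


def demography_table(clusters: list[ClusterProfile], rates: RateConfig) -> pd.DataFrame:
    """One row per cluster plus a ``Total`` row, unrounded.

    The totals row sums the unrounded per-cluster values; ratio columns
    (flock size, ewes per household, litter size, per-CBBP means) are
    left blank in the totals row.
    """
    if not clusters:
        raise InputError("at least one cluster is required")
    ids = [c.cluster_id for c in clusters]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate cluster ids: {dupes}")

    rows = []
    for c in clusters:
        fs = flock_structure(c, rates)
        rows.append({
            "cluster": c.cluster_id,
            "n_cbbps": c.n_cbbps,
            "households": c.households,
            "flock_size": c.flock_size,
            "ewes_per_household": c.ewes_per_household,
            "litter_size": c.litter_size,
            "households_per_cbbp": c.households / c.n_cbbps if c.n_cbbps else float("nan"),
            "ewes_per_cbbp": fs.ewes / c.n_cbbps if c.n_cbbps else float("nan"),
            "ewes": fs.ewes,
            "sires": fs.sires,
            "young_sires": fs.replacement_rams_per_year,
            "lamb_crop": fs.lamb_crop_per_year,
            "male_lambs": fs.male_lambs_per_year,
            "culled_for_meat": fs.culled_for_meat_per_year,
        })
    table = pd.DataFrame(rows).set_index("cluster")
    total = table[_SUM_COLS].sum()
    table.loc["Total"] = total
    return table


def demography_report(table: pd.DataFrame) -> pd.DataFrame:
    """Presentation version of :func:`demography_table`: integer heads.

    Head-count columns are half-up rounded to whole animals; the survey
    ratio columns are shown at two decimals.
    """
    report = round_frame(table.fillna(0.0), 0, _SUM_COLS)
    for c in ("flock_size", "ewes_per_household", "litter_size",
              "households_per_cbbp", "ewes_per_cbbp"):
        report[c] = table[c].round(2)
    return report
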