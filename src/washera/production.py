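"""Carcass-meat production under three chain-integration scenarios.

* non-integrated: every surplus cooperative male lamb is culled at sale
  weight (unfinished dressing percentage);
* partially integrated: cooperatives sell breeding rams to client
  production units, whose entire male lamb crop is culled for meat;
* fully integrated: a feedlot tier additionally fattens part of the
  client lamb pool (+gain kg over the feeding period, finished dressing
  percentage) under one of three capacity schedules — the current
  station capacity (c1), a 1,000-lambs-per-year expansion to a ceiling
  (c2), or growth to the whole above-average lamb pool by the end of the
  horizon (c3).

Reported meat flows are tons of carcass per year at the end of the
planning horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import InputError, ParameterError, RateConfig

__all__ = [
    "carcass_meat",
    "CapacitySchedule",
    "capacity_schedule",
    "ProductionReport",
    "scenario_report",
    "production_table",
    "genetic_increment_meat",
]

SCENARIOS = ("none", "partial", "c1", "c2", "c3")


def carcass_meat(lambs: float, live_weight: float, dressing: float) -> float:
    """Tons of carcass from ``lambs`` head at ``live_weight`` kg."""
    if not 0.0 < dressing < 1.0:
        raise ParameterError(f"dressing fraction must be in (0, 1), got {dressing}")
    if lambs < 0 or live_weight < 0:
        raise InputError("lamb count and weight cannot be negative")
    return lambs * live_weight * dressing / 1000.0


@dataclass(frozen=True)
class CapacitySchedule:
    """Feedlot intake (lambs/yr) for each year 0..horizon."""

    kind: str
    values: np.ndarray
    start: float = 0.0
    increment: float = 0.0
    target: float = 0.0

    def final(self) -> float:
        return float(self.values[-1])


def capacity_schedule(
    kind: str, rates: RateConfig, horizon: int, pool: float
) -> CapacitySchedule:
    """Build the feedlot capacity schedule for one integrated case.

    ``pool`` is the above-average client lamb pool per year (the c3
    end-point).  Schedules:

    * ``c1`` — constant at the current station capacity;
    * ``c2`` — current capacity plus a constant annual increment, capped
      at the configured ceiling;
    * ``c3`` — a ramp reaching the full pool at the end of the horizon:
      capacity in year t is ``max(current, pool * t / horizon)``, i.e.
      existing stations keep operating while new capacity grows in
      proportion to the remaining time.

    Capacity never exceeds the pool; excess is clamped with a warning.
    """
    if pool < 0:
        raise InputError("fattening pool cannot be negative")
    t = np.arange(horizon + 1, dtype=float)
    if kind == "c1":
        values = np.full(horizon + 1, rates.fattening_capacity)
        sched = CapacitySchedule(kind, values, start=rates.fattening_capacity)
    elif kind == "c2":
        values = np.minimum(
            rates.fattening_capacity + rates.fattening_increment * t,
            rates.fattening_target,
        )
        sched = CapacitySchedule(
            kind, values, start=rates.fattening_capacity,
            increment=rates.fattening_increment, target=rates.fattening_target,
        )
    elif kind == "c3":
        if horizon == 0:
            ramp = np.full(1, pool)
        else:
            ramp = pool * t / horizon
        values = np.maximum(rates.fattening_capacity, ramp)
        sched = CapacitySchedule(kind, values, start=rates.fattening_capacity, target=pool)
    else:
        raise ParameterError(f"unknown capacity schedule kind {kind!r}")
    if np.any(sched.values > pool + 1e-9):
        warnings.warn(
            f"capacity schedule {kind!r} exceeds the fattening pool ({pool:.0f}); clamped",
            stacklevel=2,
        )
        sched = CapacitySchedule(
            kind, np.minimum(sched.values, pool),
            start=sched.start, increment=sched.increment, target=sched.target,
        )
    return sched


@dataclass(frozen=True)
class ProductionReport:
    """Annual lamb flows and carcass meat of one scenario (final year)."""

    scenario: str
    lambs_culled: float          # head/yr sold unfinished
    lambs_finished: float        # head/yr leaving the feedlot
    cull_meat: float             # t carcass/yr
    finished_meat: float         # t carcass/yr
    components: dict[str, float] = field(default_factory=dict)

    @property
    def total_meat(self) -> float:
        return self.cull_meat + self.finished_meat


def scenario_report(
    scenario: str,
    demography_report: pd.DataFrame,
    upscale_table: pd.DataFrame | None,
    schedule: CapacitySchedule | None,
    rates: RateConfig,
) -> ProductionReport:
    """Lamb and meat flows of one integration scenario.

    ``none`` needs only the demography report; the others also need the
    up-scaling table, and the integrated cases a capacity schedule.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if scenario == "none":
        culled = float(demography_report.loc["Total", "culled_for_meat"])
        meat = carcass_meat(culled, rates.lamb_weight, rates.dressing_cull)
        return ProductionReport(scenario, culled, 0.0, meat, 0.0,
                                components={"cbbp_culled": culled})

    if upscale_table is None:
        raise InputError(f"scenario {scenario!r} requires the up-scaling table")
    cbbp_culled = float(upscale_table.loc["Total", "cbbp_culled"])
    client_lambs = float(upscale_table.loc["Total", "client_meat_lambs"])
    pool = float(upscale_table.loc["Total", "fattening_pool"])

    if scenario == "partial":
        culled = cbbp_culled + client_lambs
        meat = carcass_meat(culled, rates.lamb_weight, rates.dressing_cull)
        return ProductionReport(
            scenario, culled, 0.0, meat, 0.0,
            components={"cbbp_culled": cbbp_culled, "client_culled": client_lambs},
        )

    if schedule is None:
        raise InputError(f"integrated scenario {scenario!r} requires a capacity schedule")
    capacity = min(schedule.final(), pool)
    culled = cbbp_culled + client_lambs - capacity
    finished = capacity * rates.fattening_survival
    cull_meat = carcass_meat(culled, rates.lamb_weight, rates.dressing_cull)
    finished_meat = carcass_meat(
        finished, rates.lamb_weight + rates.fattening_gain, rates.dressing_finished
    )
    return ProductionReport(
        scenario, culled, finished, cull_meat, finished_meat,
        components={
            "cbbp_culled": cbbp_culled,
            "client_culled": client_lambs - capacity,
            "feedlot_intake": capacity,
        },
    )


def production_table(
    demography_report: pd.DataFrame,
    upscale_table: pd.DataFrame,
    rates: RateConfig,
    horizon: int | None = None,
) -> pd.DataFrame:
    """All-scenario summary mirroring the meat-production comparison.

    Columns: non-integrated, partial (with CBBP / production-unit
    breakdown) and the three integrated cases; rows are lamb counts and
    carcass-meat tons.
    """
    horizon = rates.horizon if horizon is None else horizon
    pool = float(upscale_table.loc["Total", "fattening_pool"])
    cols: dict[str, ProductionReport] = {}
    cols["non_integrated"] = scenario_report("none", demography_report, None, None, rates)
    partial = scenario_report("partial", demography_report, upscale_table, None, rates)
    cols["partial"] = partial
    for kind in ("c1", "c2", "c3"):
        sched = capacity_schedule(kind, rates, horizon, pool)
        cols[kind] = scenario_report(kind, demography_report, upscale_table, sched, rates)

    rows = {
        "lambs_culled": {k: r.lambs_culled for k, r in cols.items()},
        "lambs_finished": {k: r.lambs_finished for k, r in cols.items()},
        "cull_meat_t": {k: r.cull_meat for k, r in cols.items()},
        "finished_meat_t": {k: r.finished_meat for k, r in cols.items()},
        "total_meat_t": {k: r.total_meat for k, r in cols.items()},
    }
    table = pd.DataFrame(rows).T
    # partial-scenario tier breakdown, as separate columns
    table.insert(
        1, "partial_cbbp",
        [partial.components["cbbp_culled"], 0.0,
         carcass_meat(partial.components["cbbp_culled"], rates.lamb_weight, rates.dressing_cull),
         0.0,
         carcass_meat(partial.components["cbbp_culled"], rates.lamb_weight, rates.dressing_cull)],
    )
    table.insert(
        2, "partial_production_unit",
        [partial.components["client_culled"], 0.0,
         carcass_meat(partial.components["client_culled"], rates.lamb_weight, rates.dressing_cull),
         0.0,
         carcass_meat(partial.components["client_culled"], rates.lamb_weight, rates.dressing_cull)],
    )
    return table


def genetic_increment_meat(
    culled_lambs: float,
    weight_gain: float,
    extra_lambs: float,
    rates: RateConfig,
) -> tuple[float, float]:
    """Additional carcass meat attributable to genetic improvement.

    Returns ``(weight_term, extra_lamb_term)`` in tons/yr: the heavier
    carcasses of the existing cull stream, and — reported separately —
    the meat of the extra lambs born from improved litter size (culled
    unfinished at sale weight).
    """
    weight_term = culled_lambs * weight_gain * rates.dressing_cull / 1000.0
    extra_term = carcass_meat(extra_lambs, rates.lamb_weight, rates.dressing_cull)
    return weight_term, extra_term
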