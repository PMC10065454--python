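"""Discounted cash-flow appraisal of the integration scenarios.

All flows are nominal USD occurring at whole years 0..horizon inclusive
(eleven payment dates) and are discounted to year 0 at the configured
rate.  Two separate ledgers are kept, matching how the study conditions
are defined:

* the *baseline* ledger values the chain without genetic improvement —
  lamb and ram sales, ram purchases, cooperative program costs and the
  feedlot's purchases, operating costs and finished-lamb sales;
* the *genetic-benefit* ledger contains only the increments caused by
  selection — heavier lambs, extra lambs from improved litter size, the
  breeding-ram price premium — against the selection program costs.

Return on investment is accumulated discounted income over accumulated
discounted cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_gain import TraitTrend
from .params import InputError, ParameterError, RateConfig
from .production import CapacitySchedule

__all__ = [
    "DiscountSpec",
    "CashLedger",
    "accumulate",
    "baseline_cashflows",
    "genetic_benefit_ledger",
    "annual_benefit_series",
    "first_positive_year",
]

INCOME_CATEGORIES = frozenset({"lamb_sales", "ram_sales", "finished_sales"})
COST_CATEGORIES = frozenset({"ram_purchase", "program_cost", "fattening_purchase", "fattening_ops"})


@dataclass(frozen=True)
class DiscountSpec:
    """Discounting convention: flows at years 0..horizon, NPV at year 0."""

    rate: float = 0.07
    base_year: int = 0
    horizon: int = 10

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ParameterError(f"discount rate must be non-negative, got {self.rate}")
        if self.horizon < 0:
            raise ParameterError(f"horizon must be non-negative, got {self.horizon}")

    def factors(self) -> np.ndarray:
        """Discount factor for each year 0..horizon."""
        t = np.arange(self.horizon + 1, dtype=float) - self.base_year
        return (1.0 + self.rate) ** -t

    def annuity(self, start: int = 0) -> float:
        """Closed-form present value of 1 USD/yr over years ``start``..horizon."""
        if self.rate == 0:
            return float(self.horizon - start + 1)
        v = 1.0 / (1.0 + self.rate)
        # geometric series v^start + ... + v^horizon
        return float((v ** start - v ** (self.horizon + 1)) / (1.0 - v))


@dataclass
class CashLedger:
    """Tidy collection of (tier, year, category, direction, amount) flows."""

    entries: list[dict] = field(default_factory=list)

    def add(self, tier: str, year: int, category: str, amount: float) -> None:
        """Record one nominal flow; direction follows from the category."""
        if category in INCOME_CATEGORIES:
            direction = "income"
        elif category in COST_CATEGORIES:
            direction = "cost"
        else:
            raise InputError(f"unknown cash-flow category {category!r}")
        if amount < 0:
            raise InputError("amounts are sign-free; use the category direction")
        if amount == 0:
            return
        self.entries.append({
            "tier": tier, "year": int(year), "category": category,
            "direction": direction, "amount": float(amount),
        })

    def add_stream(self, tier: str, category: str, amounts: np.ndarray, start: int = 0) -> None:
        """Record a year-indexed stream beginning at ``start``."""
        for offset, amount in enumerate(np.atleast_1d(amounts)):
            self.add(tier, start + offset, category, float(amount))

    def frame(self) -> pd.DataFrame:
        if not self.entries:
            return pd.DataFrame(columns=["tier", "year", "category", "direction", "amount"])
        return pd.DataFrame(self.entries)

    def scaled(self, k: float) -> "CashLedger":
        """A ledger with every amount multiplied by ``k`` (linearity helper)."""
        out = CashLedger()
        for e in self.entries:
            out.entries.append({**e, "amount": e["amount"] * k})
        return out

    def merged(self, other: "CashLedger") -> "CashLedger":
        out = CashLedger()
        out.entries = [dict(e) for e in self.entries] + [dict(e) for e in other.entries]
        return out


def accumulate(ledger: CashLedger, spec: DiscountSpec) -> pd.DataFrame:
    """Accumulated discounted income, cost, benefit and ROI per tier.

    Returns one row per tier plus ``Total``; money in USD (not
    thousands).  ROI is NaN when a tier has no costs.
    """
    frame = ledger.frame()
    if frame.empty:
        raise InputError("ledger is empty")
    bad_years = frame[(frame["year"] < 0) | (frame["year"] > spec.horizon)]
    if not bad_years.empty:
        raise InputError(f"ledger entries outside years 0..{spec.horizon}:\n{bad_years}")
    factors = spec.factors()
    frame = frame.assign(discounted=frame["amount"] * factors[frame["year"].to_numpy()])
    pivot = (
        frame.pivot_table(index="tier", columns="direction", values="discounted",
                          aggfunc="sum", fill_value=0.0)
        .reindex(columns=["income", "cost"], fill_value=0.0)
    )
    pivot.loc["Total"] = pivot.sum()
    pivot["benefit"] = pivot["income"] - pivot["cost"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pivot["roi"] = np.where(pivot["cost"] > 0, pivot["income"] / pivot["cost"], np.nan)
    return pivot[["income", "cost", "benefit", "roi"]]


def _program_costs(ledger: CashLedger, n_cbbps: int, rates: RateConfig, horizon: int) -> None:
    ledger.add("cbbp", 0, "program_cost", n_cbbps * rates.cbbp_initial_cost)
    ledger.add_stream(
        "cbbp", "program_cost",
        np.full(horizon + 1, n_cbbps * rates.cbbp_annual_cost),
    )


def baseline_cashflows(
    scenario: str,
    demography_report: pd.DataFrame,
    upscale_table: pd.DataFrame | None,
    schedule: CapacitySchedule | None,
    rates: RateConfig,
) -> CashLedger:
    """Whole-chain ledger of a scenario, excluding genetic improvement.

    Timing conventions: cooperative lamb and ram sales run over years
    0..horizon; production units start paying for rams in year 1 (their
    first purchase); the feedlot tier follows its capacity schedule from
    year 0.
    """
    horizon = rates.horizon
    n_cbbps = int(demography_report.loc["Total", "n_cbbps"])
    ledger = CashLedger()
    lamb_price = rates.lamb_price
    ram_price = lamb_price + rates.ram_overprice

    if scenario == "none":
        culled = float(demography_report.loc["Total", "culled_for_meat"])
        ledger.add_stream("cbbp", "lamb_sales", np.full(horizon + 1, culled * lamb_price))
        _program_costs(ledger, n_cbbps, rates, horizon)
        return ledger

    if upscale_table is None:
        raise InputError(f"scenario {scenario!r} requires the up-scaling table")
    cbbp_culled = float(upscale_table.loc["Total", "cbbp_culled"])
    rams = float(upscale_table.loc["Total", "rams_for_clients"])
    client_lambs = float(upscale_table.loc["Total", "client_meat_lambs"])

    ledger.add_stream("cbbp", "lamb_sales", np.full(horizon + 1, cbbp_culled * lamb_price))
    ledger.add_stream("cbbp", "ram_sales", np.full(horizon + 1, rams * ram_price))
    _program_costs(ledger, n_cbbps, rates, horizon)
    ledger.add_stream(
        "production_unit", "lamb_sales", np.full(horizon + 1, client_lambs * lamb_price)
    )
    ledger.add_stream(
        "production_unit", "ram_purchase", np.full(horizon, rams * ram_price), start=1
    )
    if scenario == "partial":
        return ledger

    if scenario in ("c1", "c2", "c3"):
        if schedule is None:
            raise InputError(f"integrated scenario {scenario!r} requires a capacity schedule")
        capacity = np.asarray(schedule.values, dtype=float)
        ops_per_lamb = rates.fattening_cost_share * rates.fattening_gain * rates.price_per_kg
        finished_price = (rates.lamb_weight + rates.fattening_gain) * rates.price_per_kg
        ledger.add_stream("fattening", "fattening_purchase", capacity * lamb_price)
        ledger.add_stream("fattening", "fattening_ops", capacity * ops_per_lamb)
        ledger.add_stream(
            "fattening", "finished_sales",
            capacity * rates.fattening_survival * finished_price,
        )
        return ledger
    raise ParameterError(f"unknown scenario {scenario!r}")


def genetic_benefit_ledger(
    trends: dict[str, TraitTrend],
    demography_report: pd.DataFrame,
    upscale_table: pd.DataFrame,
    rates: RateConfig,
) -> CashLedger:
    """Incremental ledger of the selection program (partial integration).

    Income counted for the cooperatives: heavier cull lambs (expressed
    lamb-weight gain x live price), extra cull lambs from the litter-size
    trend expressed by the nucleus ewe flock, and the breeding-ram price
    premium.  Against them, the full selection program costs.  For
    production units: heavier meat lambs (expression starts in year 2,
    when the first progeny of purchased rams reach sale age) and extra
    lambs from their dam flock's litter-size merit (zero with base
    dams); against the ram premium paid from year 1.
    """
    horizon = rates.horizon
    smw = trends["SMW"]
    ls = trends["LS"]
    n_cbbps = int(demography_report.loc["Total", "n_cbbps"])
    ewes = float(demography_report.loc["Total", "ewes"])
    cbbp_culled = float(upscale_table.loc["Total", "cbbp_culled"])
    rams = float(upscale_table.loc["Total", "rams_for_clients"])
    client_lambs = float(upscale_table.loc["Total", "client_meat_lambs"])
    client_ewes = float(upscale_table.loc["Total", "client_ewes"])

    # surviving lambs per unit litter size, both tiers
    lambing_units = rates.conception * rates.lamb_survival * (12.0 / rates.lambing_interval)
    nucleus_births = ewes * lambing_units
    client_births = client_ewes * lambing_units

    ledger = CashLedger()
    years = np.arange(horizon + 1)
    smw_nuc = np.array([smw.expressed_nucleus(t) for t in years])
    smw_cli = np.array([smw.expressed_client(t) for t in years])
    extra_nuc = nucleus_births * ls.nucleus_dam          # extra surviving lambs/yr
    extra_cli = client_births * ls.dam

    ledger.add_stream(
        "cbbp", "lamb_sales",
        cbbp_culled * smw_nuc * rates.price_per_kg
        + extra_nuc * rates.sex_ratio_male * rates.lamb_price,
    )
    ledger.add_stream("cbbp", "ram_sales", np.full(horizon + 1, rams * rates.ram_overprice))
    _program_costs(ledger, n_cbbps, rates, horizon)

    ledger.add_stream(
        "production_unit", "lamb_sales",
        client_lambs * smw_cli * rates.price_per_kg
        + extra_cli * rates.sex_ratio_male * rates.lamb_price,
    )
    ledger.add_stream(
        "production_unit", "ram_purchase",
        np.full(horizon, rams * rates.ram_overprice), start=1,
    )
    return ledger


def annual_benefit_series(ledger: CashLedger, spec: DiscountSpec) -> pd.DataFrame:
    """Discounted net benefit per tier and year (long format)."""
    frame = ledger.frame()
    if frame.empty:
        raise InputError("ledger is empty")
    factors = spec.factors()
    signed = np.where(frame["direction"] == "income", 1.0, -1.0)
    frame = frame.assign(net=signed * frame["amount"] * factors[frame["year"].to_numpy()])
    grid = pd.MultiIndex.from_product(
        [sorted(frame["tier"].unique()), range(spec.horizon + 1)], names=["tier", "year"]
    )
    series = frame.groupby(["tier", "year"])["net"].sum().reindex(grid, fill_value=0.0)
    return series.reset_index().rename(columns={"net": "discounted_benefit"})


def first_positive_year(series: pd.DataFrame, tier: str) -> int | None:
    """First year a tier's annual discounted benefit turns positive."""
    sub = series[(series["tier"] == tier) & (series["discounted_benefit"] > 0)]
    return int(sub["year"].min()) if not sub.empty else None
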