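"""End-to-end orchestration: demography → up-scaling → trends →
production → economics, with CSV outputs mirroring the study's summary
tables.

The heavy lifting lives in the stage modules; this module wires them
together, builds the two cross-module summaries (the genetic-benefit
table and the whole-chain financial table) and writes tidy CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import demography, economics, genetic_gain, io, production, scaling
from .params import ClusterProfile, ParameterError, RateConfig, SelectionScheme, TraitSet
from .synthetic_data import washera_fixture
from .utils import round_half_up

__all__ = ["RunConfig", "run_pipeline", "financial_summary", "genetic_summary", "build_tables"]

log = logging.getLogger("washera")

SCENARIO_CHOICES = ("none", "partial", "c1", "c2", "c3")


@dataclass
class RunConfig:
    """What to run and where to put it."""

    clusters_path: str | None = None      # default: packaged Washera census
    config_path: str | None = None        # default: packaged rates/traits
    scenario: str = "partial"
    sensitivity: tuple[float, ...] = (1.0, 0.8, 1.2)
    horizon: int | None = None
    out_dir: str = "results"
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_CHOICES:
            raise ParameterError(f"scenario must be one of {SCENARIO_CHOICES}, got {self.scenario!r}")
        if any(m <= 0 for m in self.sensitivity):
            raise ParameterError("sensitivity multipliers must be positive")


def load_inputs(config: RunConfig) -> tuple[list[ClusterProfile], RateConfig, TraitSet, SelectionScheme]:
    fixture = washera_fixture()
    clusters = io.read_clusters(config.clusters_path) if config.clusters_path else fixture.clusters
    if config.config_path:
        rates, traits, scheme = io.load_config(config.config_path)
    else:
        rates, traits, scheme = fixture.rates, fixture.traits, fixture.scheme
    if config.horizon is not None:
        rates = rates.model_copy(update={"horizon": config.horizon})
    return clusters, rates, traits, scheme


def financial_summary(
    demog_report: pd.DataFrame,
    upscale_table: pd.DataFrame,
    rates: RateConfig,
) -> pd.DataFrame:
    """Whole-chain financials without genetic improvement.

    Columns: the non-integrated cooperative tier, the partial scenario's
    tiers and total, and the three integrated cases' chain totals.
    Income/cost/benefit in thousand USD (half-up), ROI in USD per USD at
    one decimal.
    """
    spec = economics.DiscountSpec(rates.discount_rate, horizon=rates.horizon)
    pool = float(upscale_table.loc["Total", "fattening_pool"])

    columns: dict[str, pd.Series] = {}
    acc_none = economics.accumulate(
        economics.baseline_cashflows("none", demog_report, None, None, rates), spec
    )
    columns["non_integrated_cbbp"] = acc_none.loc["cbbp"]

    partial_ledger = economics.baseline_cashflows("partial", demog_report, upscale_table, None, rates)
    acc_partial = economics.accumulate(partial_ledger, spec)
    columns["partial_cbbp"] = acc_partial.loc["cbbp"]
    columns["partial_production_unit"] = acc_partial.loc["production_unit"]
    columns["partial_total"] = acc_partial.loc["Total"]

    for kind in ("c1", "c2", "c3"):
        sched = production.capacity_schedule(kind, rates, rates.horizon, pool)
        fat_ledger = economics.baseline_cashflows(kind, demog_report, upscale_table, sched, rates)
        columns[f"{kind}_total"] = economics.accumulate(fat_ledger, spec).loc["Total"]

    table = pd.DataFrame(columns)
    out = table.loc[["income", "cost", "benefit"]].map(lambda v: int(round_half_up(v / 1_000.0)))
    out.loc["roi"] = table.loc["roi"].map(lambda v: round_half_up(v, 1))
    out.index = ["income_k_usd", "cost_k_usd", "benefit_k_usd", "roi"]
    return out


def genetic_summary(
    demog_report: pd.DataFrame,
    upscale_table: pd.DataFrame,
    rates: RateConfig,
    traits: TraitSet,
    scheme: SelectionScheme,
    multipliers: tuple[float, ...] = (1.0, 0.8, 1.2),
) -> pd.DataFrame:
    """Genetic merit after the horizon and its meat/economic increments.

    One column pair (cooperative tier, production-unit tier) per
    sensitivity multiplier; additional-meat rows report the
    heavier-carcass term, with extra-lamb meat as a separate row.
    """
    spec = economics.DiscountSpec(rates.discount_rate, horizon=rates.horizon)
    horizon = rates.horizon
    cbbp_culled = float(upscale_table.loc["Total", "cbbp_culled"])
    client_lambs = float(upscale_table.loc["Total", "client_meat_lambs"])
    ewes = float(demog_report.loc["Total", "ewes"])
    client_ewes = float(upscale_table.loc["Total", "client_ewes"])
    lambing_units = rates.conception * rates.lamb_survival * (12.0 / rates.lambing_interval)

    blocks = {}
    for m in multipliers:
        scaled = genetic_gain.sensitivity_scale(traits, m)
        trends = {
            tp.name: genetic_gain.trait_trend(tp, scheme, horizon) for tp in scaled.traits
        }
        smw, ls = trends["SMW"], trends["LS"]
        extra_cbbp = ewes * lambing_units * float(ls.nucleus_dam[horizon])
        extra_client = client_ewes * lambing_units * float(ls.dam[horizon])
        meat_cbbp, extra_meat_cbbp = production.genetic_increment_meat(
            cbbp_culled, smw.expressed_nucleus(horizon), extra_cbbp * rates.sex_ratio_male, rates
        )
        meat_client, extra_meat_client = production.genetic_increment_meat(
            client_lambs, smw.expressed_client(horizon), extra_client * rates.sex_ratio_male, rates
        )
        ledger = economics.genetic_benefit_ledger(trends, demog_report, upscale_table, rates)
        acc = economics.accumulate(ledger, spec)
        for tier, key in (("cbbp", "cbbp"), ("production_unit", "production_unit")):
            nucleus = tier == "cbbp"
            blocks[(m, tier)] = {
                "initial_lamb_weight_kg": traits.smw.base_mean,
                "initial_litter_size": traits.ls.base_mean,
                "final_lamb_weight_kg": smw.final_mean("nucleus" if nucleus else "client"),
                "final_litter_size": ls.final_mean("nucleus" if nucleus else "client"),
                "additional_lambs": extra_cbbp if nucleus else extra_client,
                "additional_meat_t": meat_cbbp if nucleus else meat_client,
                "additional_extra_lamb_meat_t": extra_meat_cbbp if nucleus else extra_meat_client,
                "income_k_usd": acc.loc[key, "income"] / 1_000.0,
                "cost_k_usd": acc.loc[key, "cost"] / 1_000.0,
                "benefit_k_usd": acc.loc[key, "benefit"] / 1_000.0,
                "roi": acc.loc[key, "roi"],
            }
    table = pd.DataFrame(blocks)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["rate_multiplier", "tier"])
    return table


def build_tables(
    clusters: list[ClusterProfile],
    rates: RateConfig,
    traits: TraitSet,
    scheme: SelectionScheme,
    sensitivity: tuple[float, ...] = (1.0, 0.8, 1.2),
) -> dict[str, pd.DataFrame]:
    """Compute every summary table of the analysis from raw inputs."""
    demog = demography.demography_table(clusters, rates)
    demog_report = demography.demography_report(demog)
    upscale = scaling.upscaling_table(clusters, demog_report, rates)
    upscale_report = scaling.upscaling_report(upscale)
    trends = genetic_gain.trend_frame(traits, scheme, rates.horizon)
    prod = production.production_table(demog_report, upscale, rates)
    financials = financial_summary(demog_report, upscale, rates)
    genetic = genetic_summary(demog_report, upscale, rates, traits, scheme, sensitivity)

    base_trends = {
        tp.name: genetic_gain.trait_trend(tp, scheme, rates.horizon) for tp in traits.traits
    }
    ledger = economics.genetic_benefit_ledger(base_trends, demog_report, upscale, rates)
    spec = economics.DiscountSpec(rates.discount_rate, horizon=rates.horizon)
    benefit_series = economics.annual_benefit_series(ledger, spec)

    return {
        "demography": demog_report,
        "demography_raw": demog,
        "upscaling": upscale_report,
        "upscaling_raw": upscale,
        "trends": trends,
        "production": prod,
        "financials": financials,
        "genetic_benefit": genetic,
        "annual_benefit": benefit_series,
    }


_CSV_NAMES = {
    "demography": "table1_demography.csv",
    "upscaling": "table2_upscaling.csv",
    "trends": "genetic_trends.csv",
    "production": "table3_production.csv",
    "genetic_benefit": "table4_genetic_benefit.csv",
    "financials": "table5_financials.csv",
    "annual_benefit": "fig3_annual_benefit.csv",
}


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write the summary CSVs.

    Returns the computed tables keyed by name.  Raises
    :class:`InputError`/:class:`ParameterError` on invalid inputs; the
    CLI converts those into a non-zero exit status.
    """
    logging.basicConfig(level=logging.DEBUG if config.verbose else logging.INFO,
                        format="%(message)s")
    clusters, rates, traits, scheme = load_inputs(config)
    log.info("clusters: %d; rates: %s", len(clusters),
             {k: v for k, v in rates.model_dump().items()})
    log.info("traits: %s", traits.model_dump())
    tables = build_tables(clusters, rates, traits, scheme, config.sensitivity)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, fname in _CSV_NAMES.items():
        tables[name].to_csv(out_dir / fname)
        log.info("wrote %s", out_dir / fname)

    served = float(tables["upscaling_raw"].loc["Total", "client_ewes"])
    targeted = float(tables["upscaling_raw"].loc["Total", "targeted_ewes"])
    if targeted > 0:
        log.info("coverage: %.1f%% of targeted ewes served by current CBBPs",
                 100.0 * served / targeted)
    return tables
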