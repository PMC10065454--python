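"""Discounted cash-flow ledgers: annuity oracle, worked cells, linearity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from washera import RateConfig
from washera.economics import (
    CashLedger,
    DiscountSpec,
    accumulate,
    annual_benefit_series,
    baseline_cashflows,
    first_positive_year,
    genetic_benefit_ledger,
)
from washera.genetic_gain import trait_trend
from washera.params import InputError
from washera.production import capacity_schedule

RATES = RateConfig()
SPEC = DiscountSpec(rate=0.07, horizon=10)


def _trends(traits, scheme, horizon=10):
    return {tp.name: trait_trend(tp, scheme, horizon) for tp in traits.traits}


class TestDiscounting:
    def test_annuity_matches_year_by_year_summation(self):
        """Closed form against brute-force summation, machine precision."""
        brute = sum(1.07 ** -t for t in range(11))
        assert SPEC.annuity() == pytest.approx(brute, rel=1e-14)
        assert SPEC.annuity() == pytest.approx(8.0236, abs=5e-5)
        brute_late = sum(1.07 ** -t for t in range(1, 11))
        assert SPEC.annuity(start=1) == pytest.approx(brute_late, rel=1e-14)

    def test_zero_rate_annuity_counts_payments(self):
        assert DiscountSpec(rate=0.0, horizon=10).annuity() == 11.0

    def test_one_dollar_stream_accumulates_to_annuity(self):
        ledger = CashLedger()
        ledger.add_stream("cbbp", "lamb_sales", np.ones(11))
        acc = accumulate(ledger, SPEC)
        assert acc.loc["cbbp", "income"] == pytest.approx(SPEC.annuity(), rel=1e-14)


class TestAccumulate:
    def test_costs_only_ledger_has_negative_benefit(self):
        ledger = CashLedger()
        ledger.add_stream("cbbp", "program_cost", np.full(11, 100.0))
        acc = accumulate(ledger, SPEC)
        assert acc.loc["cbbp", "benefit"] == pytest.approx(-acc.loc["cbbp", "cost"])
        assert acc.loc["cbbp", "income"] == 0.0
        assert acc.loc["cbbp", "roi"] == 0.0

    def test_roi_undefined_without_costs(self):
        ledger = CashLedger()
        ledger.add_stream("cbbp", "lamb_sales", np.full(11, 100.0))
        acc = accumulate(ledger, SPEC)
        assert np.isnan(acc.loc["cbbp", "roi"])

    def test_empty_ledger_rejected(self):
        with pytest.raises(InputError):
            accumulate(CashLedger(), SPEC)

    def test_entries_beyond_horizon_rejected(self):
        ledger = CashLedger()
        ledger.add("cbbp", 11, "lamb_sales", 1.0)
        with pytest.raises(InputError, match="outside"):
            accumulate(ledger, SPEC)

    def test_unknown_category_rejected(self):
        with pytest.raises(InputError, match="category"):
            CashLedger().add("cbbp", 0, "bribes", 1.0)

    @given(k=st.floats(min_value=0.1, max_value=100.0))
    @settings(derandomize=True, max_examples=25)
    def test_accumulation_linear_in_flows(self, k):
        ledger = CashLedger()
        ledger.add_stream("cbbp", "lamb_sales", np.linspace(10, 20, 11))
        ledger.add_stream("cbbp", "program_cost", np.linspace(5, 8, 11))
        base = accumulate(ledger, SPEC)
        scaled = accumulate(ledger.scaled(k), SPEC)
        for col in ("income", "cost", "benefit"):
            assert scaled.loc["cbbp", col] == pytest.approx(k * base.loc["cbbp", col])


class TestBaselineLedgers:
    def test_non_integrated_cbbp_income_cost_roi(self, demog_report):
        acc = accumulate(baseline_cashflows("none", demog_report, None, None, RATES), SPEC)
        assert acc.loc["cbbp", "income"] == pytest.approx(12_387e3, rel=0.005)
        assert acc.loc["cbbp", "cost"] == pytest.approx(222e3, rel=0.005)
        assert round(acc.loc["cbbp", "roi"], 1) == 55.9

    def test_partial_scenario_tier_cells(self, demog_report, upscale_table):
        acc = accumulate(
            baseline_cashflows("partial", demog_report, upscale_table, None, RATES), SPEC
        )
        assert acc.loc["cbbp", "income"] == pytest.approx(12_675e3, rel=0.005)
        assert acc.loc["production_unit", "cost"] == pytest.approx(5_280e3, rel=0.005)

    def test_fattening_ops_cost_is_65_percent_of_gain_value(self):
        # 0.65 x 8 kg x 4.5 USD/kg
        assert RATES.fattening_cost_share * RATES.fattening_gain * RATES.price_per_kg == pytest.approx(23.40)

    def test_integrated_chain_totals(self, demog_report, upscale_table):
        pool = float(upscale_table.loc["Total", "fattening_pool"])
        sched = capacity_schedule("c2", RATES, 10, pool)
        acc = accumulate(
            baseline_cashflows("c2", demog_report, upscale_table, sched, RATES), SPEC
        )
        assert acc.loc["Total", "income"] == pytest.approx(299_409e3, rel=0.005)
        assert acc.loc["Total", "cost"] == pytest.approx(12_990e3, rel=0.005)

    def test_benefit_is_income_minus_cost_for_every_tier(self, demog_report, upscale_table):
        acc = accumulate(
            baseline_cashflows("partial", demog_report, upscale_table, None, RATES), SPEC
        )
        assert np.allclose(acc["benefit"], acc["income"] - acc["cost"])

    def test_integrated_scenario_requires_schedule(self, demog_report, upscale_table):
        with pytest.raises(InputError, match="schedule"):
            baseline_cashflows("c1", demog_report, upscale_table, None, RATES)


class TestGeneticBenefit:
    def test_production_unit_ram_premium_cost(self, fixture, demog_report, upscale_table):
        ledger = genetic_benefit_ledger(
            _trends(fixture.traits, fixture.scheme), demog_report, upscale_table, RATES
        )
        acc = accumulate(ledger, SPEC)
        assert acc.loc["production_unit", "cost"] == pytest.approx(251e3, rel=0.005)

    def test_zero_rates_leave_only_premium_and_costs(self, fixture, demog_report, upscale_table):
        zero = fixture.traits.model_copy(update={
            "smw": fixture.traits.smw.model_copy(update={"realized_rate": 0.0}),
            "ls": fixture.traits.ls.model_copy(update={"realized_rate": 0.0}),
        })
        ledger = genetic_benefit_ledger(
            _trends(zero, fixture.scheme), demog_report, upscale_table, RATES
        )
        acc = accumulate(ledger, SPEC)
        # only the ram premium remains as income; benefit net of program costs
        rams = float(upscale_table.loc["Total", "rams_for_clients"])
        assert acc.loc["cbbp", "income"] == pytest.approx(rams * 4.5 * SPEC.annuity(), rel=1e-9)
        assert acc.loc["production_unit", "benefit"] < 0

    def test_benefit_scales_with_rate_multiplier_after_fixed_costs(
        self, fixture, demog_report, upscale_table
    ):
        """Income net of the rate-independent premium scales by the multiplier."""
        def income(mult):
            ledger = genetic_benefit_ledger(
                _trends(fixture.traits.scaled(mult), fixture.scheme),
                demog_report, upscale_table, RATES,
            )
            acc = accumulate(ledger, SPEC)
            rams = float(upscale_table.loc["Total", "rams_for_clients"])
            premium = rams * 4.5 * SPEC.annuity()
            return acc.loc["cbbp", "income"] - premium

        assert income(0.8) == pytest.approx(0.8 * income(1.0), rel=1e-9)
        assert income(1.2) == pytest.approx(1.2 * income(1.0), rel=1e-9)


class TestAnnualBenefit:
    def test_cbbp_benefit_turns_positive_by_year_one(self, fixture, demog_report, upscale_table):
        ledger = genetic_benefit_ledger(
            _trends(fixture.traits, fixture.scheme), demog_report, upscale_table, RATES
        )
        series = annual_benefit_series(ledger, SPEC)
        assert first_positive_year(series, "cbbp") <= 1

    def test_production_units_turn_positive_by_year_three(
        self, fixture, demog_report, upscale_table
    ):
        ledger = genetic_benefit_ledger(
            _trends(fixture.traits, fixture.scheme), demog_report, upscale_table, RATES
        )
        series = annual_benefit_series(ledger, SPEC)
        assert first_positive_year(series, "production_unit") <= 3

    def test_without_improvement_cbbp_series_never_positive(
        self, fixture, demog_report, upscale_table
    ):
        zero = fixture.traits.model_copy(update={
            "smw": fixture.traits.smw.model_copy(update={"realized_rate": 0.0}),
            "ls": fixture.traits.ls.model_copy(update={"realized_rate": 0.0}),
        })
        rates = RATES.model_copy(update={"ram_overprice_kg": 0.0})
        ledger = genetic_benefit_ledger(
            _trends(zero, fixture.scheme), demog_report, upscale_table, rates
        )
        series = annual_benefit_series(ledger, SPEC)
        cbbp = series[series["tier"] == "cbbp"]["discounted_benefit"]
        assert (cbbp < 0).all()
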