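"""Genetic-merit trajectories and selection-index potential gains.

Two-tier gene flow, parsimonious cohort recursion
-------------------------------------------------
The nucleus tier (the breeding cooperatives) realizes a constant genetic
trend of ``rate`` trait units per year: the selected cohort *born* in
year ``t`` has merit ``rate * (t + 1)`` above the base (the first
selected progeny are born in year 0 and express their superiority at
lamb age, one year later, so the year-``T`` report value is the cohort
born in ``T - 1``, i.e. ``rate * T``).

The client tier (production units) buys the nucleus ram lambs born the
previous year; its lamb cohort of year ``t`` expresses the parent
average of the ram team and the client dams.  With unimproved (base)
dams — the default, since clients do not recruit improved females — the
client cohort merit is exactly half the ram-team merit, so clients lag
the nucleus by roughly two generations after ten years.

An optional dam-recruitment model (a fraction of client dams replaced by
improved daughters after a configurable age) is provided but off by
default.

Selection-index potential
-------------------------
Given phenotypic/genetic (co)variances P and G of the two goal traits
and economic values ``a``, the index weights are ``b = P^{-1} G a``; the
per-generation response of trait j is ``i * (b' G_j) / sigma_I`` with
``sigma_I = sqrt(b' P b)``, and the annual response divides by the
generation length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterError, SelectionScheme, TraitParams, TraitSet

__all__ = [
    "nucleus_trend",
    "client_trend",
    "TraitTrend",
    "trait_trend",
    "trend_frame",
    "index_response",
    "sensitivity_scale",
]


class NumericalError(RuntimeError):
    """A matrix operation failed (e.g. singular phenotypic covariance)."""


def nucleus_trend(rate: float, horizon: int) -> np.ndarray:
    """Merit of the nucleus lamb cohort born in each year 0..horizon.

    Cohort born in year ``t`` carries ``rate * (t + 1)`` trait units
    above the base mean.
    """
    if horizon < 0:
        raise ParameterError(f"horizon must be non-negative, got {horizon}")
    if rate < 0:
        raise ParameterError(f"gain rate must be non-negative, got {rate}")
    t = np.arange(horizon + 1, dtype=float)
    return rate * (t + 1.0)


def client_trend(nucleus: np.ndarray, dam: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Ram-team and client-cohort merit series from a nucleus trend.

    The ram team serving clients in year ``t`` is the nucleus cohort
    born in ``t - 1`` (zero before any improved ram exists); the client
    cohort born in year ``t`` is the parent average of the ram team and
    the client dam flock (base ewes, merit 0, unless ``dam`` is given).
    """
    n = len(nucleus)
    ram_team = np.zeros(n)
    ram_team[1:] = nucleus[:-1]
    if dam is None:
        dam = np.zeros(n)
    client = 0.5 * ram_team + 0.5 * dam
    return ram_team, client


@dataclass(frozen=True)
class TraitTrend:
    """Year-indexed genetic-merit series of one trait, both tiers.

    Merit is in trait units above the base mean.  ``nucleus_dam`` is the
    standing nucleus ewe flock, which lags the lamb-cohort trend by one
    generation (its own birth cohorts); it drives the extra-lamb flow
    when the trait is litter size.
    """

    trait: TraitParams
    years: np.ndarray
    nucleus_cohort: np.ndarray
    ram_team: np.ndarray
    client_cohort: np.ndarray
    dam: np.ndarray
    nucleus_dam: np.ndarray

    def expressed_nucleus(self, year: int) -> float:
        """Merit expressed by nucleus lambs sold in ``year`` (cohort born year-1)."""
        return float(self.nucleus_cohort[year - 1]) if year >= 1 else 0.0

    def expressed_client(self, year: int) -> float:
        """Merit expressed by client lambs sold in ``year``."""
        return float(self.client_cohort[year - 1]) if year >= 1 else 0.0

    def final_mean(self, tier: str) -> float:
        """Trait mean reported at the end of the horizon for a tier."""
        last = int(self.years[-1])
        gain = self.expressed_nucleus(last) if tier == "nucleus" else self.expressed_client(last)
        return self.trait.base_mean + gain


def trait_trend(
    trait: TraitParams,
    scheme: SelectionScheme,
    horizon: int = 10,
    dam_recruit_fraction: float = 0.0,
    dam_recruit_age: int = 2,
) -> TraitTrend:
    """Build the full two-tier trend of one trait.

    With ``dam_recruit_fraction > 0`` a share of client dams is replaced
    by home-bred improved daughters once those reach breeding age,
    coupling the dam flock back to earlier client cohorts (off by
    default: the printed client endpoint is only consistent with base
    dams).
    """
    years = np.arange(horizon + 1)
    nucleus = nucleus_trend(trait.realized_rate, horizon)
    lag = int(round(scheme.generation_length))
    nucleus_dam = np.zeros(horizon + 1)
    if lag <= horizon:
        nucleus_dam[lag:] = nucleus[: horizon + 1 - lag]

    if dam_recruit_fraction == 0.0:
        ram_team, client = client_trend(nucleus)
        dam = np.zeros(horizon + 1)
    else:
        ram_team = np.zeros(horizon + 1)
        ram_team[1:] = nucleus[:-1]
        dam = np.zeros(horizon + 1)
        client = np.zeros(horizon + 1)
        for t in range(horizon + 1):
            if t - dam_recruit_age >= 0:
                dam[t] = dam_recruit_fraction * client[t - dam_recruit_age]
            client[t] = 0.5 * ram_team[t] + 0.5 * dam[t]
    return TraitTrend(
        trait=trait, years=years, nucleus_cohort=nucleus,
        ram_team=ram_team, client_cohort=client, dam=dam, nucleus_dam=nucleus_dam,
    )


def trend_frame(traits: TraitSet, scheme: SelectionScheme, horizon: int = 10):
    """Tidy (year, tier, trait, merit) table of both traits' trends."""
    import pandas as pd

    records = []
    for tp in traits.traits:
        tt = trait_trend(tp, scheme, horizon)
        for series, tier in (
            (tt.nucleus_cohort, "nucleus_cohort"),
            (tt.ram_team, "ram_team"),
            (tt.client_cohort, "client_cohort"),
            (tt.dam, "client_dam"),
            (tt.nucleus_dam, "nucleus_dam"),
        ):
            for year, merit in zip(tt.years, series):
                records.append({"year": int(year), "tier": tier,
                                "trait": tp.name, "merit": float(merit)})
    return pd.DataFrame.from_records(records)


def _covariances(traits: TraitSet) -> tuple[np.ndarray, np.ndarray]:
    """Phenotypic and genetic 2x2 covariance matrices (SMW first)."""
    sp = np.array([t.phenotypic_sd for t in traits.traits])
    sa = sp * np.sqrt([t.heritability for t in traits.traits])
    P = np.array([
        [sp[0] ** 2, traits.phenotypic_correlation * sp[0] * sp[1]],
        [traits.phenotypic_correlation * sp[0] * sp[1], sp[1] ** 2],
    ])
    G = np.array([
        [sa[0] ** 2, traits.genetic_correlation * sa[0] * sa[1]],
        [traits.genetic_correlation * sa[0] * sa[1], sa[1] ** 2],
    ])
    return P, G


def index_response(traits: TraitSet, scheme: SelectionScheme) -> dict[str, float]:
    """Potential annual genetic gain of each trait under index selection.

    Returns trait-name -> annual response in trait units per year.
    """
    P, G = _covariances(traits)
    a = np.array([t.economic_value for t in traits.traits])
    try:
        b = np.linalg.solve(P, G @ a)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate inputs
        raise NumericalError(f"phenotypic covariance matrix is singular: {P}") from exc
    var_index = float(b @ P @ b)
    if var_index <= 0:
        raise NumericalError("index variance is not positive; check covariances")
    sigma_index = np.sqrt(var_index)
    per_generation = scheme.selection_intensity * (b @ G) / sigma_index
    annual = per_generation / scheme.generation_length
    return {t.name: float(r) for t, r in zip(traits.traits, annual)}


def sensitivity_scale(traits: TraitSet, multiplier: float) -> TraitSet:
    """Trait set with realized gain rates at ``multiplier`` x the baseline.

    All downstream merit, additional-meat and genetic-benefit income
    quantities are homogeneous of degree one in this multiplier.
    """
    return traits.scaled(multiplier)
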