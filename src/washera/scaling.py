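"""Up-scaling and out-scaling of the breeding cooperatives.

Up-scaling: instead of culling every surplus male lamb, each cooperative
cluster sells its above-average ram lambs (minus a small appearance cull
and its own replacements) to surrounding client communities ("production
units"), whose ewe flocks they serve at the standard mating ratio.

Out-scaling: the gap between the ewes those rams can serve and the
regionally targeted ewe population is converted into a number of
additional cooperatives of average size ("gap of CBBPs"); a negative gap
means a cluster has surplus ram capacity.

The stage consumes the *reported* (integer) demography table — the
published census is the interface between the two stages — and carries
real numbers from there on, rounding again only at report time.
"""

from __future__ import annotations

import pandas as pd

from .params import ClusterProfile, InputError, RateConfig
from .utils import round_frame, round_half_up

__all__ = [
    "breeding_capacity",
    "ewes_served",
    "client_production",
    "cbbp_gap",
    "upscaling_table",
    "upscaling_report",
    "coverage_fraction",
]

_SUM_COLS = [
    "sire_capacity", "rams_for_clients", "cbbp_culled", "client_ewes",
    "client_meat_lambs", "fattening_pool", "finished_lambs",
    "targeted_ewes", "ewe_gap",
]


def breeding_capacity(male_lambs: float, rates: RateConfig) -> float:
    """Ram lambs fit for breeding out of an annual male lamb crop.

    The above-average half of the male lambs, excluding the fraction
    culled for physical appearance.
    """
    if male_lambs < 0:
        raise InputError("male lamb count cannot be negative")
    return male_lambs * rates.top_fraction * (1.0 - rates.appearance_cull)


def ewes_served(rams_per_year: float, rates: RateConfig) -> float:
    """Client ewes a steady annual stream of rams can serve.

    One cohort of rams serves for ``serving_period`` years (discounted by
    ram survival) at ``mating_ratio`` ewes each, so in steady state the
    standing ram team covers rams/yr x period x survival x ratio ewes.
    """
    if rams_per_year < 0:
        raise InputError("ram stream cannot be negative")
    return rams_per_year * rates.serving_period * rates.ram_survival * rates.mating_ratio


def client_production(
    ewes: float, cluster: ClusterProfile, rates: RateConfig
) -> tuple[float, float, float]:
    """Annual client-flock output: (meat lambs, fattening pool, finished).

    In production units *all* male lambs are culled for meat; the
    above-average half of them is the potential feedlot intake, of which
    ``fattening_survival`` finish.
    """
    if ewes < 0:
        raise InputError("ewe count cannot be negative")
    meat_lambs = (
        ewes
        * rates.conception
        * cluster.litter_size
        * rates.lamb_survival
        * (12.0 / rates.lambing_interval)
        * rates.sex_ratio_male
    )
    pool = meat_lambs * rates.top_fraction
    finished = pool * rates.fattening_survival
    return meat_lambs, pool, finished


def cbbp_gap(ewe_gap: float, cbbp_ewes: float, client_ewes: float, n_cbbps: int) -> int:
    """Additional average-sized cooperatives needed to close an ewe gap.

    The divisor is the total service of one average existing cooperative:
    its own ewes plus the client ewes its rams serve.  Rounded to the
    nearest whole cooperative; negative values flag surplus capacity.
    """
    if n_cbbps <= 0:
        raise InputError("cluster must contain at least one CBBP to define an average")
    service_per_cbbp = (cbbp_ewes + client_ewes) / n_cbbps
    if service_per_cbbp <= 0:
        raise InputError("average CBBP serves zero ewes; gap undefined")
    return int(round_half_up(ewe_gap / service_per_cbbp))


def upscaling_table(
    clusters: list[ClusterProfile],
    demography_report: pd.DataFrame,
    rates: RateConfig,
) -> pd.DataFrame:
    """Per-cluster up-scaling flows plus a ``Total`` row, unrounded.

    ``demography_report`` is the integer-rounded demography table; its
    reported male lamb crop (culled + young sires) per cluster seeds the
    sire-production capacity.  The totals row sums unrounded values,
    except ``cbbp_gap`` which is the signed sum of the per-cluster
    integer gaps (a surplus in one cluster offsets deficits elsewhere).
    """
    by_id = {c.cluster_id: c for c in clusters}
    rows = []
    for cid, rep in demography_report.iterrows():
        if cid == "Total":
            continue
        if cid not in by_id:
            raise InputError(f"cluster {cid!r} missing from profiles")
        cluster = by_id[cid]
        male_lambs = float(rep["culled_for_meat"] + rep["young_sires"])
        capacity = breeding_capacity(male_lambs, rates)
        rams_for_clients = capacity - float(rep["young_sires"])
        cbbp_culled = male_lambs - capacity
        client_ewes = ewes_served(rams_for_clients, rates)
        meat_lambs, pool, finished = client_production(client_ewes, cluster, rates)
        ewe_gap = cluster.targeted_ewes - client_ewes
        gap = cbbp_gap(ewe_gap, float(rep["ewes"]), client_ewes, cluster.n_cbbps)
        rows.append({
            "cluster": cid,
            "sire_capacity": capacity,
            "rams_for_clients": rams_for_clients,
            "cbbp_culled": cbbp_culled,
            "client_ewes": client_ewes,
            "client_meat_lambs": meat_lambs,
            "fattening_pool": pool,
            "finished_lambs": finished,
            "targeted_ewes": cluster.targeted_ewes,
            "ewe_gap": ewe_gap,
            "cbbp_gap": gap,
        })
    if not rows:
        raise InputError("no clusters to up-scale")
    table = pd.DataFrame(rows).set_index("cluster")
    total = table[_SUM_COLS].sum()
    total["cbbp_gap"] = table["cbbp_gap"].sum()
    table.loc["Total"] = total
    return table


def upscaling_report(table: pd.DataFrame) -> pd.DataFrame:
    """Integer (half-up) presentation of :func:`upscaling_table`."""
    return round_frame(table, 0)


def coverage_fraction(table: pd.DataFrame) -> float:
    """Share of the targeted ewe population served by current cooperatives."""
    targeted = float(table.loc["Total", "targeted_ewes"])
    if targeted <= 0:
        raise InputError("no targeted ewe population recorded")
    return float(table.loc["Total", "client_ewes"]) / targeted
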