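"""Synthetic cluster tables and the packaged Washera study inputs.

The generator draws internally consistent cluster censuses in realistic
smallholder ranges so every pipeline stage can be exercised and
property-tested without the study's own numbers.  All draws come from a
single seeded generator; repeated calls with the same spec are
identical.

:func:`washera_fixture` packages the actual Washera inputs: the five
production clusters, the default rate configuration and the default
trait block.  Per-cluster ewe counts in the published census carry more
precision than the two-decimal ewes-per-household means, so the fixture
stores ``ewes_per_household = census ewes / households`` exactly.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .params import ClusterProfile, ParameterError, RateConfig, SelectionScheme, TraitSet

__all__ = ["SyntheticSpec", "generate_clusters", "washera_fixture", "Fixture"]


class SyntheticSpec(BaseModel):
    """Ranges for random but internally consistent cluster tables."""

    model_config = ConfigDict(frozen=True)

    n_clusters: int = Field(default=5, ge=1)
    seed: int = 0
    households_range: tuple[int, int] = (50, 1_500)
    ewes_per_household_range: tuple[float, float] = (3.0, 10.0)
    litter_size_range: tuple[float, float] = (1.0, 1.6)
    cbbps_range: tuple[int, int] = (1, 10)
    target_multiplier_range: tuple[float, float] = (0.5, 20.0)

    @model_validator(mode="after")
    def _ordered(self) -> "SyntheticSpec":
        for name in ("households_range", "ewes_per_household_range",
                     "litter_size_range", "cbbps_range", "target_multiplier_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name} is empty: {lo} > {hi}")
        return self


def generate_clusters(spec: SyntheticSpec) -> list[ClusterProfile]:
    """Draw ``spec.n_clusters`` internally consistent cluster profiles.

    The regional ewe target is drawn as a multiple of the cluster's own
    breeding ewes, so clusters range from ram-surplus to badly
    under-served.
    """
    rng = np.random.default_rng(spec.seed)
    clusters = []
    for i in range(spec.n_clusters):
        households = int(rng.integers(spec.households_range[0], spec.households_range[1] + 1))
        ewes_hh = float(rng.uniform(*spec.ewes_per_household_range))
        litter = float(rng.uniform(*spec.litter_size_range))
        n_cbbps = int(rng.integers(spec.cbbps_range[0], spec.cbbps_range[1] + 1))
        flock = ewes_hh * float(rng.uniform(1.2, 2.2))  # ewes are a subset of the flock
        target = households * ewes_hh * float(rng.uniform(*spec.target_multiplier_range))
        clusters.append(ClusterProfile(
            cluster_id=str(i + 1),
            n_cbbps=n_cbbps,
            households=households,
            flock_size=flock,
            ewes_per_household=ewes_hh,
            litter_size=litter,
            targeted_ewes=target,
        ))
    return clusters


class Fixture(NamedTuple):
    clusters: list[ClusterProfile]
    rates: RateConfig
    traits: TraitSet
    scheme: SelectionScheme


# (id, CBBPs, households, flock size, census ewes, litter size, targeted ewes)
_WASHERA_CLUSTERS = [
    ("1", 7, 875, 19.71, 8_500, 1.51, 147_844),
    ("2", 9, 1_179, 9.82, 6_538, 1.28, 1_092_459),
    ("3", 2, 200, 6.00, 767, 1.10, 155_874),
    ("4", 5, 600, 10.00, 3_943, 1.18, 260_948),
    ("5", 5, 379, 8.00, 2_020, 1.06, 490_750),
]


def washera_fixture() -> Fixture:
    """The Washera study inputs: five clusters and the default parameters."""
    clusters = [
        ClusterProfile(
            cluster_id=cid,
            n_cbbps=n_cbbps,
            households=households,
            flock_size=flock,
            ewes_per_household=ewes / households,
            litter_size=litter,
            targeted_ewes=float(target),
        )
        for cid, n_cbbps, households, flock, ewes, litter, target in _WASHERA_CLUSTERS
    ]
    return Fixture(clusters, RateConfig(), TraitSet(), SelectionScheme())
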