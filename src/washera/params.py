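"""Parameter and record types shared across the pipeline.

Three blocks of constants drive every downstream formula:

* :class:`ClusterProfile` — one geographic cluster's breeding-cooperative
  census (the row unit of the whole analysis),
* :class:`RateConfig` — biological and management rates plus prices and
  costs (single source of truth; defaults are the Washera study values),
* :class:`TraitSet` / :class:`SelectionScheme` — genetic parameters for
  the two breeding-goal traits, six-month lamb weight (SMW, kg live) and
  litter size (LS, lambs per lambing).

All models are frozen: a configuration is immutable once built, and
variants (e.g. sensitivity-scaled trait rates) are produced with
``model_copy(update=...)``.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ClusterProfile",
    "RateConfig",
    "TraitParams",
    "TraitSet",
    "SelectionScheme",
    "ParameterError",
    "InputError",
]


class ParameterError(ValueError):
    """A rate/price/trait parameter is outside its valid domain."""


class InputError(ValueError):
    """Structurally invalid input data (e.g. duplicated cluster ids)."""


class ClusterProfile(BaseModel):
    """Census of one cluster of community-based breeding programs (CBBPs).

    ``ewes_per_household`` is the survey mean and may carry more decimals
    than a printed summary table would show; ``households *
    ewes_per_household`` is *the* definition of the cluster's breeding-ewe
    count used everywhere downstream.
    """

    model_config = ConfigDict(frozen=True)

    cluster_id: str
    n_cbbps: int = Field(ge=0, description="breeding cooperatives in the cluster")
    households: int = Field(ge=0, description="member households across those CBBPs")
    flock_size: float = Field(ge=0.0, description="mean sheep per household")
    ewes_per_household: float = Field(ge=0.0, description="mean breeding ewes per household")
    litter_size: float = Field(ge=1.0, le=3.0, description="lambs born per ewe lambing")
    targeted_ewes: float = Field(
        default=0.0, ge=0.0,
        description="regional ewe population the cluster should eventually serve",
    )

    @model_validator(mode="after")
    def _check_flock(self) -> "ClusterProfile":
        if self.ewes_per_household > self.flock_size + 1e-9:
            raise ValueError(
                f"cluster {self.cluster_id!r}: ewes per household "
                f"({self.ewes_per_household}) exceeds flock size ({self.flock_size})"
            )
        return self

    @property
    def ewes(self) -> float:
        """Breeding ewes in the cluster's CBBPs (households x ewes/household)."""
        return self.households * self.ewes_per_household


class RateConfig(BaseModel):
    """Biological, management and economic constants.

    Defaults are the Washera study conditions; units in the field names or
    descriptions.  Fractions are proportions in [0, 1].
    """

    model_config = ConfigDict(frozen=True)

    # -- mating and flock turnover -------------------------------------
    mating_ratio: float = Field(default=25.0, gt=0.0, description="breeding ewes per sire")
    serving_period: float = Field(default=2.5, gt=0.0, description="productive years per ram")
    ram_survival: float = Field(default=0.95, ge=0.0, le=1.0)
    conception: float = Field(default=0.9, ge=0.0, le=1.0, description="conceptions per ewe join")
    lamb_survival: float = Field(default=0.9, ge=0.0, le=1.0, description="survival to selection/culling age")
    lambing_interval: float = Field(default=8.0, gt=0.0, description="months between lambings")
    sex_ratio_male: float = Field(default=0.5, ge=0.0, le=1.0)

    # -- selection stream ----------------------------------------------
    top_fraction: float = Field(default=0.5, ge=0.0, le=1.0, description="male lambs above average")
    appearance_cull: float = Field(default=0.05, ge=0.0, le=1.0, description="culled for physical appearance")

    # -- fattening ------------------------------------------------------
    fattening_gain: float = Field(default=8.0, ge=0.0, description="kg live gained in the feedlot")
    fattening_days: int = Field(default=90, ge=0, description="feedlot period (informational)")
    fattening_survival: float = Field(default=0.95, ge=0.0, le=1.0)
    fattening_capacity: float = Field(default=3_900.0, ge=0.0, description="current station capacity, lambs/yr")
    fattening_increment: float = Field(default=1_000.0, ge=0.0, description="capacity growth, lambs/yr per yr")
    fattening_target: float = Field(default=13_900.0, ge=0.0, description="capacity ceiling for the ramp, lambs/yr")
    fattening_cost_share: float = Field(default=0.65, ge=0.0, le=1.0, description="fattening cost as share of gain value")

    # -- carcass and prices ----------------------------------------------
    dressing_cull: float = Field(default=0.442, gt=0.0, lt=1.0, description="dressing % of unfinished lambs")
    dressing_finished: float = Field(default=0.4948, gt=0.0, lt=1.0, description="dressing % of fattened lambs")
    lamb_weight: float = Field(default=20.0, gt=0.0, description="kg live at sale")
    price_per_kg: float = Field(default=4.5, ge=0.0, description="USD per kg live weight")
    ram_overprice_kg: float = Field(default=1.0, ge=0.0, description="breeding-ram premium in kg-equivalents")

    # -- program economics ------------------------------------------------
    discount_rate: float = Field(default=0.07, ge=0.0, description="per year")
    horizon: int = Field(default=10, ge=0, description="planning years (flows at years 0..horizon)")
    cbbp_initial_cost: float = Field(default=700.0, ge=0.0, description="USD, establishment of one CBBP")
    cbbp_annual_cost: float = Field(default=900.0, ge=0.0, description="USD, running one CBBP for a year")

    @property
    def lamb_price(self) -> float:
        """Market price of one sale-weight lamb (USD)."""
        return self.lamb_weight * self.price_per_kg

    @property
    def ram_overprice(self) -> float:
        """Premium paid for a breeding ram over its meat value (USD)."""
        return self.ram_overprice_kg * self.price_per_kg


class TraitParams(BaseModel):
    """Genetic parameters of one breeding-goal trait."""

    model_config = ConfigDict(frozen=True)

    name: str
    base_mean: float
    phenotypic_sd: float = Field(gt=0.0)
    heritability: float = Field(gt=0.0, le=1.0)
    realized_rate: float = Field(ge=0.0, description="realized genetic trend, trait units per year")
    economic_value: float = Field(description="USD per trait unit")


def _default_smw() -> TraitParams:
    return TraitParams(
        name="SMW", base_mean=20.0, phenotypic_sd=3.87,
        heritability=0.4090, realized_rate=0.18, economic_value=4.5,
    )


def _default_ls() -> TraitParams:
    return TraitParams(
        name="LS", base_mean=1.287, phenotypic_sd=0.34,
        heritability=0.0515, realized_rate=0.0021, economic_value=90.0,
    )


class TraitSet(BaseModel):
    """The two-trait breeding goal and its (co)variance structure.

    Economic values: lamb weight is worth the live-weight price per kg;
    an extra lamb per lambing is worth one market lamb (both traits are
    expressed about the same number of times per ewe-year, so the raw
    prices can be used as index weights directly).
    """

    model_config = ConfigDict(frozen=True)

    smw: TraitParams = Field(default_factory=_default_smw)
    ls: TraitParams = Field(default_factory=_default_ls)
    phenotypic_correlation: float = Field(default=-0.0828, ge=-1.0, le=1.0)
    genetic_correlation: float = Field(default=0.0340, ge=-1.0, le=1.0)

    @property
    def traits(self) -> tuple[TraitParams, TraitParams]:
        return (self.smw, self.ls)

    def scaled(self, multiplier: float) -> "TraitSet":
        """Return a copy with both realized gain rates multiplied.

        Used for the 80% / 120% sensitivity settings.
        """
        if multiplier <= 0:
            raise ParameterError(f"sensitivity multiplier must be > 0, got {multiplier}")
        return self.model_copy(update={
            "smw": self.smw.model_copy(update={"realized_rate": self.smw.realized_rate * multiplier}),
            "ls": self.ls.model_copy(update={"realized_rate": self.ls.realized_rate * multiplier}),
        })


class SelectionScheme(BaseModel):
    """Truncation-selection design of the breeding nucleus."""

    model_config = ConfigDict(frozen=True)

    selection_intensity: float = Field(default=0.877, ge=0.0, description="standardized, averaged over sexes")
    generation_length: float = Field(default=3.0, gt=0.0, description="years")
    male_selected_fraction: float = Field(default=0.10, gt=0.0, le=1.0, description="informational")
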