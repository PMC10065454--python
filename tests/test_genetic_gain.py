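"""Gene-flow recursion and selection-index response.

The index response is cross-checked against an independent brute-force
oracle: a fine grid over index-weight directions, keeping the one that
maximizes the correlation between index and aggregate genotype.
"""

import numpy as np
import pytest

from washera import SelectionScheme, TraitParams, TraitSet, washera_fixture
from washera.genetic_gain import (
    _covariances,
    index_response,
    nucleus_trend,
    sensitivity_scale,
    trait_trend,
)
from washera.params import ParameterError


@pytest.fixture(scope="module")
def traits():
    return washera_fixture().traits


@pytest.fixture(scope="module")
def scheme():
    return washera_fixture().scheme


class TestTrends:
    def test_nucleus_cohort_merit_counts_from_first_selected_crop(self):
        """Cohort born in year t carries rate*(t+1); year-10 report is rate*10."""
        trend = nucleus_trend(0.18, 10)
        assert trend[0] == pytest.approx(0.18)
        assert trend[9] == pytest.approx(1.80)  # reported at year 10

    def test_zero_rate_gives_flat_trend(self):
        assert np.all(nucleus_trend(0.0, 10) == 0.0)

    def test_negative_horizon_rejected(self):
        with pytest.raises(ParameterError):
            nucleus_trend(0.18, -1)

    def test_final_means_match_two_tier_predictions(self, traits, scheme):
        """Nucleus reaches 21.8 kg / 1.308 lambs; clients 20.81 / 1.296."""
        smw = trait_trend(traits.smw, scheme, 10)
        ls = trait_trend(traits.ls, scheme, 10)
        assert smw.final_mean("nucleus") == pytest.approx(21.8)
        assert smw.final_mean("client") == pytest.approx(20.81)
        assert round(ls.final_mean("nucleus"), 3) == 1.308
        assert round(ls.final_mean("client"), 3) == 1.296

    def test_client_gain_is_half_nucleus_gain_one_year_back(self, traits, scheme):
        tt = trait_trend(traits.smw, scheme, 10)
        for year in range(1, 11):
            assert tt.expressed_client(year) == pytest.approx(
                0.5 * tt.expressed_nucleus(year - 1)
            )

    def test_no_improved_expression_before_year_one(self, traits, scheme):
        tt = trait_trend(traits.smw, scheme, 10)
        assert tt.expressed_nucleus(0) == 0.0
        assert tt.expressed_client(0) == 0.0
        assert tt.client_cohort[0] == 0.0  # first rams' progeny unborn

    def test_client_never_ahead_of_nucleus_and_both_nondecreasing(self, traits, scheme):
        tt = trait_trend(traits.smw, scheme, 10)
        assert np.all(tt.client_cohort <= tt.nucleus_cohort + 1e-12)
        assert np.all(np.diff(tt.client_cohort) >= 0)
        assert np.all(np.diff(tt.nucleus_cohort) >= 0)

    def test_client_lag_behind_nucleus_at_most_six_years(self, traits, scheme):
        """Clients trail by about two generations at the end of the horizon."""
        tt = trait_trend(traits.smw, scheme, 10)
        client_final = tt.expressed_client(10)
        years_nucleus = [t for t in range(11) if tt.expressed_nucleus(t) >= client_final]
        lag = 10 - min(years_nucleus)
        assert 0 < lag <= 6

    def test_merit_linear_in_rate_multiplier(self, traits, scheme):
        base = trait_trend(traits.smw, scheme, 10)
        scaled = trait_trend(sensitivity_scale(traits, 1.2).smw, scheme, 10)
        assert np.allclose(scaled.nucleus_cohort, 1.2 * base.nucleus_cohort)
        assert np.allclose(scaled.client_cohort, 1.2 * base.client_cohort)

    def test_sensitivity_identity_at_unity(self, traits):
        assert sensitivity_scale(traits, 1.0) == traits

    def test_dam_recruitment_accelerates_client_trend(self, traits, scheme):
        base = trait_trend(traits.smw, scheme, 10)
        recruited = trait_trend(traits.smw, scheme, 10, dam_recruit_fraction=0.5)
        assert recruited.client_cohort[-1] > base.client_cohort[-1]
        assert np.all(recruited.client_cohort >= base.client_cohort - 1e-12)


def _brute_force_response(traits: TraitSet, scheme: SelectionScheme) -> dict[str, float]:
    """Grid-search oracle: maximize corr(index, aggregate genotype)."""
    P, G = _covariances(traits)
    a = np.array([t.economic_value for t in traits.traits])
    theta = np.linspace(0.0, np.pi, 200_001)[:-1]
    B = np.column_stack([np.cos(theta), np.sin(theta)])  # all weight directions
    var_i = np.einsum("ij,jk,ik->i", B, P, B)
    rho = (B @ G @ a) / np.sqrt(var_i * (a @ G @ a))
    best = B[np.argmax(rho)]
    sigma_i = np.sqrt(best @ P @ best)
    per_gen = scheme.selection_intensity * (best @ G) / sigma_i
    return {t.name: r / scheme.generation_length for t, r in zip(traits.traits, per_gen)}


class TestIndexResponse:
    def test_matrix_algebra_agrees_with_grid_search_oracle(self, traits, scheme):
        algebra = index_response(traits, scheme)
        oracle = _brute_force_response(traits, scheme)
        for name in ("SMW", "LS"):
            assert algebra[name] == pytest.approx(oracle[name], rel=1e-3)

    def test_two_trait_potential_lamb_weight_gain(self, traits, scheme):
        assert index_response(traits, scheme)["SMW"] == pytest.approx(0.455, abs=0.001)
        assert index_response(traits, scheme)["LS"] == pytest.approx(0.0020, abs=0.0001)

    def test_reduces_to_single_trait_mass_selection(self, scheme):
        """No value on litter size, no correlations: response = i*h^2*sigma_p/L."""
        traits = TraitSet(
            ls=TraitParams(name="LS", base_mean=1.287, phenotypic_sd=0.34,
                           heritability=0.0515, realized_rate=0.0021, economic_value=0.0),
            phenotypic_correlation=0.0,
            genetic_correlation=0.0,
        )
        resp = index_response(traits, scheme)
        expected = 0.877 * 0.4090 * 3.87 / 3.0
        assert resp["SMW"] == pytest.approx(expected, rel=1e-12)
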