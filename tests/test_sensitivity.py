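import numpy as np
import pandas as pd
import pytest

from cvdscreen.cea import COST_SAVING
from cvdscreen.parameters import LifeTable, ParameterSet
from cvdscreen.policy import base_case
from cvdscreen.population import PopulationSpec, generate_population
from cvdscreen.sensitivity import (
    DistributionError,
    ParameterDistribution,
    default_distributions,
    default_dsa_overrides,
    draw_parameters,
    one_way,
    pill_disutility_analysis,
    run_psa,
    scenario_icer,
)
from .conftest import flat_case_fatality


@pytest.fixture(scope="module")
def small_pop():
    return generate_population(PopulationSpec(n=300, seed=11))


@pytest.fixture(scope="module")
def fast_params():
    """Full default costs/effects but a simple mortality backdrop."""
    return ParameterSet(life_table=LifeTable.flat(0.01),
                        case_fatality=flat_case_fatality(0.3))


ALT = base_case().with_(
    scenario_id="alt", risk_tool="who2019", mode="office",
    high_risk_threshold=0.10, lowered_bp_threshold=True,
)

#: same tool as the base case with strictly more generous rules, so its
#: medicated set is a superset of the base case's by construction
NESTED = base_case().with_(
    scenario_id="nested", high_risk_threshold=0.10,
    statins_all_diabetics=True, lowered_bp_threshold=True,
)


class TestDistributions:
    def test_point_is_constant(self):
        d = ParameterDistribution("cost_statin", "point", 3.98)
        assert np.all(d.draw(np.random.default_rng(0), 100) == 3.98)

    def test_uniform_pct_support(self):
        d = ParameterDistribution("cost_statin", "uniform_pct", 10.0, half_width=0.1)
        x = d.draw(np.random.default_rng(0), 10_000)
        assert x.min() >= 9.0 and x.max() <= 11.0
        assert x.mean() == pytest.approx(10.0, rel=0.01)

    def test_lognormal_from_ci_quantiles(self):
        """Fitted log-normal reproduces the statin non-fatal MI CI."""
        d = ParameterDistribution("rr_statin_nonfatal_chd", "lognormal_from_ci",
                                  0.74, lo=0.67, hi=0.81)
        sdlog = (np.log(0.81) - np.log(0.67)) / (2 * 1.959964)
        assert sdlog == pytest.approx(0.0484, abs=5e-4)
        x = d.draw(np.random.default_rng(1), 100_000)
        assert np.quantile(x, 0.025) == pytest.approx(0.67, abs=0.005)
        assert np.quantile(x, 0.975) == pytest.approx(0.81, abs=0.005)

    def test_gamma_mean_sd_moments(self):
        d = ParameterDistribution("cost_metformin", "gamma_mean_sd", 6.27,
                                  sd_fraction=0.10)
        x = d.draw(np.random.default_rng(2), 100_000)
        assert x.mean() == pytest.approx(6.27, rel=0.005)
        assert x.std() == pytest.approx(0.627, rel=0.02)

    def test_beta_from_ci_moments(self):
        d = ParameterDistribution("p_death_post_chd", "beta_from_ci", 0.03,
                                  lo=0.01, hi=0.04)
        x = d.draw(np.random.default_rng(3), 100_000)
        assert x.mean() == pytest.approx(0.03, abs=0.001)
        assert np.all((x > 0) & (x < 1))

    def test_beta_infeasible_sd_rejected(self):
        d = ParameterDistribution("p", "beta_from_ci", 0.5, lo=0.0, hi=3.0)
        with pytest.raises(DistributionError, match="infeasible"):
            d.draw(np.random.default_rng(0), 10)

    def test_negated_lognormal_for_sign_definite_ci(self):
        d = ParameterDistribution("disutility_nonfatal_stroke", "neg_lognormal_from_ci",
                                  -0.2493, lo=-0.340, hi=-0.158)
        x = d.draw(np.random.default_rng(4), 100_000)
        assert np.all(x < 0)
        assert np.quantile(x, 0.5) == pytest.approx(-0.2493, abs=0.01)

    def test_negated_lognormal_with_ci_crossing_zero(self):
        d = ParameterDistribution("disutility_nonfatal_chd", "neg_lognormal_from_ci",
                                  -0.0210, lo=-0.066, hi=0.024)
        x = d.draw(np.random.default_rng(5), 100_000)
        assert np.median(x) == pytest.approx(-0.021, abs=0.005)
        # values may cross zero, mirroring the stated interval
        assert (x > 0).any() and (x < 0).any()

    def test_ci_order_enforced(self):
        with pytest.raises(DistributionError, match="lo < hi"):
            ParameterDistribution("x", "lognormal_from_ci", 1.0, lo=2.0, hi=1.0)


class TestDrawParameters:
    def test_reproducible_under_seed(self):
        dists = default_distributions()
        a = draw_parameters(dists, 42)
        b = draw_parameters(dists, 42)
        assert a.scalar_dict() == b.scalar_dict()

    def test_unknown_parameter_rejected(self):
        with pytest.raises(DistributionError, match="unknown parameter"):
            draw_parameters([ParameterDistribution("not_a_param", "point", 1.0)], 0)

    def test_point_distributions_recover_base(self):
        base = ParameterSet()
        dists = [ParameterDistribution("cost_statin", "point", base.cost_statin)]
        assert draw_parameters(dists, 0, base).cost_statin == base.cost_statin

    def test_default_distributions_cover_valid_names(self):
        names = {d.name for d in default_distributions()}
        assert names <= set(ParameterSet().scalar_dict())


class TestOneWay:
    def test_empty_overrides_base_row_only(self, small_pop, fast_params):
        table = one_way(small_pop, base_case(), ALT, fast_params, {})
        assert list(table["variation"]) == ["base"]

    def test_identity_override_bit_identical(self, small_pop, fast_params):
        table = one_way(
            small_pop, base_case(), ALT, fast_params,
            {"same": {"discount_rate": fast_params.discount_rate}},
        )
        assert table["icer"].iloc[0] == table["icer"].iloc[1]

    def test_unknown_override_rejected(self, small_pop, fast_params):
        with pytest.raises(DistributionError, match="unknown"):
            one_way(small_pop, base_case(), ALT, fast_params, {"x": {"bogus": 1.0}})

    def test_discounting_direction(self, small_pop, fast_params):
        """Removing discounting inflates both incremental QALYs and costs."""
        table = one_way(small_pop, base_case(), ALT, fast_params,
                        {"r0": {"discount_rate": 0.0}})
        base_row, r0_row = table.iloc[0], table.iloc[1]
        assert r0_row["incr_qalys"] > base_row["incr_qalys"]
        assert r0_row["incr_cost"] > base_row["incr_cost"]

    def test_default_overrides_run(self, small_pop, fast_params):
        overrides = default_dsa_overrides(fast_params)
        table = one_way(small_pop, base_case(), ALT, fast_params, overrides)
        assert len(table) == len(overrides) + 1


class TestPSA:
    def test_point_distributions_degenerate(self, small_pop, fast_params):
        dists = [ParameterDistribution("cost_statin", "point", 3.98)]
        psa = run_psa(small_pop, [ALT], base_case(), dists, n_draws=3, seed=1,
                      base_params=fast_params)
        by_scen = psa.draws.groupby("scenario_id")[["total_cost", "total_qalys"]].nunique()
        assert (by_scen == 1).all().all()
        assert set(psa.ceac["probability"].round(12)) <= {0.0, 1.0, 0.5}

    def test_point_psa_matches_deterministic(self, small_pop, fast_params):
        dists = [ParameterDistribution("cost_statin", "point",
                                       fast_params.cost_statin)]
        psa = run_psa(small_pop, [ALT], base_case(), dists, n_draws=1, seed=1,
                      base_params=fast_params)
        d_cost, d_q, icer, label = scenario_icer(small_pop, base_case(), ALT, fast_params)
        draw = psa.draws.set_index("scenario_id")
        got = (draw.loc["alt", "total_cost"] - draw.loc["base", "total_cost"])
        assert got == pytest.approx(d_cost, rel=1e-12)

    def test_single_draw_probabilities_binary(self, small_pop, fast_params):
        psa = run_psa(small_pop, [ALT], base_case(), default_distributions(fast_params),
                      n_draws=1, seed=2, base_params=fast_params)
        assert set(psa.threshold_prob["probability"]) <= {0.0, 1.0}

    def test_ceac_probabilities_sum_to_one(self, small_pop, fast_params):
        psa = run_psa(small_pop, [ALT], base_case(), default_distributions(fast_params),
                      n_draws=5, seed=3, base_params=fast_params)
        sums = psa.ceac.groupby("wtp")["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_identical_scenarios_split_ties(self, small_pop, fast_params):
        twin = ALT.with_(scenario_id="twin")
        dists = [ParameterDistribution("cost_statin", "point", fast_params.cost_statin)]
        psa = run_psa(small_pop, [ALT, twin], base_case(), dists, n_draws=2, seed=4,
                      base_params=fast_params)
        wide = psa.ceac.pivot(index="wtp", columns="scenario_id", values="probability")
        pd.testing.assert_series_equal(wide["alt"], wide["twin"], check_names=False)
        assert np.allclose(wide.sum(axis=1), 1.0)

    def test_n_draws_validated(self, small_pop, fast_params):
        with pytest.raises(DistributionError):
            run_psa(small_pop, [ALT], base_case(), [], n_draws=0, seed=1,
                    base_params=fast_params)


class TestPillDisutility:
    def test_zero_disutility_identical(self, small_pop, fast_params):
        table = pill_disutility_analysis(small_pop, [NESTED], base_case(),
                                         fast_params, disutility=0.0)
        assert table["incr_qalys"].iloc[0] == table["incr_qalys_pill"].iloc[0]

    def test_positive_disutility_weakly_decreases_incremental_qalys(
        self, small_pop, fast_params
    ):
        table = pill_disutility_analysis(small_pop, [NESTED], base_case(),
                                         fast_params, disutility=0.00384)
        assert (table["d_incr_qalys"] <= 1e-12).all()

    def test_negative_disutility_rejected(self, small_pop, fast_params):
        with pytest.raises(DistributionError):
            pill_disutility_analysis(small_pop, [ALT], base_case(), fast_params,
                                     disutility=-0.1)
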