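"""Growth, stone and sugar sub-models: closed forms, ODE behavior, invariants."""

import numpy as np
import pandas as pd
import pytest

from ideopeach import fruit_model as fm

# Frozen oracle values, computed once by 20-digit symbolic evaluation of the
# closed forms (sympy), for the intercept coefficients with DM0=0.5, dj0=300.
DM_FRUIT_AT_P3 = 2.2765741313745514
DM_FRUIT_LIMIT = 4.1117804209694539
DM_STONE_AT_10 = 3.3290754612419119

SMALL_CFG = fm.GrowthConfig(DM0=0.5, dj0=300.0)
P_INTERCEPT = fm.FruitParameters(A=8.29138, B=1.17567, RGRini=0.00172, P3=2695.74,
                                 kstone=0.19725, Wstone=3.86701, SLA=0.02103)


class TestDmFruit:
    def test_exact_at_dj0(self):
        assert fm.dm_fruit(300.0, P_INTERCEPT, SMALL_CFG) == SMALL_CFG.DM0

    def test_matches_symbolic_value_at_inflection(self):
        assert fm.dm_fruit(2695.74, P_INTERCEPT, SMALL_CFG) == \
            pytest.approx(DM_FRUIT_AT_P3, rel=1e-12)

    def test_large_dj_limit(self):
        assert fm.dm_fruit(1e9, P_INTERCEPT, SMALL_CFG) == \
            pytest.approx(DM_FRUIT_LIMIT, rel=1e-12)

    def test_monotone_in_thermal_time(self):
        dj = np.linspace(300, 5000, 400)
        dm = fm.dm_fruit(dj, P_INTERCEPT, SMALL_CFG)
        assert np.all(np.diff(dm) > 0)

    def test_increasing_A_increases_mass(self):
        bigger = fm.FruitParameters(**{**P_INTERCEPT.__dict__, "A": 10.0})
        assert fm.dm_fruit(2000.0, bigger, SMALL_CFG) > \
            fm.dm_fruit(2000.0, P_INTERCEPT, SMALL_CFG)

    def test_no_overflow_for_extreme_rates(self):
        p = fm.FruitParameters(A=8.0, B=1.0, RGRini=5.0, P3=2000.0,
                               kstone=0.2, Wstone=3.9, SLA=0.02)
        values = fm.dm_fruit(np.array([300.0, 1e7]), p, SMALL_CFG)
        assert np.all(np.isfinite(values))


class TestDmStone:
    def test_zero_at_zero_mass(self):
        assert fm.dm_stone(0.0, P_INTERCEPT) == 0.0

    def test_plateau_is_wstone(self):
        assert fm.dm_stone(1e9, P_INTERCEPT) == pytest.approx(P_INTERCEPT.Wstone, rel=1e-12)

    def test_matches_symbolic_value(self):
        assert fm.dm_stone(10.0, P_INTERCEPT) == pytest.approx(DM_STONE_AT_10, rel=1e-12)

    def test_stone_ratio_composition(self):
        dj = 2000.0
        dm = fm.dm_fruit(dj, P_INTERCEPT, SMALL_CFG)
        expected = fm.dm_stone(dm, P_INTERCEPT) / dm
        assert fm.stone_ratio(dj, P_INTERCEPT, SMALL_CFG) == pytest.approx(expected)
        assert 0 < expected < 1

    def test_stone_ratio_rejects_nonpositive_mass(self):
        # a huge asymptote drags the curve negative below the anchor point
        p = fm.FruitParameters(A=500.0, B=1.2, RGRini=0.004, P3=1200.0,
                               kstone=0.2, Wstone=3.9, SLA=0.02)
        with pytest.raises(fm.SimulationError):
            fm.stone_ratio(250.0, p, SMALL_CFG)


class TestCarbonSupply:
    def test_matches_finite_difference(self, growth_config, weather):
        eps = 1e-4
        a_b = growth_config.alpha + growth_config.beta

        def flesh(t):
            dj = weather.gdd_at(t)
            dm = fm.dm_fruit(dj, P_INTERCEPT, growth_config,
                             dj0=weather.gdd_at(growth_config.start_dab))
            return dm - fm.dm_stone(dm, P_INTERCEPT)

        for t in (95.0, 110.0, 130.0, 148.0):
            numeric = a_b * (flesh(t + eps) - flesh(t - eps)) / (2 * eps)
            assert fm.flesh_carbon_supply(t, P_INTERCEPT, growth_config, weather) == \
                pytest.approx(numeric, rel=1e-6)

    def test_supply_nonnegative_over_window(self, growth_config, weather):
        t = np.linspace(growth_config.start_dab, growth_config.end_dab, 200)
        assert np.all(fm.flesh_carbon_supply(t, P_INTERCEPT, growth_config, weather) >= 0)


class TestSugarOde:
    def test_constant_supply_steady_state_is_preserved(self, growth_config):
        c = growth_config
        s = 0.8
        part = 1 - c.alpha / (c.alpha + c.beta)
        c_star = s * part / c.ksugar
        t = np.arange(c.start_dab, c.end_dab + 1, 1.0)
        sol = fm.integrate_sugar(lambda tq: s, c_star, t, c)
        np.testing.assert_allclose(sol, c_star, rtol=1e-8)

    def test_zero_consumption_is_pure_accumulation(self, growth_config):
        c = growth_config.with_(ksugar=0.0)
        part = 1 - c.alpha / (c.alpha + c.beta)
        t = np.linspace(0, 10, 101)
        supply = lambda tq: np.cos(0.3 * tq)
        sol = fm.integrate_sugar(supply, 1.0, t, c)
        exact = 1.0 + part * np.sin(0.3 * t) / 0.3
        np.testing.assert_allclose(sol, exact, rtol=1e-6)

    def test_fourth_order_convergence(self, growth_config):
        # manufactured solution c(t) = exp(-k t) + 2 + sin t on a smooth supply
        c = growth_config.with_(ksugar=1.0)
        part = 1 - c.alpha / (c.alpha + c.beta)
        k = c.ksugar
        supply = lambda tq: (np.cos(tq) + k * (2.0 + np.sin(tq))) / part
        exact = lambda tq: np.exp(-k * tq) + 2.0 + np.sin(tq)
        errors = []
        for n in (20, 40, 80):
            t = np.linspace(0.0, 4.0, n + 1)
            sol = fm.integrate_sugar(supply, exact(0.0), t, c)
            errors.append(np.max(np.abs(sol - exact(t))))
        orders = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert np.all(orders >= 3.5)

    def test_matches_step_refined_reference(self, growth_config, weather):
        p = P_INTERCEPT.to_array().reshape(1, 7)
        c = growth_config
        supply = lambda tq: fm._flesh_growth_rate(tq, p, c, weather) * (c.alpha + c.beta)
        coarse_t = np.arange(c.start_dab, c.end_dab + 1, 1.0)
        fine_t = np.arange(c.start_dab, c.end_dab + 0.01, 0.01)
        c0 = np.array([1.0])
        coarse = fm.integrate_sugar(supply, c0, coarse_t, c)
        fine = fm.integrate_sugar(supply, c0, fine_t, c)
        assert coarse[-1, 0] == pytest.approx(fine[-1, 0], rel=1e-6)

    def test_negative_solution_raises(self, growth_config):
        c = growth_config.with_(ksugar=0.0)
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(fm.SimulationError, match="smaller step"):
            fm.integrate_sugar(lambda tq: -5.0, 1.0, t, c)


class TestSugarConcentration:
    def test_reference_cases(self, growth_config):
        c = growth_config
        assert fm.sugar_concentration(c.sigma_ts * 50.0, 50.0, c) == pytest.approx(100.0)
        assert fm.sugar_concentration(0.0, 50.0, c) == 0.0
        assert fm.sugar_concentration(4.0, 50.0, c) == \
            pytest.approx(2 * fm.sugar_concentration(2.0, 50.0, c))

    def test_zero_flesh_rejected(self, growth_config):
        with pytest.raises(fm.SimulationError):
            fm.sugar_concentration(1.0, 0.0, growth_config)


class TestSimulation:
    def test_golden_intercept_triplet(self, intercept_params, growth_config, weather):
        # regression pin recorded at first implementation, after step-refinement checks
        triplet = fm.simulate_phenotype(intercept_params, growth_config, weather)
        assert triplet.DM == pytest.approx(52.48160967229594, rel=1e-9)
        assert triplet.SR == pytest.approx(0.0736807913207198, rel=1e-9)
        assert triplet.SU == pytest.approx(4.832292724372252, rel=1e-9)

    def test_sla_does_not_move_traits_without_source_limitation(self, growth_config, weather):
        a = P_INTERCEPT
        b = fm.FruitParameters(**{**a.__dict__, "SLA": a.SLA / 2})
        ta = fm.simulate_phenotype(a, growth_config, weather)
        tb = fm.simulate_phenotype(b, growth_config, weather)
        assert ta.to_array() == pytest.approx(tb.to_array(), rel=1e-12)

    def test_sla_reference_hook_limits_growth(self, growth_config, weather):
        limited = growth_config.with_(sla_ref=0.04)  # SLA/sla_ref ~ 0.5
        t_free = fm.simulate_phenotype(P_INTERCEPT, growth_config, weather)
        t_lim = fm.simulate_phenotype(P_INTERCEPT, limited, weather)
        assert t_lim.DM < t_free.DM

    def test_vanishing_stone_mass_gives_vanishing_ratio(self, growth_config, weather):
        p = fm.FruitParameters(**{**P_INTERCEPT.__dict__, "Wstone": 1e-6})
        assert fm.simulate_phenotype(p, growth_config, weather).SR < 1e-6

    def test_trajectory_invariants(self, intercept_params, growth_config, weather):
        _, traj = fm.simulate_phenotype(intercept_params, growth_config, weather,
                                        return_trajectory=True)
        assert traj.DMfruit[0] == growth_config.DM0
        assert np.all(np.diff(traj.DMfruit) >= 0)
        assert np.all(traj.DMstone < intercept_params.Wstone)
        assert np.all((traj.DMstone / traj.DMfruit > 0) & (traj.DMstone / traj.DMfruit < 1))
        assert np.all(traj.DMflesh > 0)
        assert np.all(traj.Csugar >= 0)
        frame = traj.to_frame()
        assert list(frame.columns) == ["t", "dj", "DMfruit", "DMstone", "DMflesh",
                                       "FCsupp", "Csugar", "FMflesh", "SU"]

    def test_su_scales_inversely_with_dry_matter_content(self, intercept_params,
                                                         growth_config, weather):
        half = growth_config.with_(dmc=growth_config.dmc / 2)
        su_ref = fm.simulate_phenotype(intercept_params, growth_config, weather).SU
        su_half = fm.simulate_phenotype(intercept_params, half, weather).SU
        assert su_half == pytest.approx(su_ref / 2, rel=1e-12)

    def test_batch_matches_scalar(self, model_params_batch, growth_config, weather):
        batch = fm.simulate_phenotypes(model_params_batch, growth_config, weather)
        for i in range(model_params_batch.shape[0]):
            scalar = fm.simulate_phenotype(
                fm.FruitParameters.from_array(model_params_batch[i]),
                growth_config, weather)
            np.testing.assert_allclose(batch[i], scalar.to_array(), rtol=1e-12)

    def test_increasing_wstone_increases_stone_ratio(self, growth_config, weather):
        lo = fm.simulate_phenotype(P_INTERCEPT, growth_config, weather).SR
        hi = fm.simulate_phenotype(
            fm.FruitParameters(**{**P_INTERCEPT.__dict__, "Wstone": 6.0}),
            growth_config, weather).SR
        assert hi > lo

    def test_asymptote_mode_switch(self, growth_config, weather):
        product = growth_config.with_(asymptote_mode="product")
        dm_pow = fm.simulate_phenotype(P_INTERCEPT, growth_config, weather).DM
        dm_prod = fm.simulate_phenotype(P_INTERCEPT, product, weather).DM
        assert dm_pow != dm_prod


@pytest.fixture(scope="module")
def model_params_batch():
    from ideopeach import genetic_model as gm
    rng = np.random.default_rng(7)
    G = rng.integers(0, 2, (5, gm.N_LOCI))
    return gm.predict_parameters_batch(G, gm.default_genetic_model())


class TestWeather:
    def test_constant_weather_gdd_is_linear(self):
        w = fm.WeatherSeries.constant(tmean=22.0, base_temp=7.0)
        assert w.gdd_at(87) == pytest.approx(87 * 15.0)
        assert w.rate_at(100.0) == pytest.approx(15.0)

    def test_gdd_non_decreasing_and_interpolated(self, rng):
        days = np.arange(0, 40)
        tmean = 5.0 + 20.0 * rng.random(40)  # some days below base temperature
        w = fm.WeatherSeries(days, tmean, base_temp=7.0)
        grid = np.linspace(0, 39, 500)
        assert np.all(np.diff(w.gdd_at(grid)) >= 0)

    def test_csv_roundtrip(self, tmp_path):
        w = fm.WeatherSeries.constant(tmean=20.0, end=60)
        path = tmp_path / "weather.csv"
        w.to_frame().to_csv(path, index=False)
        back = fm.WeatherSeries.read_csv(path)
        assert back.gdd_at(50.0) == pytest.approx(w.gdd_at(50.0))

    def test_out_of_window_query_rejected(self, weather):
        with pytest.raises(ValueError):
            weather.gdd_at(1e4)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"DM0": -1.0}, {"dmc": 1.5}, {"step": 0.0}, {"end_dab": 10},
        {"asymptote_mode": "sum"}, {"alpha": -0.1},
    ])
    def test_bad_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            fm.GrowthConfig(**kwargs)

    def test_uneven_step_rejected(self, intercept_params, weather):
        cfg = fm.GrowthConfig(step=2.0)
        with pytest.raises(ValueError, match="evenly"):
            fm.simulate_phenotype(intercept_params, cfg, weather)
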