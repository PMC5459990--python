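"""Lattice fire-vegetation dynamics: rates, fire, stepping, simulation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from firesavanna.suitability import SuitabilityModel
from firesavanna.vegmodel import (
    CoverState,
    Drivers,
    FireVegetationModel,
    ModelParams,
    StateClass,
    classify_tree_cover,
    critical_cover,
    demographic_rates,
    deterministic_increments,
    effective_precip,
    local_equilibrium,
    local_fire_probability,
    logging_rate,
    simulate,
    spread_fire,
    step,
    summarize_state,
)


class TestEffectivePrecip:
    def test_reference_conditions_are_identity(self, reference_model, default_params):
        P = np.array([1500.0])
        out = effective_precip(P, default_params.M_ref, 0.0, reference_model,
                               M_ref=default_params.M_ref)
        assert out[0] == pytest.approx(1500.0)

    def test_seasonality_shift(self, reference_model):
        base = effective_precip(1700.0, 0.5, 0.0, reference_model, M_ref=0.5)
        moved = effective_precip(1700.0, 0.6, 0.0, reference_model, M_ref=0.5)
        assert moved - base == pytest.approx(0.1 * (-7.05) / 0.0029, rel=1e-9)

    def test_soil_shift_in_rainfall_equivalents(self, reference_model):
        base = effective_precip(1700.0, 0.5, 0.0, reference_model, M_ref=0.5)
        moved = effective_precip(1700.0, 0.5, 0.29, reference_model, M_ref=0.5)
        assert moved - base == pytest.approx(0.29 / 0.0029, rel=1e-9)

    def test_zero_rainfall_coefficient_rejected(self):
        broken = SuitabilityModel(np.r_[1.0, 0, 0, 0, 0, 0, 0.0])
        with pytest.raises(ValueError):
            effective_precip(1700.0, 0.5, 0.0, broken)


class TestFire:
    def test_critical_cover_at_reference_climate(self, default_params):
        assert critical_cover(default_params.P_ref, default_params) == 0.59

    def test_critical_cover_clips_when_very_dry(self, default_params):
        assert critical_cover(-5000.0, default_params) == default_params.C_lo

    def test_critical_cover_monotone_in_rainfall(self, default_params):
        P = np.linspace(200, 3200, 50)
        cc = critical_cover(P, default_params)
        assert np.all(np.diff(cc) >= 0)

    def test_sigmoid_midpoint_and_limits(self, default_params):
        p = default_params
        cc = 0.59
        assert local_fire_probability(cc, cc, p) == pytest.approx(1 / (2 * p.I))
        assert local_fire_probability(0.0, cc, p) < 1e-4
        assert local_fire_probability(1.0, cc, p) == pytest.approx(1 / p.I, rel=1e-3)

    def test_nonpositive_return_interval_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(I=0.0)

    def test_spread_of_constant_field_is_identity(self):
        for v in (0.0, 1.0):
            f = np.full((6, 6), v)
            np.testing.assert_allclose(spread_fire(f, 0.1), f)

    def test_spread_stencil_hand_value(self):
        f = np.zeros((5, 5))
        f[2, 2] = 1.0
        out = spread_fire(f, 0.1)
        assert out[2, 2] == pytest.approx(0.6)  # 1 - 4*0.1
        for ij in ((1, 2), (3, 2), (2, 1), (2, 3)):
            assert out[ij] == pytest.approx(0.1)

    def test_zero_spread_is_identity(self):
        rng = np.random.default_rng(0)
        f = (rng.random((8, 8)) < 0.3).astype(float)
        np.testing.assert_array_equal(spread_fire(f, 0.0), f)

    def test_noflux_boundary_conserves_nothing_lost_at_edges(self):
        # a burning corner cell has only 2 neighbours: f_eff = 1 - 2*D
        f = np.zeros((4, 4))
        f[0, 0] = 1.0
        out = spread_fire(f, 0.1, boundary="noflux")
        assert out[0, 0] == pytest.approx(0.8)

    def test_instability_guard(self):
        with pytest.raises(ValueError):
            ModelParams(D=0.3)


class TestDemographicRates:
    def test_saturation_limits(self, default_params):
        r = demographic_rates(1e9, default_params)
        assert r["g_F"] == pytest.approx(default_params.g_max_F, rel=1e-6)
        assert r["m_F"] == pytest.approx(default_params.m0_F, rel=1e-3)

    def test_half_saturation(self, default_params):
        r = demographic_rates(default_params.h_F, default_params)
        assert r["g_F"] == pytest.approx(default_params.g_max_F / 2)

    def test_savanna_trees_more_drought_resistant(self, default_params):
        """Wherever forest mortality is elevated above baseline, the savanna
        tree increment is no larger; growth also holds up at lower rainfall."""
        P = np.linspace(100, 3000, 60)
        r = demographic_rates(P, default_params)
        forest_elev = r["m_F"] - default_params.m0_F
        savanna_elev = r["m_T"] - default_params.m0_T
        sel = forest_elev > 0.01
        assert np.all(savanna_elev[sel] <= forest_elev[sel] + 1e-9)
        assert np.all(r["g_T"] / default_params.g_max_T
                      >= r["g_F"] / default_params.g_max_F - 1e-12)

    def test_grass_to_bare_increases_with_dryness(self, default_params):
        P = np.linspace(100, 2500, 40)
        m = demographic_rates(P, default_params)["m_GB"]
        assert np.all(np.diff(m) <= 0)


class TestLogging:
    def test_inactive_window_is_zero(self, default_params):
        delta = np.array([[0.0, 1.0], [2.0, np.inf]])
        agri = delta == 0
        rF, rTS = logging_rate(delta, agri, False, default_params)
        assert not rF.any() and not rTS.any()

    def test_managed_cells_full_removal(self, default_params):
        delta = np.array([[0.0, 1.0]])
        rF, rTS = logging_rate(delta, delta == 0, True, default_params)
        assert rF[0, 0] == default_params.r0
        assert rTS[0, 0] == default_params.r0
        assert rTS[0, 1] == 0.0  # edge logging targets forest only

    def test_exponential_decay(self, default_params):
        lam = default_params.lambda_r
        delta = np.array([[3 * lam]])
        rF, _ = logging_rate(delta, np.array([[False]]), True, default_params)
        assert rF[0, 0] == pytest.approx(default_params.r0 * np.exp(-3.0))


def _mean_field_rhs(t, y, P_eff, params):
    """Independent RHS of the local model (fire at its expectation)."""
    F, T, S, G, B = y
    r = demographic_rates(P_eff, params)
    C = G + S
    cc = critical_cover(P_eff, params)
    f = local_fire_probability(C, cc, params)
    q = params.q0 * (1 - params.d * f)
    dF = r["g_F"] * F * (S + T + G) - r["m_F"] * F - params.b * f * F
    dT = q * S - r["m_T"] * T - r["g_F"] * F * T
    dS = r["g_T"] * T * G - q * S - r["m_S"] * S - r["g_F"] * F * S
    dB = r["m_GB"] * G - r["g_G"] * G * B
    dG = -(dF + dT + dS + dB)
    return [dF, dT, dS, dG, dB]


class TestStep:
    def _drivers(self, P, params, shape=(1, 1)):
        return Drivers.build(np.full(shape, float(P)), np.full(shape, np.inf),
                             np.zeros(shape, dtype=bool), params)

    def test_deterministic_increments_conserve_exactly(self, default_params):
        rng = np.random.default_rng(0)
        state = CoverState.random((7, 5), rng)
        drv = self._drivers(1500.0, default_params, (7, 5))
        f = rng.random((7, 5))
        rF = np.zeros((7, 5))
        d = deterministic_increments(state, f, drv.rates, rF, rF, default_params)
        np.testing.assert_allclose(sum(d), 0.0, atol=1e-15)

    def test_single_step_matches_ode_oracle(self):
        """One Euler step of the mean-field local model agrees with a
        high-resolution integration of the same right-hand side to O(dt^2)."""
        dt = 0.05
        params = ModelParams(sigma=0.0, D=0.0, dt=dt)
        y0 = [0.3, 0.1, 0.1, 0.4, 0.1]
        P = 1500.0
        state = CoverState.uniform((1, 1), y0)
        new, _ = step(state, self._drivers(P, params), params,
                      deterministic_fire=True)
        sol = solve_ivp(_mean_field_rhs, (0, dt), y0, args=(P, params),
                        rtol=1e-10, atol=1e-12)
        euler = np.array([getattr(new, k)[0, 0] for k in ("F", "T", "S", "G", "B")])
        np.testing.assert_allclose(euler, sol.y[:, -1], atol=5 * dt ** 2)

    def test_wet_forest_settles_below_full_cover(self, default_params):
        eq = local_equilibrium(2400.0, default_params, init="forest")
        F = eq.F[0, 0]
        assert 0.5 < F < 1.0
        # the equilibrium balances growth into free space against mortality
        r = demographic_rates(2400.0, default_params)
        assert F == pytest.approx(1 - r["m_F"] / r["g_F"], abs=0.02)

    def test_dry_grass_bare_equilibrium(self, default_params):
        eq = local_equilibrium(800.0, default_params, init="grass")
        r = demographic_rates(800.0, default_params)
        assert eq.B[0, 0] == pytest.approx(r["m_GB"] / r["g_G"], abs=0.01)
        assert eq.F[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_noise_requires_rng(self, default_params):
        state = CoverState.uniform((2, 2), [0.2, 0.2, 0.2, 0.2, 0.2])
        with pytest.raises(ValueError):
            step(state, self._drivers(1500.0, default_params, (2, 2)),
                 default_params, rng=None, deterministic_fire=True)


class TestSimulate:
    def test_same_seed_bit_identical(self, default_params):
        P = np.full((12, 12), 1500.0)
        a = simulate(P, default_params, seed=9, t_pre=20, t_end=30)
        b = simulate(P, default_params, seed=9, t_pre=20, t_end=30)
        np.testing.assert_array_equal(a.final.F, b.final.F)
        np.testing.assert_array_equal(a.mean_tree_cover, b.mean_tree_cover)

    def test_simplex_conserved_through_noisy_run(self, default_params):
        P = np.full((16, 16), 1500.0)
        res = simulate(P, default_params, seed=2, t_pre=60, t_end=100)
        total = res.final.stack().sum(axis=0)
        assert np.max(np.abs(total - 1.0)) < 1e-9
        res.final.validate()

    def test_very_wet_landscape_forests_everywhere(self, default_params):
        res = simulate(np.full((32, 32), 2600.0), default_params, seed=5,
                       t_pre=300, t_end=300)
        assert (res.tree_cover() > 40.0).mean() >= 0.99

    def test_very_dry_landscape_is_treeless(self, default_params):
        res = simulate(np.full((32, 32), 600.0), default_params, seed=5,
                       t_pre=300, t_end=300)
        assert (res.tree_cover() < 5.0).mean() >= 0.99

    def test_logging_monotonically_suppresses_forest(self, default_params):
        """Raising the managed removal rate never increases equilibrium
        forest cover (uniform managed landscape at wet climate)."""
        P = np.full((16, 16), 2200.0)
        delta = np.zeros((16, 16))
        agri = np.ones((16, 16), dtype=bool)
        means = []
        for r0 in (0.0, 0.05, 0.15, 0.4):
            res = simulate(P, default_params.replace(r0=r0), delta=delta,
                           agri_mask=agri, seed=3, t_pre=100, t_end=220)
            means.append(res.final.F.mean())
        assert all(a >= b - 0.02 for a, b in zip(means, means[1:]))
        assert means[-1] < 0.05

    def test_invalid_horizon(self, default_params):
        with pytest.raises(ValueError):
            simulate(np.full((8, 8), 1500.0), default_params, seed=0,
                     t_pre=100, t_end=50)


class TestSummaries:
    @pytest.mark.parametrize(
        "F, T, expected",
        [
            (0.5, 0.1, StateClass.FOREST),  # 60 %
            (0.0, 0.2, StateClass.SAVANNA),  # 20 %
            (0.02, 0.02, StateClass.TREELESS),  # 4 %
            (0.30, 0.10, StateClass.SAVANNA),  # exactly 40 % -> savanna
            (0.05, 0.00, StateClass.SAVANNA),  # exactly 5 % -> savanna
        ],
    )
    def test_class_cuts(self, F, T, expected):
        state = CoverState.uniform((1, 1), [F, T, 0.0, 1 - F - T, 0.0])
        tc, cls = summarize_state(state)
        assert tc[0, 0] == pytest.approx(100 * (F + T))
        assert cls[0, 0] == expected

    def test_agricultural_override(self):
        cls = classify_tree_cover(np.array([[80.0]]), np.array([[True]]))
        assert cls[0, 0] == StateClass.AGRICULTURAL


class TestParams:
    def test_toml_round_trip(self, tmp_path, default_params):
        path = tmp_path / "params.toml"
        default_params.to_toml(path)
        assert ModelParams.from_toml(path) == default_params

    def test_shipped_default_file_matches_code_defaults(self):
        from importlib import resources

        path = resources.files("firesavanna") / "params_default.toml"
        assert ModelParams.from_toml(path) == ModelParams()

    def test_stability_warning_fires_for_defaults(self, default_params):
        with pytest.warns(RuntimeWarning, match="outflow"):
            default_params.stability_check(include_humans=True)

    def test_phase_style_initialisation_excludes_grass(self):
        rng = np.random.default_rng(0)
        st = CoverState.random((20, 20), rng, include_grass=False)
        assert np.all(st.G == 0.0)
        st.validate()


class TestModelObject:
    def test_binds_fields_and_runs(self, default_params):
        from firesavanna.landscape import LandscapeConfig, generate_environment

        fields = generate_environment(LandscapeConfig(shape=(16, 16)), seed=4)
        model = FireVegetationModel(fields, params=default_params)
        assert model.P_eff.shape == fields.shape
        res = model.simulate(seed=1, t_pre=10, t_end=15)
        assert res.final.F.shape == fields.shape
        assert res.classify().shape == fields.shape
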