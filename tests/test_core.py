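"""Core ODE model: right-hand sides, steady-state maps, fixed points, PDL."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from tgfswitch import (
    CoreParams,
    ExtendedParams,
    SystemState,
    classify_stability,
    compute_pdl,
    core_rhs,
    dump_params,
    find_fixed_points,
    load_params,
    pdl_modulation,
    reduced_map,
    reduced_map_derivative,
    simulate_deterministic,
    steady_fmod,
    steady_thbs1,
    substitute_endogenous,
)
from tgfswitch.core import packaged_defaults

from conftest import brute_force_roots


class TestRightHandSide:
    def test_vanishes_at_fixed_points(self, endo_params):
        for fp in find_fixed_points(endo_params).points:
            assert np.allclose(core_rhs(fp.state, endo_params), 0.0, atol=1e-8)

    def test_fmod_production_at_origin(self):
        # at the zero state the FMOD equation reduces to its maximal rate b
        d = core_rhs(SystemState(0.0, 0.0, 0.0), CoreParams())
        assert d[1] == pytest.approx(0.33)

    def test_matches_term_by_term_hand_evaluation(self):
        # frozen independent evaluation of the three equations at (1, 0.1, 0.5)
        d = core_rhs((1.0, 0.1, 0.5), CoreParams())
        assert d[0] == pytest.approx(1.2508282353690179, rel=1e-12)
        assert d[1] == pytest.approx(-0.09786949771828964, rel=1e-12)
        assert d[2] == pytest.approx(-0.04545454545454547, rel=1e-12)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="fmod"):
            core_rhs((0.1, -0.2, 0.1), CoreParams())


class TestSteadyStateCurves:
    def test_thbs1_limits_and_half_saturation(self):
        p = CoreParams()
        assert steady_thbs1(0.0, p) == 0.0
        assert steady_thbs1(1e6, p) == pytest.approx(2.36, abs=1e-3)
        assert steady_thbs1(p.Ka ** (1 / p.na), p) == pytest.approx(1.18)

    def test_fmod_limits_and_half_saturation(self):
        p = CoreParams()
        assert steady_fmod(0.0, p) == pytest.approx(0.33)
        assert steady_fmod(1e6, p) == pytest.approx(0.0, abs=1e-6)
        assert steady_fmod(p.Kb ** (1 / p.nb), p) == pytest.approx(0.165)

    def test_monotonicity_over_dose_grid(self):
        p = CoreParams()
        doses = np.geomspace(1e-4, 100, 300)
        assert np.all(np.diff(steady_thbs1(doses, p)) >= 0)
        assert np.all(np.diff(steady_fmod(doses, p)) <= 0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            steady_thbs1(-0.1, CoreParams())


class TestReducedMap:
    def test_zero_at_origin(self, endo_params):
        assert reduced_map(0.0, endo_params) == 0.0

    def test_saturating_limit(self, endo_params):
        # analytic limit: TH -> a/d1, F -> 0, so f -> γ·(a/d1)/((a/d1)+K̃1)
        assert reduced_map(1e6, endo_params) == pytest.approx(
            3.5 * 2.36 / (2.36 + 0.46), rel=1e-3
        )

    def test_roots_coincide_with_full_system_zero_set(self, endo_params):
        # self-consistency: T − f(T) vanishes exactly where the TGF-β1
        # equation of the full system vanishes on the steady-state manifold
        grid = np.geomspace(1e-8, 5, 2000)
        lhs = grid - reduced_map(grid, endo_params)
        rhs = np.array(
            [
                -core_rhs(
                    (
                        float(steady_thbs1(t, endo_params)),
                        float(steady_fmod(t, endo_params)),
                        float(t),
                    ),
                    endo_params,
                )[2]
                for t in grid
            ]
        )
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_derivative_matches_finite_difference(self, endo_params):
        for t in (1e-4, 0.01, 0.5, 2.9):
            h = 1e-7 * max(t, 1.0)
            fd = (reduced_map(t + h, endo_params) - reduced_map(t - h, endo_params)) / (2 * h)
            assert reduced_map_derivative(t, endo_params) == pytest.approx(fd, rel=1e-5)


class TestFixedPoints:
    def test_zero_state_always_present_and_stable(self, endo_params):
        fps = find_fixed_points(endo_params)
        zero = fps.points[0]
        assert zero.state.tgfb1 == 0.0
        assert zero.state.fmod == pytest.approx(0.33)
        assert zero.stability == "stable"

    def test_low_gamma_single_state(self, endo_params):
        p = replace(endo_params, c=0.05)
        fps = find_fixed_points(p)
        assert len(fps.points) == 1

    def test_fitted_gamma_three_states_alternating(self, endo_params):
        fps = find_fixed_points(endo_params)
        assert [p.stability for p in fps.points] == ["stable", "unstable", "stable"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = CoreParams(
            a=float(rng.uniform(0.5, 5)),
            b=float(rng.uniform(0.1, 2)),
            c=float(rng.uniform(0.2, 8)),
            Ka=float(rng.uniform(1e-3, 0.5)),
            Kb=float(rng.uniform(1e-3, 0.5)),
            K1=float(rng.uniform(0.05, 5)),
            K2=float(rng.uniform(0.05, 5)),
            na=float(rng.uniform(1.1, 3)),
            nb=float(rng.uniform(1.1, 3)),
        )
        upper = 1.5 * p.c_over_d3 + 1.0
        expected = brute_force_roots(p, upper)
        got = find_fixed_points(p, (0.0, upper)).tgfb1_values()
        assert len(got) == len(expected)
        assert np.allclose(got, expected, atol=1e-6, rtol=1e-4)

    def test_inverted_interval_rejected(self, endo_params):
        with pytest.raises(ValueError, match="inverted"):
            find_fixed_points(endo_params, (5.0, 1.0))

    def test_interval_must_cover_map_supremum(self, endo_params):
        with pytest.raises(ValueError, match="supremum"):
            find_fixed_points(endo_params, (0.0, 1.0))


class TestStability:
    def test_zero_state_superlinear_map_slope_zero(self, endo_params):
        fp = classify_stability(0.0, endo_params)
        assert fp.stability == "stable"
        assert fp.slope == 0.0

    def test_reduced_and_jacobian_modes_agree(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = CoreParams(
                a=float(rng.uniform(0.5, 5)),
                c=float(rng.uniform(0.5, 8)),
                K1=float(rng.uniform(0.05, 5)),
                K2=float(rng.uniform(0.05, 5)),
                na=float(rng.uniform(1.1, 3)),
                nb=float(rng.uniform(1.1, 3)),
            )
            for t in find_fixed_points(p).tgfb1_values():
                red = classify_stability(t, p, mode="reduced")
                jac = classify_stability(t, p, mode="jacobian")
                assert red.stability == jac.stability

    def test_non_fixed_point_rejected(self, endo_params):
        with pytest.raises(ValueError, match="fixed-point"):
            classify_stability(1.0, endo_params)


class TestDeterministicSimulation:
    def test_fixed_point_initial_stays_constant(self, endo_params):
        fp = find_fixed_points(endo_params).points[-1]
        _, states = simulate_deterministic(fp.state, endo_params, t_end=5.0, dt=0.01)
        assert np.allclose(states, states[0], atol=1e-6)

    def test_basins_split_at_unstable_root(self, endo_params):
        fps = find_fixed_points(endo_params)
        unstable = fps.points[1].state.tgfb1
        upper = fps.points[2].state.tgfb1
        for t0, target in ((unstable * 3, upper), (unstable / 3, 0.0)):
            _, states = simulate_deterministic(
                SystemState(0.0, 0.0, t0), endo_params, t_end=100.0, dt=0.01
            )
            assert states[-1, 2] == pytest.approx(target, abs=1e-4)

    def test_euler_first_order_convergence(self, endo_params):
        x0 = SystemState(0.1, 0.1, 1.0)
        ends = {}
        for dt in (0.02, 0.01, 0.005):
            _, states = simulate_deterministic(x0, endo_params, t_end=2.0, dt=dt)
            ends[dt] = states[-1]
        err_coarse = np.abs(ends[0.02] - ends[0.005]).max()
        err_fine = np.abs(ends[0.01] - ends[0.005]).max()
        assert err_fine < err_coarse


class TestEndogenousSubstitution:
    def test_installs_printed_values(self):
        p = substitute_endogenous(ExtendedParams())
        assert p.c_over_d3 == pytest.approx(3.5)
        assert p.K1 == pytest.approx(0.46)
        assert p.K2 == pytest.approx(0.62)

    def test_identity_substitution(self):
        core = CoreParams(c=2.0, K1=0.3, K2=0.7)
        ext = ExtendedParams(gamma=2.0, K1t=0.3, K2t=0.7)
        assert substitute_endogenous(ext, core) == core

    def test_scale_invariance_of_fold_structure(self, endo_params):
        # jointly scaling a/d1 and K1 leaves the fixed-point count unchanged
        for gamma in (0.05, 0.5, 3.5):
            p1 = replace(endo_params, c=gamma)
            p2 = replace(endo_params, c=gamma, a=endo_params.a * 3, K1=endo_params.K1 * 3)
            assert len(find_fixed_points(p1).points) == len(find_fixed_points(p2).points)


class TestPDL:
    def test_modulation_limits(self):
        ext = ExtendedParams()
        assert pdl_modulation(0.0, ext) == (0.0, 5.0)
        th_inf, f_inf = pdl_modulation(1e9, ext)
        assert th_inf == pytest.approx(3.0, rel=1e-6)
        assert f_inf == pytest.approx(0.0, abs=1e-6)
        th_half, _ = pdl_modulation(10.1, ext)
        assert th_half == pytest.approx(1.5)

    @given(st.floats(0.1, 1e6), st.floats(0.0, 60.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pdl_formula_doubling_property(self, b, x):
        # one doubling of the population adds 3.32·log10(2) ≈ 0.9994 PDL
        one = compute_pdl(2 * b, b, x)
        assert one == pytest.approx(x + 3.32 * np.log10(2), rel=1e-9)

    def test_printed_examples(self):
        assert compute_pdl(1.0, 1.0, 17.0) == 17.0
        assert compute_pdl(8.0, 1.0, 24.0) == pytest.approx(26.998258756813254)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_pdl(0.0, 1.0, 5.0)


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        p = CoreParams(a=1.7, Ka=0.05)
        path = tmp_path / "p.yaml"
        dump_params(p, path)
        assert load_params(path) == p

    def test_json_round_trip(self, tmp_path):
        e = ExtendedParams(gamma=1.25)
        path = tmp_path / "e.json"
        dump_params(e, path)
        assert load_params(path, kind="extended") == e

    def test_packaged_defaults_carry_fitted_values(self):
        d = packaged_defaults()
        assert d["core"]["a"] == 2.36
        assert d["core"]["Kb"] == 0.002
        assert d["extended"]["Kalpha"] == 10.1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="na"):
            CoreParams(na=0.5)
        with pytest.raises(ValueError, match="Ka"):
            CoreParams(Ka=-1.0)
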