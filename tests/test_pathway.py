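"""Reduced TGF-β–VEGF network: conservation, interventions, sensitivity, DE."""

import numpy as np
import pytest

from tgfswitch import (
    NoiseSpec,
    Reaction,
    ReactionNetwork,
    StimulusProtocol,
    build_reduced_network,
    estimate_parameters,
    gen_timecourse,
    integral_metric,
    normalize_minmax,
    sensitivity,
    simulate,
    training_sse,
)
from tgfswitch.pathway import CONSERVED_POOLS, SMAD_POOLS_NM

HOURS_48 = (0.0, 48.0)


class TestNetworkConstruction:
    def test_smad_pools_use_measured_concentrations(self):
        net = build_reduced_network(equilibrate=False)
        assert net.species["SMAD4"] == SMAD_POOLS_NM["SMAD4"] == 0.0044
        assert net.species["SMAD4"] == min(
            net.species[s] for s in ("SMAD2", "SMAD3", "SMAD4")
        )

    def test_stoichiometry_balances_every_conserved_pool(self, network):
        for pool in CONSERVED_POOLS:
            balance = network.stoichiometry_balance(pool)
            assert all(v == 0 for v in balance.values()), pool

    def test_unknown_override_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            build_reduced_network({"species_overrides": {"NOPE": 1.0}}, equilibrate=False)

    def test_yaml_round_trip_simulates_identically(self, network, tmp_path):
        path = tmp_path / "net.yaml"
        network.to_yaml(path)
        reloaded = ReactionNetwork.from_yaml(path)
        protocol = StimulusProtocol(tgfb1_dose=1.0, t_grid=HOURS_48)
        a = simulate(network, protocol, horizon=48.0)
        b = simulate(reloaded, protocol, horizon=48.0)
        assert np.allclose(a.species.to_numpy(), b.species.to_numpy(), rtol=1e-10)


class TestSimulation:
    def test_zero_dose_baseline_is_flat(self, network):
        traj = simulate(network, StimulusProtocol(tgfb1_dose=0.0, t_grid=HOURS_48), horizon=48.0)
        obs = traj.observable_table()
        drift = (obs.max() - obs.min()) / (obs.mean().abs() + 1e-12)
        assert (drift < 1e-3).all()

    def test_stimulation_induces_thbs1_and_represses_fmod(self, network):
        traj = simulate(network, StimulusProtocol(tgfb1_dose=1.0, t_grid=HOURS_48), horizon=48.0)
        assert traj.species["THBS1"].iloc[-1] > 10 * network.species["THBS1"]
        assert traj.species["FMOD"].iloc[-1] < 0.5 * network.species["FMOD"]

    def test_washout_removes_external_input(self, network):
        protocol = StimulusProtocol(tgfb1_dose=1.0, washout_time=4.0, t_grid=HOURS_48)
        assert protocol.external_input(3.9) == 1.0
        assert protocol.external_input(4.0) == 0.0

    def test_smad4_pool_conserved_along_trajectory(self, network):
        traj = simulate(network, StimulusProtocol(tgfb1_dose=1.0, t_grid=HOURS_48), horizon=48.0)
        total = sum(traj.species[m] for m in CONSERVED_POOLS["SMAD4"])
        expected = sum(network.species[m] for m in CONSERVED_POOLS["SMAD4"])
        assert np.allclose(total, expected, rtol=1e-6)

    def test_all_conserved_pools_constant(self, network):
        traj = simulate(network, StimulusProtocol(tgfb1_dose=1.0, t_grid=HOURS_48), horizon=48.0)
        for pool, members in CONSERVED_POOLS.items():
            total = sum(traj.species[m] for m in members)
            assert np.allclose(total, total.iloc[0], rtol=1e-6), pool

    def test_grid_beyond_horizon_rejected(self, network):
        with pytest.raises(ValueError, match="horizon"):
            simulate(network, StimulusProtocol(t_grid=(0.0, 60.0)), horizon=48.0)


class TestInterventionCalibration:
    """Qualitative orderings the shipped parameterization is calibrated to."""

    def test_smad4_knockdown_strongest(self, network):
        base = integral_metric(
            simulate(network, StimulusProtocol(tgfb1_dose=1.0, t_grid=HOURS_48), horizon=48.0),
            "THBS1",
        )
        rel = {}
        for pool in ("SMAD2", "SMAD3", "SMAD4"):
            protocol = StimulusProtocol(
                tgfb1_dose=1.0, knockdowns=((pool, 0.2),), t_grid=HOURS_48
            )
            rel[pool] = integral_metric(simulate(network, protocol, horizon=48.0), "THBS1") / base
        assert rel["SMAD4"] < rel["SMAD2"]
        assert rel["SMAD4"] < rel["SMAD3"]

    def test_akt_inhibition_timing_breakpoint(self, network):
        fmod0 = network.species["FMOD"]
        terminal = {}
        for t_i in (0.0, 8.0, 24.0, 32.0):
            protocol = StimulusProtocol(
                tgfb1_dose=1.0, inhibitor_events=(("pAkt", t_i, 0.1),), t_grid=HOURS_48
            )
            traj = simulate(network, protocol, horizon=48.0)
            terminal[t_i] = float(traj.species["FMOD"].iloc[-1])
        for t_i in (0.0, 8.0, 24.0):
            assert abs(terminal[t_i] - fmod0) / fmod0 <= 0.2, t_i
        assert abs(terminal[32.0] - fmod0) / fmod0 > 0.2

    def test_thbs1_more_input_sensitive_than_fmod(self, network):
        th1 = integral_metric(
            simulate(network, StimulusProtocol(tgfb1_dose=1.0, t_grid=HOURS_48), horizon=48.0),
            "THBS1",
        )
        th10 = integral_metric(
            simulate(network, StimulusProtocol(tgfb1_dose=10.0, t_grid=HOURS_48), horizon=48.0),
            "THBS1",
        )
        f1 = integral_metric(
            simulate(network, StimulusProtocol(vegf_dose=1.0, t_grid=HOURS_48), horizon=48.0),
            "FMOD",
        )
        f10 = integral_metric(
            simulate(network, StimulusProtocol(vegf_dose=10.0, t_grid=HOURS_48), horizon=48.0),
            "FMOD",
        )
        assert th10 / th1 > f10 / f1

    def test_transient_and_sustained_inputs_agree(self, network):
        sustained = simulate(
            network, StimulusProtocol(tgfb1_dose=1.0, t_grid=HOURS_48), horizon=48.0
        )
        washout = simulate(
            network,
            StimulusProtocol(tgfb1_dose=1.0, washout_time=4.0, t_grid=HOURS_48),
            horizon=48.0,
        )
        a = sustained.species["THBS1"].iloc[-1]
        b = washout.species["THBS1"].iloc[-1]
        assert abs(a - b) / a <= 0.2


class TestMetricsAndSensitivity:
    def test_integral_of_constant_and_ramp(self, network):
        import pandas as pd
        from tgfswitch import TrajectorySet

        times = np.linspace(0.0, 10.0, 21)
        const = TrajectorySet(
            times=times,
            species=pd.DataFrame({"X": np.full_like(times, 3.0)}),
            protocol=StimulusProtocol(t_grid=(0.0, 10.0)),
        )
        assert integral_metric(const, "X") == pytest.approx(30.0)
        ramp = TrajectorySet(
            times=times,
            species=pd.DataFrame({"X": 0.5 * times}),
            protocol=StimulusProtocol(t_grid=(0.0, 10.0)),
        )
        assert integral_metric(ramp, "X") == pytest.approx(25.0)

    def test_disconnected_decoy_has_zero_coefficient(self):
        net = build_reduced_network({"include_decoy": True})
        sm = sensitivity(
            net,
            StimulusProtocol(tgfb1_dose=1.0, t_grid=HOURS_48),
            targets=["decoy_turnover"],
        )
        assert abs(sm.coefficients[0]) < 1e-8

    def test_pass_through_network_has_unit_coefficient(self):
        # toy chain: constant synthesis of X scaled by k, M = integral of X
        net = ReactionNetwork(
            species={"X": 1.0},
            reactions=[Reaction("x_in", {"X": +1}, lambda c, p: p["k"]),
                       Reaction("x_out", {"X": -1}, lambda c, p: c["X"])],
            parameters={"k": 1.0},
        )
        sm = sensitivity(
            net,
            StimulusProtocol(t_grid=(0.0, 200.0)),
            metric_species="X",
            targets=["x_in"],
            horizon=200.0,
        )
        assert sm.coefficients[0] == pytest.approx(1.0, abs=0.02)

    def test_trimer_tops_single_smad_reactions(self, network):
        sm = sensitivity(
            network,
            StimulusProtocol(tgfb1_dose=1.0, t_grid=HOURS_48),
            targets=[
                "smad_trimer_formation",
                "smad2_phosphorylation",
                "smad3_phosphorylation",
            ],
        )
        tri, s2, s3 = np.abs(sm.coefficients)
        assert tri > s2 and tri > s3

    def test_species_mode_requires_nonzero_initial(self):
        net = build_reduced_network(equilibrate=False)  # S234 starts at zero
        with pytest.raises(ValueError, match="zero initial"):
            sensitivity(
                net,
                StimulusProtocol(tgfb1_dose=1.0, t_grid=HOURS_48),
                target_kind="species",
                targets=["S234"],
            )


class TestNormalization:
    def test_basic_and_fixed_point(self):
        assert np.allclose(normalize_minmax([0.0, 5.0, 10.0]), [0.0, 0.5, 1.0])
        x = np.array([0.0, 0.25, 1.0])
        assert np.allclose(normalize_minmax(x), x)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        assert np.allclose(normalize_minmax(3.5 * x - 2.0), normalize_minmax(x))

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_minmax([2.0, 2.0, 2.0])


class TestParameterEstimation:
    def test_de_runs_return_requested_sets_with_monotone_traces(self, network):
        training = gen_timecourse(network, noise=NoiseSpec(cv=0.05, seed=2))
        runs = estimate_parameters(
            network, training, ["k_th", "k_fdeg"], n_runs=3, maxiter=4, popsize=4
        )
        assert len(runs) == 3
        assert len({r["seed"] for r in runs}) == 3
        for r in runs:
            trace = r["objective_trace"]
            assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_de_deterministic_given_seed(self, network):
        training = gen_timecourse(network, noise=NoiseSpec(cv=0.05, seed=2))
        a = estimate_parameters(network, training, ["k_th"], n_runs=1, maxiter=3, popsize=4)
        b = estimate_parameters(network, training, ["k_th"], n_runs=1, maxiter=3, popsize=4)
        assert a[0]["objective"] == b[0]["objective"]
        assert a[0]["parameters"] == b[0]["parameters"]

    def test_recovery_from_self_generated_data(self, network):
        # 8 time points, N = 3, 5% noise: the best run's simulated observables
        # track the generating curves
        training = gen_timecourse(network, noise=NoiseSpec(cv=0.05, n_replicates=3, seed=7))
        runs = estimate_parameters(
            network, training, ["k_th", "k_fdeg"], n_runs=2, maxiter=12, popsize=6
        )
        best = min(runs, key=lambda r: r["objective"])
        fitted = network.with_parameters(best["parameters"])
        protocol = StimulusProtocol(tgfb1_dose=1.0)
        truth = simulate(network, protocol, horizon=48.0)
        fit = simulate(fitted, protocol, horizon=48.0)
        for obs_species in ("THBS1", "FMOD"):
            a = normalize_minmax(truth.species[obs_species].to_numpy())
            b = normalize_minmax(fit.species[obs_species].to_numpy())
            rmse = np.sqrt(np.mean((a - b) ** 2))
            assert rmse < 0.10, obs_species

    def test_unbounded_parameter_rejected(self, network):
        training = gen_timecourse(network, noise=NoiseSpec(cv=0.0))
        net = network.with_parameters({})
        net.bounds = {k: v for k, v in network.bounds.items() if k != "k_th"}
        with pytest.raises(ValueError, match="bounds"):
            estimate_parameters(net, training, ["k_th"], n_runs=1)
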