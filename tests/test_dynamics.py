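"""Deterministic and Langevin integration of the dimer equations."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tetdimer import (
    DimerParams,
    IntegratorConfig,
    NoiseModel,
    SystemState,
    equations_of_motion,
    initial_state,
    integrate,
    run_ensemble,
)


GENERIC_STATE = SystemState(
    phi_D=np.sqrt(0.6) + 0j,
    phi_A=np.sqrt(0.4) * np.exp(0.3j),
    u_z=0.5, u_x=-0.1, p_z=0.2, p_x=0.1,
)


class TestInitialState:
    def test_donor_localised_symmetric_mode_is_zero(self, tet_params):
        state = initial_state(tet_params, "donor")
        assert state.u_x == 0.0

    def test_donor_localised_ionic_mode_sign(self):
        # u_z = -(k_z/Omega_z^2) * (|phi_A|^2 - |phi_D|^2) = -(1)*(0-1) = +1
        state = initial_state(DimerParams(k_z=1.0, Omega_z=1.0), "donor")
        assert state.u_z == pytest.approx(1.0)

    @pytest.mark.parametrize("site", ["donor", "acceptor"])
    def test_normalised(self, site, near_tet_params):
        assert initial_state(near_tet_params, site).norm2 == 1.0

    def test_unknown_site_rejected(self, tet_params):
        with pytest.raises(ValueError):
            initial_state(tet_params, "bridge")


class TestDeterministicIntegration:
    def test_energy_conserved_without_damping(self, tet_params):
        params = tet_params.replace(gamma_z=0.0, gamma_x=0.0)
        traj = integrate(GENERIC_STATE, params,
                         config=IntegratorConfig(t_max=200.0))
        assert np.abs(traj.energy - traj.energy[0]).max() < 1e-8

    def test_damped_energy_decay_matches_dissipation_identity(self):
        """With damping but no noise, dH/dt = -gamma_z p_z^2 - gamma_x p_x^2;
        the finely sampled energy series must reproduce it to discretisation
        accuracy, and the energy must be monotone non-increasing."""
        params = DimerParams(E_D=0.0, E_A=0.0, gamma_z=0.2, gamma_x=0.3)
        traj = integrate(GENERIC_STATE, params,
                         config=IntegratorConfig(t_max=20.0, sample_stride=1))
        assert np.all(np.diff(traj.energy) <= 1e-14)
        dHdt = np.diff(traj.energy) / traj.dt
        dissipation = -(params.gamma_z * traj.y[:, 5] ** 2
                        + params.gamma_x * traj.y[:, 7] ** 2)
        midpoint = 0.5 * (dissipation[1:] + dissipation[:-1])
        assert np.abs(dHdt - midpoint).max() < 1e-6

    def test_agrees_with_independent_adaptive_integrator(self, near_tet_params):
        """Dual route: the compiled fixed-step kernel against scipy's DOP853
        driven by the Python-level equations_of_motion."""
        params = near_tet_params

        def rhs(t, y):
            d = equations_of_motion(SystemState.from_vector(y), params)
            return [d.phi_D.real, d.phi_D.imag, d.phi_A.real, d.phi_A.imag,
                    d.u_z, d.p_z, d.u_x, d.p_x]

        traj = integrate(GENERIC_STATE, params, config=IntegratorConfig(t_max=20.0))
        sol = solve_ivp(rhs, (0.0, traj.times[-1]), GENERIC_STATE.as_vector(),
                        t_eval=traj.times, method="DOP853",
                        rtol=1e-12, atol=1e-12)
        assert np.abs(sol.y.T - traj.y).max() < 1e-9

    def test_step_halving_convergence(self, near_tet_params):
        """Fifth-order method: halving dt shrinks the error against a fine
        reference by roughly 2^5."""
        ref = integrate(GENERIC_STATE, near_tet_params,
                        config=IntegratorConfig(dt=0.001, t_max=10.0,
                                                sample_stride=1000))
        errs = []
        for dt, stride in ((0.1, 10), (0.05, 20)):
            traj = integrate(GENERIC_STATE, near_tet_params,
                             config=IntegratorConfig(dt=dt, t_max=10.0,
                                                     sample_stride=stride))
            errs.append(np.abs(traj.y[:, :4] - ref.y[:, :4]).max())
        assert errs[1] < errs[0] / 16

    def test_norm_conserved_over_long_horizon(self, tet_params):
        traj = integrate(initial_state(tet_params), tet_params,
                         config=IntegratorConfig(t_max=1000.0))
        assert np.abs(traj.P_D + traj.P_A - 1.0).max() < 1e-6

    def test_norm_drift_beyond_tolerance_is_a_hard_error(self, near_tet_params):
        with pytest.raises(RuntimeError, match="norm drift"):
            integrate(initial_state(near_tet_params), near_tet_params,
                      config=IntegratorConfig(dt=0.5, t_max=2000.0))

    def test_renormalize_option_keeps_norm_exact(self, near_tet_params):
        traj = integrate(initial_state(near_tet_params), near_tet_params,
                         config=IntegratorConfig(dt=0.01, t_max=50.0,
                                                 renormalize=True))
        assert np.abs(traj.P_D + traj.P_A - 1.0).max() < 1e-12

    def test_exchange_symmetry_of_trajectories(self):
        """An acceptor-localised start with swapped on-site energies retraces
        the donor run with the roles of the sites exchanged."""
        params = DimerParams(E_D=0.5, E_A=0.0, eps_x=-0.05,
                             gamma_z=0.1, gamma_x=0.1)
        swapped = params.replace(E_D=params.E_A, E_A=params.E_D)
        cfg = IntegratorConfig(t_max=50.0)
        donor_run = integrate(initial_state(params, "donor"), params, config=cfg)
        acceptor_run = integrate(initial_state(swapped, "acceptor"), swapped,
                                 config=cfg)
        np.testing.assert_allclose(acceptor_run.P_D, donor_run.P_A, atol=1e-9)
        np.testing.assert_allclose(acceptor_run.u_z, -donor_run.u_z, atol=1e-9)


class TestLangevinIntegration:
    def test_zero_temperature_consumes_no_randomness(self, tet_params):
        assert NoiseModel(kBT=0.0, seed=5).draw_forces(100, 0.001, tet_params) is None
        cfg = IntegratorConfig(t_max=5.0)
        s0 = initial_state(tet_params)
        a = integrate(s0, tet_params, NoiseModel(kBT=0.0, seed=1), cfg)
        b = integrate(s0, tet_params, None, cfg)
        np.testing.assert_array_equal(a.y, b.y)

    def test_fixed_seed_is_bitwise_reproducible(self, tet_params):
        cfg = IntegratorConfig(t_max=5.0)
        s0 = initial_state(tet_params)
        a = integrate(s0, tet_params, NoiseModel(kBT=1.5, seed=7), cfg)
        b = integrate(s0, tet_params, NoiseModel(kBT=1.5, seed=7), cfg)
        c = integrate(s0, tet_params, NoiseModel(kBT=1.5, seed=8), cfg)
        np.testing.assert_array_equal(a.y, b.y)
        assert np.abs(a.y - c.y).max() > 0

    def test_noise_variance_scaling(self, tet_params):
        forces = NoiseModel(kBT=1.5, seed=0).draw_forces(200_000, 0.001, tet_params)
        expected_var = 2 * tet_params.gamma_z * 1.5 / 0.001
        assert forces[:, 0].var() == pytest.approx(expected_var, rel=0.02)

    def test_fluctuation_dissipation_equilibration(self):
        """A damped mode decoupled from the electron must thermalise to the
        equipartition value Omega^2 <u^2> / 2 = kBT / 2, validating the
        2 gamma kBT / dt noise-variance convention."""
        params = DimerParams(k_z=0.0, k_x=0.0, Omega_z=1.0, Omega_x=1.3,
                             gamma_z=0.2, gamma_x=0.2)
        kBT = 0.7
        estimates = []
        for seed in range(3):
            traj = integrate(SystemState(phi_D=1.0 + 0j, phi_A=0j), params,
                             NoiseModel(kBT=kBT, seed=seed),
                             IntegratorConfig(t_max=3000.0, sample_stride=5))
            burn = len(traj.times) // 4
            estimates.append(0.5 * params.Omega_z ** 2
                             * np.mean(traj.u_z[burn:] ** 2))
            estimates.append(0.5 * params.Omega_x ** 2
                             * np.mean(traj.u_x[burn:] ** 2))
        assert np.mean(estimates) == pytest.approx(kBT / 2, rel=0.1)

    def test_transfer_integral_sign_change_warns_and_strict_raises(self, near_tet_params):
        s0 = initial_state(near_tet_params)
        with pytest.warns(RuntimeWarning, match="changed sign"):
            traj = integrate(s0, near_tet_params,
                             config=IntegratorConfig(t_max=100.0))
        assert traj.transfer_sign_flips > 0
        with pytest.raises(RuntimeError, match="changed sign"):
            integrate(s0, near_tet_params,
                      config=IntegratorConfig(t_max=100.0,
                                              strict_transfer_sign=True))


class TestEnsembles:
    def test_single_member_matches_direct_call(self, tet_params):
        cfg = IntegratorConfig(t_max=5.0)
        members = run_ensemble(tet_params, 1.5, 1, base_seed=11, config=cfg)
        direct = integrate(initial_state(tet_params), tet_params,
                           NoiseModel(kBT=1.5, seed=11), cfg)
        np.testing.assert_array_equal(members[0].y, direct.y)

    def test_noise_free_members_are_identical(self, tet_params):
        members = run_ensemble(tet_params, 0.0, 5, base_seed=0,
                               config=IntegratorConfig(t_max=5.0))
        for member in members[1:]:
            np.testing.assert_array_equal(member.y, members[0].y)

    def test_members_share_time_grid(self, tet_params):
        members = run_ensemble(tet_params, 1.0, 3, base_seed=0,
                               config=IntegratorConfig(t_max=5.0))
        for member in members[1:]:
            np.testing.assert_array_equal(member.times, members[0].times)

    def test_invalid_size_rejected(self, tet_params):
        with pytest.raises(ValueError):
            run_ensemble(tet_params, 1.0, 0, base_seed=0)


class TestTrajectoryExport:
    def test_csv_and_sidecar_round_trip(self, tmp_path, tet_params):
        import json

        import pandas as pd

        traj = integrate(initial_state(tet_params), tet_params,
                         NoiseModel(kBT=1.0, seed=3),
                         IntegratorConfig(t_max=2.0))
        csv_path = tmp_path / "traj.csv"
        traj.to_csv(csv_path)
        frame = pd.read_csv(csv_path)
        assert list(frame.columns) == [
            "t", "re_phi_D", "im_phi_D", "re_phi_A", "im_phi_A",
            "P_D", "P_A", "u_z", "u_x", "p_z", "p_x", "energy"]
        np.testing.assert_allclose(frame["P_A"], traj.P_A)
        meta_path = tmp_path / "traj.json"
        traj.write_sidecar(meta_path)
        meta = json.loads(meta_path.read_text())
        assert meta["seed"] == 3 and meta["dt"] == 0.001
        assert meta["params"] == tet_params.to_dict()
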