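import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from cortnet import (AmplitudeFlowModel, BlowUpError, SimConfig, Trajectory,
                     amplitude_phase, clamp_phase, complexify, decomplexify,
                     network_rhs, simulate, simulate_batch)
from cortnet.simulate import read_trajectory_text, write_trajectory_text

from conftest import OMEGA, single_population_net, two_column_net


class TestComplexify:
    @pytest.mark.parametrize("q,p,omega,expected", [
        (1.0, 0.0, 2.0, 1.0 + 0.0j),
        (0.0, 0.0, 1.0, 0.0 + 0.0j),
        (0.3, -0.4, 2.0, 0.3 - 0.2j),
    ])
    def test_z_definition(self, q, p, omega, expected):
        assert complexify(q, p, omega) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10),
           st.floats(0.1, 50, exclude_min=True))
    def test_roundtrip_exact(self, q, p, omega):
        q2, p2 = decomplexify(complexify(q, p, omega), omega)
        assert q2 == q
        assert p2 == pytest.approx(p, rel=1e-15, abs=1e-300)

    def test_invalid_omega(self):
        with pytest.raises(ValueError):
            complexify(1.0, 0.0, 0.0)


class TestNetworkRhs:
    def test_zero_coupling_is_pure_rotation(self):
        net = single_population_net(p_scale=0.0)
        z = np.array([[0.7 * np.exp(0.3j)]])
        dz = network_rhs(z, net)
        assert dz[0, 0] == pytest.approx(-1j * OMEGA * z[0, 0])
        # no amplitude change: radial component vanishes
        assert np.real(np.conj(z[0, 0]) * dz[0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_raises(self):
        net = single_population_net()
        with pytest.raises(ValueError):
            network_rhs(np.zeros((2, 2), dtype=complex), net)

    def test_real_and_complex_forms_agree(self):
        """Euler stepping the (q, p) equations and the complexified
        equation from matched initial conditions agree to 1e-10/step."""
        p_scale, p11 = 0.02, 1.0
        net = single_population_net(p_scale=p_scale, p_self=p11)
        k = net.columns[0].kernel
        dt, n_steps = 1e-3, 500
        z = 1.3 * np.exp(0.4j)
        q, p = z.real, OMEGA * z.imag
        for _ in range(n_steps):
            z = z + dt * network_rhs(np.array([[z]]), net)[0, 0]
            dp = -OMEGA**2 * q + p_scale * OMEGA**2 * p11 * k.P(p / OMEGA)
            q, p = q + dt * p, p + dt * dp
            assert abs(z - complexify(q, p, OMEGA)) < 1e-10


class TestSimulate:
    def test_free_rotation_conserves_amplitude_to_euler_order(self):
        net = single_population_net()
        dt, t_end = 1e-3, 1.0
        cfg = SimConfig(dt=dt, t_end=t_end)
        traj = simulate(net, cfg, np.array([[1.0 + 0j]]))
        drift = np.abs(np.abs(traj.z[:, 0, 0]) - 1.0).max()
        K = 1.1 * OMEGA**2 * t_end / 2  # first-order Euler inflation constant
        assert drift <= K * dt

    def test_same_seed_bit_identical(self):
        net = single_population_net(p_scale=0.01)
        cfg = SimConfig(dt=1e-3, t_end=0.5, noise_sigma=0.1, seed=11)
        z0 = np.array([[0.5 + 0j]])
        t1 = simulate(net, cfg, z0)
        t2 = simulate(net, cfg, z0)
        assert np.array_equal(t1.z, t2.z)

    def test_trial_reproducible_in_isolation(self):
        net = single_population_net(p_scale=0.01)
        cfg = SimConfig(dt=1e-3, t_end=0.2, noise_sigma=0.1, seed=5)
        z0 = np.array([[0.5 + 0j]])
        _, z_batch = simulate_batch(net, cfg, z0, 4)
        _, z_again = simulate_batch(net, cfg, z0, 4)
        assert np.array_equal(z_batch, z_again)

    def test_blowup_reports_first_offending_time(self):
        # sign-flipped self-coupling turns the linear P-term into
        # exponential amplitude growth at rate omega/2
        from cortnet import ColumnSpec, KernelSpec, NetworkSpec, PopulationSpec
        col = ColumnSpec(populations=(PopulationSpec(OMEGA),),
                         s_mat=np.zeros((1, 1)), p_mat=np.array([[-1.0]]),
                         p_scale=1.0,
                         kernel=KernelSpec(p_coeffs=(1.0, 0.0, 0.0),
                                           saturation=1e12))
        net = NetworkSpec(columns=(col,), r_s_ref=1.0)
        cfg = SimConfig(dt=1e-3, t_end=10.0, blowup=1e3)
        with pytest.raises(BlowUpError) as err:
            simulate(net, cfg, np.array([[1.0 + 0j]]))
        assert 0 < err.value.t < 10.0

    def test_per_cycle_drift_matches_reduced_flow(self):
        """Adiabatic oracle: one period of the full simulator reproduces
        the cycle-averaged flow prediction within 2% of its scale."""
        p_scale = 0.01
        net = single_population_net(p_scale=p_scale)
        flow = AmplitudeFlowModel(omega=OMEGA, p_scale=p_scale)
        period = 2 * np.pi / OMEGA
        cfg = SimConfig(dt=period * 1e-5, t_end=period, record_stride=10 ** 5)
        R0 = np.arange(0.2, 2.45, 0.2)          # spans [0, 1.2 R_s]
        z0 = R0.astype(complex)[:, None, None]
        _, z_rec = simulate_batch(net, cfg, z0, n_trials=R0.size)
        meas = np.abs(z_rec[:, -1, 0, 0]) - R0
        pred = np.array([
            solve_ivp(lambda t, y: flow.dR_dt(y), (0, period), [r],
                      rtol=1e-12, atol=1e-14).y[0, -1] - r
            for r in R0
        ])
        assert np.abs(meas - pred).max() < 0.02 * np.abs(pred).max()


class TestClampPhase:
    def test_zero_lag_copies_driver_phase(self):
        z = np.array([[0.8 * np.exp(0.9j)], [1.5 * np.exp(-2.0j)]])
        out = clamp_phase(z, 0, 1, 0.0)
        assert np.angle(out[1, 0]) == pytest.approx(0.9)
        assert abs(out[1, 0]) == pytest.approx(1.5)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-np.pi, np.pi), st.floats(0.01, 3), st.floats(0.01, 3),
           st.floats(-np.pi, np.pi), st.floats(-np.pi, np.pi))
    def test_idempotent_and_amplitude_preserving(self, lag, r1, r2, a1, a2):
        z = np.array([[r1 * np.exp(1j * a1)], [r2 * np.exp(1j * a2)]])
        once = clamp_phase(z, 0, 1, lag)
        twice = clamp_phase(once, 0, 1, lag)
        assert np.allclose(once, twice)
        assert abs(once[1, 0]) == pytest.approx(r2, rel=1e-12)

    def test_bad_index(self):
        z = np.zeros((2, 1), dtype=complex)
        with pytest.raises(IndexError):
            clamp_phase(z, 0, 5, 0.0)


class TestAmplitudePhase:
    @pytest.mark.parametrize("z,R,phi", [
        (1.0 + 0j, 1.0, 0.0),
        (0.0 + 0j, 0.0, 0.0),       # documented tie-break at the origin
        (-2j, 2.0, -np.pi / 2),
    ])
    def test_polar_decomposition(self, z, R, phi):
        traj = Trajectory(np.array([0.0]), np.array([[[z]]]))
        Rs, phis = amplitude_phase(traj)
        assert Rs[0, 0, 0] == pytest.approx(R)
        assert phis[0, 0, 0] == pytest.approx(phi)

    def test_reconstruction(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(5, 2, 1)) + 1j * rng.normal(size=(5, 2, 1))
        traj = Trajectory(np.arange(5.0), z)
        R, phi = amplitude_phase(traj)
        assert np.allclose(R * np.exp(1j * phi), z)


def test_trajectory_text_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    z = rng.normal(size=(7, 2, 1)) + 1j * rng.normal(size=(7, 2, 1))
    traj = Trajectory(np.linspace(0, 1, 7), z)
    path = tmp_path / "traj.tsv"
    write_trajectory_text(traj, path)
    back = read_trajectory_text(path, 2, 1)
    assert np.array_equal(back.z, traj.z)
    assert np.array_equal(back.times, traj.times)
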