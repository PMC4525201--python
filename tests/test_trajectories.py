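import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosagecomp.popgen_core import ExpressionState, ModelParams, drift_matrix
from dosagecomp.trajectories import (
    DegradationProfile,
    Trajectory,
    default_initial_state,
    degradation_profile,
    rescale_time,
    solve_expected,
    stationary_covariance,
    stationary_variance,
    time_to_recover,
    unrescale_time,
)

FIG1D = dict(system="XY", S_m=1.0, S_f=0.1, rho=0.8, Ne=1125.0, mu=3e-4)


class TestRescaleTime:
    def test_zero(self):
        assert rescale_time(0.0, 3e-4) == 0.0

    def test_printed_inversion(self):
        # tau = 2 mu t / 30 = 1 at t = 30/(2 mu)
        assert rescale_time(30.0 / (2 * 0.0003), 0.0003) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(t=st.floats(0, 1e8), mu=st.floats(1e-6, 1e-2))
    def test_round_trip(self, t, mu):
        assert unrescale_time(rescale_time(t, mu), mu) == pytest.approx(t, rel=1e-12)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            rescale_time(-1.0, 1e-3)
        with pytest.raises(ValueError):
            rescale_time(1.0, 0.0)


class TestDegradationProfile:
    def test_initial_value(self):
        assert degradation_profile(0.0, 0.01, 1.0) == pytest.approx(0.5)

    def test_monotone_decreasing(self):
        t = np.linspace(0, 1e4, 100)
        y = degradation_profile(t, 1e-3, 1.0)
        assert np.all(np.diff(y) < 0)
        assert y[-1] < 1e-3

    def test_alpha_speeds_decay(self):
        assert degradation_profile(500.0, 2e-3, 1.0) < degradation_profile(
            500.0, 1e-3, 1.0
        )

    def test_profile_object_validates(self):
        with pytest.raises(ValueError):
            DegradationProfile(alpha=0.0, z0=1.0)


class TestSolveExpected:
    def test_fixed_point_at_optimum(self):
        p = ModelParams(**FIG1D)
        traj = solve_expected(p, ExpressionState(0, 0), np.linspace(0, 1e5, 50))
        assert np.allclose(traj.z_m, 0.0)
        assert np.allclose(traj.z_f, 0.0)

    def test_first_point_is_initial_state(self):
        p = ModelParams(**FIG1D)
        traj = solve_expected(p, t_grid=np.linspace(0, 1e5, 50))
        assert traj.z_m[0] == pytest.approx(-1.0)
        assert traj.z_f[0] == pytest.approx(0.0)

    def test_rho_zero_decoupling(self):
        p = ModelParams(system="XY", S_m=0.8, S_f=0.8, rho=0.0, Ne=500.0, mu=3e-4)
        t = np.linspace(0, 2e5, 200)
        traj = solve_expected(p, ExpressionState(-1.0, 0.0), t)
        assert np.allclose(traj.z_f, 0.0, atol=1e-12)
        # exponential at the printed rate: 10 sigma2 Ne S_het per unit tau
        rate = 10.0 * p.sigma2 * p.Ne * p.S_m
        assert np.allclose(traj.z_m, -np.exp(-rate * traj.tau), atol=1e-9)

    def test_closed_form_matches_numeric_fig1d(self):
        p = ModelParams(**FIG1D)
        t = np.linspace(0, 4e5, 800)
        a = solve_expected(p, t_grid=t, method="closed_form")
        b = solve_expected(p, t_grid=t, method="numeric")
        assert np.max(np.abs(a.z_m - b.z_m)) <= 1e-6
        assert np.max(np.abs(a.z_f - b.z_f)) <= 1e-6
        # female overshoot: strictly positive excursion, then back toward 0
        assert a.z_f.max() > 0.1
        assert a.z_f[-1] < a.z_f.max()

    def test_closed_form_rejects_variants(self):
        p = ModelParams(**FIG1D).replace(dominance="dominant")
        with pytest.raises(ValueError):
            solve_expected(p, method="closed_form")

    def test_gradual_reports_y_and_copy_state(self):
        p = ModelParams(**FIG1D).replace(degradation="gradual", alpha=1e-4)
        t = np.linspace(0, 2e5, 200)
        traj = solve_expected(p, t_grid=t, method="numeric")
        assert traj.y is not None
        assert traj.z_m[0] == pytest.approx(-0.5)
        # realized phenotype starts at the optimum
        assert traj.z_het_realized[0] == pytest.approx(0.0)

    def test_global_convergence(self):
        for system in ("XY", "ZW"):
            p = ModelParams(system=system, S_m=0.6, S_f=0.9, rho=0.7,
                            Ne=1125.0, mu=3e-4)
            traj = solve_expected(p, t_grid=np.linspace(0, 3e6, 300))
            assert abs(traj.z_m[-1]) < 1e-6
            assert abs(traj.z_f[-1]) < 1e-6

    def test_trajectory_validation(self):
        p = ModelParams(**FIG1D)
        with pytest.raises(ValueError):
            Trajectory(t=[0, 1], tau=[0], z_m=[0, 0], z_f=[0, 0], params=p)
        with pytest.raises(ValueError):
            Trajectory(t=[1, 0], tau=[1, 0], z_m=[0, 0], z_f=[0, 0], params=p)

    def test_tsv_export(self, tmp_path):
        p = ModelParams(**FIG1D)
        traj = solve_expected(p, t_grid=np.linspace(0, 1e4, 5))
        out = tmp_path / "traj.tsv"
        traj.to_tsv(out)
        data = np.loadtxt(out, skiprows=1)
        assert data.shape == (5, 4)
        assert np.allclose(data[:, 2], traj.z_m)


class TestRecoveryTimes:
    def test_headline_asymmetry(self):
        pX = ModelParams(**FIG1D)
        pZ = pX.replace(system="ZW")
        assert time_to_recover(pX) < time_to_recover(pZ)

    def test_equal_rate_limit(self):
        pX = ModelParams(system="XY", S_m=0.5, S_f=0.5, rho=0.0, Ne=1125.0, mu=3e-4)
        pZ = pX.replace(system="ZW")
        tX, tZ = time_to_recover(pX), time_to_recover(pZ)
        assert tX == pytest.approx(tZ, rel=1e-6)

    def test_overshoot_orderings(self):
        p = ModelParams(**FIG1D)
        t = np.linspace(0, 4e5, 2001)
        base = solve_expected(p, t_grid=t, method="closed_form")
        dom = solve_expected(p.replace(dominance="dominant"), t_grid=t, method="numeric")
        grad = solve_expected(
            p.replace(degradation="gradual", alpha=1e-4), t_grid=t, method="numeric"
        )
        assert base.z_f.max() > 0
        assert dom.z_f.max() <= base.z_f.max()
        assert grad.z_f.max() <= base.z_f.max()


class TestStationaryVariance:
    def test_xy_zw_swap_invariance(self):
        pX = ModelParams(system="XY", S_m=1.0, S_f=0.3, rho=0.5, Ne=300.0)
        pZ = ModelParams(system="ZW", S_m=0.3, S_f=1.0, rho=0.5, Ne=300.0)
        assert stationary_variance(pX) == pytest.approx(stationary_variance(pZ))

    def test_decreasing_in_ne(self):
        vs = [
            stationary_variance(ModelParams(S_m=1.0, S_f=0.5, rho=0.4, Ne=ne))
            for ne in (50.0, 200.0, 800.0, 3200.0)
        ]
        assert np.all(np.diff(vs) < 0)

    def test_lyapunov_residual(self):
        # the returned covariance exactly solves A S + S A^T = Q
        p = ModelParams(S_m=0.9, S_f=0.4, rho=0.6, Ne=250.0)
        S = stationary_covariance(p)
        A = drift_matrix(p)
        q_het, q_hom = 15.0 * p.sigma2, 60.0 * p.sigma2
        Q = np.diag([q_het, q_hom])
        assert np.allclose(A @ S + S @ A.T, Q, rtol=1e-10, atol=1e-12)

    def test_rho_zero_closed_form(self):
        # with rho=0 the heterogametic marginal is scalar OU: 3/(4 Ne S)
        p = ModelParams(S_m=0.7, S_f=0.2, rho=0.0, Ne=420.0)
        assert stationary_variance(p) == pytest.approx(3.0 / (4.0 * 420.0 * 0.7))


def test_default_initial_state_variants():
    inst = default_initial_state(ModelParams(system="ZW", z0=0.8))
    assert (inst.z_m, inst.z_f) == (0.0, -0.8)
    grad = default_initial_state(
        ModelParams(system="XY", z0=0.8, degradation="gradual", alpha=1e-3)
    )
    assert (grad.z_m, grad.z_f) == (-0.4, 0.0)
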