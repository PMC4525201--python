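import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import roots_hermite

from dosagecomp.popgen_core import (
    ExpressionState,
    LinearizationWarning,
    ModelParams,
    MutationEffect,
    drift_matrix,
    expected_change,
    fixation_prob,
    sample_mutation,
    sample_mutations,
)


class TestModelParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(sigma2=0.0)
        with pytest.raises(ValueError):
            ModelParams(rho=1.5)
        with pytest.raises(ValueError):
            ModelParams(system="XX")
        with pytest.raises(ValueError):
            ModelParams(S_m=-0.1)
        with pytest.raises(ValueError):
            ModelParams(N=0)

    def test_heterogametic_sex(self):
        assert ModelParams(system="XY").heterogametic_sex == "m"
        assert ModelParams(system="ZW").heterogametic_sex == "f"

    def test_config_round_trip(self, tmp_path):
        p = ModelParams(system="ZW", S_m=0.7, S_f=0.3, rho=-0.4, N=77,
                        Ne=333.5, dominance="dominant", degradation="gradual",
                        alpha=0.01)
        path = tmp_path / "params.cfg"
        p.to_config(path)
        assert ModelParams.from_config(path) == p

    def test_config_rejects_unknown_key(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("bogus = 1\n")
        with pytest.raises(KeyError):
            ModelParams.from_config(path)


class TestSampleMutation:
    def test_rho_one_collapses_to_one_dimension(self, rng):
        p = ModelParams(rho=1.0)
        for _ in range(20):
            d = sample_mutation(p, rng)
            assert d.delta_m == pytest.approx(d.delta_f, abs=1e-12)

    def test_default_variance_calibration(self, rng):
        # sample variance of 1e6 draws within 3 Monte-Carlo SE of 0.1
        p = ModelParams()
        dm, _ = sample_mutations(p, 10**6, rng)
        se = p.sigma2 * np.sqrt(2.0 / (10**6 - 1))
        assert abs(dm.var(ddof=1) - p.sigma2) < 3 * se

    def test_correlation_recovery(self, rng):
        p = ModelParams(rho=0.5)
        dm, df = sample_mutations(p, 10**6, rng)
        r = np.corrcoef(dm, df)[0, 1]
        # SE of a correlation estimate ~ (1-rho^2)/sqrt(n)
        assert abs(r - 0.5) < 3 * (1 - 0.25) / 1000.0


class TestFixationProb:
    def test_neutral_mutant(self):
        p = ModelParams(N=50, Ne=75.0)
        u = fixation_prob(MutationEffect(0, 0), ExpressionState(-0.7, 0.4), p)
        assert u == pytest.approx(1.0 / 150.0)

    def test_state_at_optimum(self):
        p = ModelParams(N=50, Ne=75.0)
        u = fixation_prob(MutationEffect(0.05, 0.05), ExpressionState(0, 0), p)
        assert u == pytest.approx(1.0 / 150.0)

    def test_beneficial_exceeds_neutral(self):
        p = ModelParams(N=50, Ne=75.0, S_m=1.0, S_f=1.0)
        u = fixation_prob(MutationEffect(0.02, 0.02), ExpressionState(-0.5, -0.5), p)
        assert u > 1.0 / 150.0

    def test_monotone_in_alignment(self):
        # fixation probability increases as -z*delta grows in each sex
        p = ModelParams(N=100, Ne=150.0, S_m=0.8, S_f=0.6)
        state = ExpressionState(-0.4, 0.3)
        us = [
            fixation_prob(MutationEffect(dm, 0.0), state, p)
            for dm in np.linspace(-0.03, 0.03, 7)
        ]
        assert np.all(np.diff(us) > 0)  # z_m<0: larger delta_m helps
        us_f = [
            fixation_prob(MutationEffect(0.0, df), state, p)
            for df in np.linspace(-0.03, 0.03, 7)
        ]
        assert np.all(np.diff(us_f) < 0)  # z_f>0: larger delta_f hurts

    def test_dominant_inflates_homogametic_term(self):
        add = ModelParams(N=50, Ne=75.0, S_f=1.0)
        dom = add.replace(dominance="dominant")
        delta, state = MutationEffect(0.0, 0.01), ExpressionState(0.0, 0.3)
        dev_add = 1.0 / 150.0 - fixation_prob(delta, state, add)
        dev_dom = 1.0 / 150.0 - fixation_prob(delta, state, dom)
        assert dev_dom == pytest.approx(dev_add * 4.0 / 3.0)

    def test_out_of_regime_flagged_and_clamped(self):
        p = ModelParams(N=50, Ne=2000.0, S_m=1.0)
        with pytest.warns(LinearizationWarning):
            u = fixation_prob(MutationEffect(0.5, 0.0), ExpressionState(5.0, 0.0), p)
        assert u == 0.0


class TestExpectedChange:
    def test_optimum_is_fixed_point(self):
        p = ModelParams()
        assert expected_change(ExpressionState(0, 0), p) == (0.0, 0.0)

    def test_decoupled_female_at_rho_zero(self):
        p = ModelParams(rho=0.0)
        dzm, dzf = expected_change(ExpressionState(-1.0, 0.0), p)
        assert dzf == 0.0
        assert dzm > 0  # pulled back toward the optimum

    def test_quadrature_oracle(self):
        # the closed-form drift equals the kernel integral of delta * u
        nodes, weights = roots_hermite(21)
        for system in ("XY", "ZW"):
            for dominance in ("additive", "dominant"):
                p = ModelParams(system=system, S_m=0.9, S_f=0.4, rho=0.6,
                                Ne=500.0, N=1000, dominance=dominance)
                state = ExpressionState(-0.8, 0.25)
                # Gauss-Hermite over the correlated bivariate normal
                sig = np.sqrt(p.sigma2)
                x, y = np.meshgrid(nodes, nodes, indexing="ij")
                w2 = np.outer(weights, weights) / np.pi
                dm = sig * np.sqrt(2.0) * x
                df = sig * np.sqrt(2.0) * (p.rho * x + np.sqrt(1 - p.rho**2) * y)
                # unclamped linearized fixation probability
                p0 = 1.0 / (3.0 * p.N)
                if system == "XY":
                    z_het, z_hom, d_het, d_hom = state.z_m, state.z_f, dm, df
                else:
                    z_het, z_hom, d_het, d_hom = state.z_f, state.z_m, df, dm
                bracket = (2.0 * p.Ne / 3.0) * (
                    p.S_het * z_het * d_het + p.hom_weight * p.S_hom * z_hom * d_hom
                )
                u = p0 * (1.0 - bracket)
                upd_het, upd_hom = d_het, 2.0 * d_hom
                scale = 15.0 * 3.0 * p.N  # (dt/dtau) * mutations per generation
                dz_het = scale * np.sum(w2 * upd_het * u)
                dz_hom = scale * np.sum(w2 * upd_hom * u)
                want = (dz_het, dz_hom) if system == "XY" else (dz_hom, dz_het)
                got = expected_change(state, p)
                assert got[0] == pytest.approx(want[0], rel=1e-4)
                assert got[1] == pytest.approx(want[1], rel=1e-4)


@settings(max_examples=40, deadline=None)
@given(
    S_m=st.floats(0.05, 2.0),
    S_f=st.floats(0.05, 2.0),
    rho=st.floats(-0.95, 0.95),
    z_m=st.floats(-2, 2),
    z_f=st.floats(-2, 2),
)
def test_xy_zw_symmetry(S_m, S_f, rho, z_m, z_f):
    """Swapping system, S_m<->S_f and the state axes mirrors the drift."""
    xy = ModelParams(system="XY", S_m=S_m, S_f=S_f, rho=rho, Ne=400.0)
    zw = ModelParams(system="ZW", S_m=S_f, S_f=S_m, rho=rho, Ne=400.0)
    dm, df = expected_change(ExpressionState(z_m, z_f), xy)
    dm2, df2 = expected_change(ExpressionState(z_f, z_m), zw)
    assert df2 == pytest.approx(dm, rel=1e-12, abs=1e-12)
    assert dm2 == pytest.approx(df, rel=1e-12, abs=1e-12)


@settings(max_examples=40, deadline=None)
@given(
    z_m=st.floats(-1.5, 1.5),
    z_f=st.floats(-1.5, 1.5),
    c=st.floats(0.1, 3.0),
)
def test_expected_change_linear_in_state(z_m, z_f, c):
    p = ModelParams(S_m=0.7, S_f=0.9, rho=0.5, Ne=600.0)
    d1 = expected_change(ExpressionState(z_m, z_f), p)
    d2 = expected_change(ExpressionState(c * z_m, c * z_f), p)
    assert d2[0] == pytest.approx(c * d1[0], rel=1e-9, abs=1e-12)
    assert d2[1] == pytest.approx(c * d1[1], rel=1e-9, abs=1e-12)


def test_drift_matrix_shape_and_sign():
    A = drift_matrix(ModelParams(S_m=1.0, S_f=0.5, rho=0.5, Ne=100.0))
    assert A.shape == (2, 2)
    assert np.all(np.linalg.eigvals(A) > 0)
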