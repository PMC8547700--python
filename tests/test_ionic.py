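"""Unit tests of the ionic right-hand side: closed-form factors, rate
switching and the rest-state fixed point."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epicard import ModelParameters
from epicard.ionic import (
    ModelRegimeError,
    derivatives,
    excitatory_current,
    recovery_current,
    recovery_rate,
    reaction_rates,
    s_u_factor,
    shape_factor,
    transient_outward_current,
    w_rate_and_asymptote,
)

P = ModelParameters()


class TestExcitatoryCurrent:
    @pytest.mark.parametrize("V", [P.B, P.a * P.A + P.B, P.A + P.B])
    def test_cubic_roots(self, V):
        assert excitatory_current(V, P) == pytest.approx(0.0, abs=1e-12)

    def test_threshold_is_minus_60_7(self):
        assert P.excitation_threshold == pytest.approx(-60.7, abs=1e-12)

    def test_inward_between_threshold_and_peak(self):
        V = np.linspace(-60.0, 49.0, 50)
        assert np.all(excitatory_current(V, P) < 0)
        V = np.linspace(-84.9, -61.0, 50)
        assert np.all(excitatory_current(V, P) > 0)


class TestRecoveryCurrent:
    def test_zero_at_rest_or_zero_u(self):
        assert recovery_current(P.B, 0.7, P) == 0.0
        assert recovery_current(-20.0, 0.0, P) == 0.0

    def test_direct_value(self):
        p1 = P.replace(c2=1.0)
        assert recovery_current(-84.0, 1.0, p1) == pytest.approx(1.0)


class TestSuFactor:
    @pytest.mark.parametrize("u,expected", [(0.0, 1.0), (P.u_M, 0.0),
                                            (P.u_M / 2, 0.25)])
    def test_values(self, u, expected):
        assert s_u_factor(u, P) == pytest.approx(expected, abs=1e-15)

    def test_violation_raises_by_default(self):
        with pytest.raises(ModelRegimeError):
            s_u_factor(P.u_M + 0.01, P)

    def test_violation_clamp_option(self):
        assert s_u_factor(P.u_M + 0.01, P, on_violation="clamp") == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, P.u_M))
    def test_bounded_and_decreasing(self, u):
        v = float(s_u_factor(u, P))
        assert 0.0 <= v <= 1.0
        if u > 1e-6:
            assert float(s_u_factor(u - 1e-6, P)) > v


class TestShapeFactor:
    def test_at_theta_u(self):
        # tanh(0) = 0: (gamma0 + gamma1*theta_u)/2 + g0
        assert shape_factor(0.2, P) == pytest.approx(6.1, abs=1e-12)

    def test_at_zero(self):
        expected = 8.0 * 0.5 * (1.0 - np.tanh(-3.0)) + 0.1
        assert shape_factor(0.0, P) == pytest.approx(expected, rel=1e-14)
        assert shape_factor(0.0, P) == pytest.approx(8.0802, abs=5e-5)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 5.0))
    def test_lower_bound_g0(self, u):
        assert float(shape_factor(u, P)) >= P.g0

    def test_limit_is_g0(self):
        assert shape_factor(50.0, P) == pytest.approx(P.g0, abs=1e-12)


class TestTransientOutward:
    @pytest.mark.parametrize("V,u,w", [(-20.0, 0.1, 0.0),
                                       (-20.0, P.u_M, 0.3),
                                       (P.B, 0.1, 0.3)])
    def test_zeros(self, V, u, w):
        assert transient_outward_current(V, u, w, P) == pytest.approx(0.0)


class TestRecoveryRate:
    def test_e1_branch_at_equality(self):
        # s = 0 at rest selects the e1 branch
        assert recovery_rate(P.B, 0.0, False, P) == pytest.approx(P.e10)

    def test_e2_branch(self):
        assert recovery_rate(P.B, 0.5, False, P) == pytest.approx(P.e2)

    def test_upstroke_boost(self):
        expected = float(shape_factor(0.0, P)) * P.e10
        assert recovery_rate(P.B, 0.0, True, P) == pytest.approx(expected)
        assert expected == pytest.approx(0.04767, abs=5e-5)

    def test_rate_never_zero_and_in_allowed_set(self):
        rng = np.random.default_rng(42)
        V = rng.uniform(-90, 50, 500)
        u = rng.uniform(0, P.u_M, 500)
        ups = rng.random(500) > 0.5
        e = np.asarray(recovery_rate(V, u, ups, P))
        assert np.all(e > 0)
        allowed = np.stack([
            np.asarray(shape_factor(u, P)) * P.e10,
            np.full(500, P.e10),
            np.full(500, P.e2),
        ])
        assert np.all(np.min(np.abs(allowed - e), axis=0) < 1e-15)


class TestWRate:
    def test_at_zero(self):
        e_w, d_w = w_rate_and_asymptote(0.0, P)
        assert d_w == pytest.approx(P.dw0)
        assert e_w == pytest.approx(float(shape_factor(0.0, P)) * P.ew0)

    def test_divisor_growth(self):
        _, d_w = w_rate_and_asymptote(P.u_M / 2, P)
        assert d_w == pytest.approx(P.dw0 / 0.25)

    def test_zero_availability_gives_zero_asymptote(self):
        e_w, d_w = w_rate_and_asymptote(P.u_M, P)
        assert np.isinf(d_w)  # asymptote (V-B)/A / d_w is exactly 0


class TestDerivatives:
    def test_rest_is_fixed_point(self):
        dV, du, dw = derivatives(P.resting_state, False, P)
        assert (dV, du, dw) == (0.0, 0.0, 0.0)

    def test_subthreshold_decays(self):
        dV, _, _ = derivatives((P.B + 10.0, 0.0, 0.0), False, P)
        assert dV < 0

    def test_suprathreshold_regenerates(self):
        dV, _, _ = derivatives((-55.0, 0.0, 0.0), False, P)
        assert dV > 0


def test_reaction_rates_match_independent_expressions():
    """The vectorized right-hand side agrees with an independently written
    direct transcription of the model equations on random states."""
    rng = np.random.default_rng(7)
    V = rng.uniform(-90.0, 50.0, 1000)
    u = rng.uniform(0.0, P.u_M * 0.999, 1000)
    w = rng.uniform(0.0, 0.5, 1000)
    ups = rng.random(1000) > 0.5

    import math

    for i in range(1000):
        g = (P.gamma0 + P.gamma1 * u[i]) \
            * (-math.tanh(P.alpha * (u[i] - P.theta_u)) + 1.0) / 2.0 + P.g0
        su = (P.u_M - u[i]) ** 2 / P.u_M ** 2
        i_exc = P.c1 * (V[i] - P.B) * (P.a - (V[i] - P.B) / P.A) \
            * (1.0 - (V[i] - P.B) / P.A)
        i_rec = P.c2 * u[i] * (V[i] - P.B)
        i_to = P.c3 * w[i] * (V[i] - P.B) * su
        dV_ref = -g * P.k * (i_exc + i_rec + i_to)
        s = (V[i] - P.B) / P.A - u[i]
        e1 = g * P.e10 if ups[i] else P.e10
        e = e1 if s >= 0 else P.e2
        du_ref = P.k * e * s
        dw_ref = P.k * g * P.ew0 * ((V[i] - P.B) / P.A - P.dw0 / su * w[i])

        dV, du, dw = reaction_rates(V[i], u[i], w[i], bool(ups[i]), P)
        assert dV == pytest.approx(dV_ref, rel=1e-12, abs=1e-12)
        assert du == pytest.approx(du_ref, rel=1e-12, abs=1e-15)
        assert dw == pytest.approx(dw_ref, rel=1e-12, abs=1e-15)


def test_parameter_invariants_enforced():
    with pytest.raises(ValueError):
        ModelParameters(a=1.5)
    with pytest.raises(ValueError):
        ModelParameters(k=-1.0)
    with pytest.raises(ValueError):
        ModelParameters(D=-0.1)
    ModelParameters(D=0.0)  # D = 0 decouples tissue into cells; allowed
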