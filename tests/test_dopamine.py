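"""Dopamine field geometry, feedback variants and temporal filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dopanet.dopamine import (
    DopamineTrace,
    dopamine_concentration,
    effective_feedback_matrix,
    feedback_independence,
    highpass_compensate,
    lowpass_dopamine,
    make_feedback_variant,
    place_varicosities,
)

from oracles import naive_dopamine_matrix


class TestVaricosities:
    def test_support_and_determinism(self):
        q = place_varicosities(4, 10, seed=3)
        assert q.shape == (4, 10, 3)
        assert np.all((q >= 0) & (q <= 1))
        assert np.array_equal(q, place_varicosities(4, 10, seed=3))

    def test_uniform_mean(self):
        q = place_varicosities(200, 50, seed=1)
        assert np.allclose(q.mean(axis=(0, 1)), 0.5, atol=0.01)

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            place_varicosities(0, 10, seed=0)


class TestEffectiveFeedbackMatrix:
    def test_one_over_e_at_lambda(self):
        # single varicosity at distance lambda: kernel drops to 1/e (~37%)
        lam = 0.1
        spn = np.array([[0.5, 0.5, 0.5]])
        at_zero = effective_feedback_matrix(spn, np.array([[[0.5, 0.5, 0.5]]]), lam)
        at_lam = effective_feedback_matrix(spn, np.array([[[0.5 + lam, 0.5, 0.5]]]), lam)
        assert at_lam[0, 0] / at_zero[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_zero_distance_value(self):
        spn = np.array([[0.2, 0.3, 0.4]])
        D = effective_feedback_matrix(spn, np.array([[[0.2, 0.3, 0.4]]]), 0.1)
        assert D[0, 0] == pytest.approx(10.0)

    def test_additive_over_varicosities(self):
        spn = np.array([[0.5, 0.5, 0.5]])
        q1 = np.array([[[0.1, 0.2, 0.3]]])
        q2 = np.array([[[0.9, 0.8, 0.7]]])
        both = np.array([[[0.1, 0.2, 0.3], [0.9, 0.8, 0.7]]])
        D = effective_feedback_matrix(spn, both, 0.1)
        D1 = effective_feedback_matrix(spn, q1, 0.1)
        D2 = effective_feedback_matrix(spn, q2, 0.1)
        assert D[0, 0] == pytest.approx(D1[0, 0] + D2[0, 0])

    def test_matches_naive_loops(self, rng):
        spn = rng.uniform(size=(5, 3))
        q = rng.uniform(size=(3, 4, 3))
        D = effective_feedback_matrix(spn, q, 0.2)
        assert np.allclose(D, naive_dopamine_matrix(spn.tolist(), q.tolist(), 0.2))
        assert np.all(D > 0)

    def test_monotone_in_distance(self):
        spn = np.array([[0.0, 0.0, 0.0]])
        vals = [
            effective_feedback_matrix(spn, np.array([[[x, 0.0, 0.0]]]), 0.1)[0, 0]
            for x in np.linspace(0.0, 1.0, 11)
        ]
        assert np.all(np.diff(vals) < 0)

    def test_lambda_limits(self, rng):
        spn = rng.uniform(size=(30, 3))
        q = rng.uniform(size=(4, 10, 3))
        D_large = effective_feedback_matrix(spn, q, 1e3)
        # rows converge to a common vector (homogeneous limit)
        assert np.allclose(D_large, D_large.mean(axis=0, keepdims=True), rtol=1e-2)
        D_small = effective_feedback_matrix(spn, q, 1e-4)
        assert np.max(D_small) < 1e-10  # no-feedback limit

    def test_rejects_bad_lambda(self, rng):
        with pytest.raises(ValueError):
            effective_feedback_matrix(rng.uniform(size=(2, 3)), rng.uniform(size=(1, 2, 3)), 0.0)


class TestConcentrationAndVariants:
    def test_linearity_and_onehot(self, rng):
        D = rng.uniform(0.1, 3.0, size=(6, 4))
        assert np.allclose(dopamine_concentration(D, np.zeros(4)), 0.0)
        e2 = np.eye(4)[2]
        assert np.allclose(dopamine_concentration(D, e2), D[:, 2])
        r = rng.normal(size=4)
        manual = [sum(D[j, k] * r[k] for k in range(4)) for j in range(6)]
        assert np.allclose(dopamine_concentration(D, r), manual)

    def test_shuffled_preserves_multiset(self, rng):
        D = rng.uniform(0.1, 3.0, size=(6, 4))
        S = make_feedback_variant(D, "shuffled", seed=0)
        assert sorted(S.ravel()) == pytest.approx(sorted(D.ravel()))
        assert not np.array_equal(S, D)

    def test_homogeneous_rows_identical(self, rng):
        D = rng.uniform(0.1, 3.0, size=(6, 4))
        H = make_feedback_variant(D, "homogeneous")
        assert np.allclose(H, D.mean())

    def test_ideal_is_sign_adjusted_transpose(self, rng):
        D = rng.uniform(0.1, 3.0, size=(6, 4))
        W = rng.normal(size=(4, 6))
        sign = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
        I = make_feedback_variant(D, "ideal", W_str_snr=W, spn_sign=sign)
        assert np.allclose(I, sign[:, None] * W.T)

    def test_none_and_unknown(self, rng):
        D = rng.uniform(size=(3, 2))
        assert np.all(make_feedback_variant(D, "none") == 0)
        with pytest.raises(ValueError):
            make_feedback_variant(D, "banana")


class TestTemporalDynamics:
    def test_instantaneous_mode_passthrough(self, rng):
        trace = DopamineTrace(n_str=4, tau_da=None)
        C = rng.normal(size=4)
        lowpass_dopamine(trace, C, dt=1.0)
        assert np.allclose(trace.a, C)

    def test_constant_input_converges_to_input(self):
        trace = DopamineTrace(n_str=2, tau_da=20.0)
        C = np.array([0.7, -0.3])
        for _ in range(2000):
            lowpass_dopamine(trace, C, dt=1.0)
        assert np.allclose(trace.C_filtered, C, atol=1e-9)

    def test_impulse_decays_by_xi(self):
        trace = DopamineTrace(n_str=1, tau_da=10.0)
        xi = np.exp(-0.1)
        lowpass_dopamine(trace, np.array([1.0]), dt=1.0)
        v1 = trace.C_filtered[0]
        lowpass_dopamine(trace, np.array([0.0]), dt=1.0)
        assert trace.C_filtered[0] == pytest.approx(xi * v1)

    def test_unnormalized_gain(self):
        # literal convolution form: constant input C accumulates to C*dt/(1-xi)
        trace = DopamineTrace(n_str=1, tau_da=10.0, unnormalized=True)
        for _ in range(2000):
            lowpass_dopamine(trace, np.array([1.0]), dt=1.0)
        assert trace.C_filtered[0] == pytest.approx(1.0 / (1 - np.exp(-0.1)), rel=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.floats(2.0, 500.0))
    def test_lowpass_highpass_exact_identity(self, seed, tau_da):
        # the compensation reconstructs the instantaneous signal exactly
        rng = np.random.default_rng(seed)
        trace = DopamineTrace(n_str=3, tau_da=tau_da)
        for _ in range(50):
            C = rng.normal(size=3)
            lowpass_dopamine(trace, C, dt=1.0)
            a = highpass_compensate(trace, dt=1.0)
            assert np.allclose(a, C, atol=1e-9)

    def test_compensation_rejects_xi_one(self):
        trace = DopamineTrace(n_str=1, tau_da=np.inf)
        lowpass_dopamine(trace, np.array([1.0]), dt=1.0)
        with pytest.raises(ValueError):
            highpass_compensate(trace, dt=1.0)


class TestFeedbackIndependence:
    def test_identical_rows_are_degenerate(self):
        D = np.tile([1.0, 2.0, 0.5, 1.5], (10, 1))
        assert feedback_independence(D) == pytest.approx(0.0, abs=1e-12)

    def test_orthonormal_rows_are_perfect(self):
        assert feedback_independence(np.eye(4)) == pytest.approx(1.0)

    def test_large_lambda_near_degenerate(self, rng):
        spn = rng.uniform(size=(30, 3))
        q = rng.uniform(size=(4, 10, 3))
        big = feedback_independence(effective_feedback_matrix(spn, q, 100.0))
        mid = feedback_independence(effective_feedback_matrix(spn, q, 0.1))
        assert big < 0.05
        assert mid > 5 * big

    def test_rejects_zero_matrix(self):
        with pytest.raises(ValueError):
            feedback_independence(np.zeros((3, 2)))
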