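"""Dynamics, connectivity construction, balancing and the readout."""

import numpy as np
import pytest

from dopanet import SimConfig
from dopanet.network import (
    balance_weights,
    init_connectivity,
    loss,
    readout_rates,
    sigmoid_rate,
    snc_error_rates,
    step_membrane,
    step_network,
)

from oracles import phi


class TestSigmoid:
    def test_midpoint_and_examples(self):
        assert sigmoid_rate(2.0, b=2.0) == pytest.approx(0.5)
        assert sigmoid_rate(0.0, b=2.0) == pytest.approx(1 / (1 + np.exp(2)), rel=1e-12)
        assert sigmoid_rate(50.0, b=2.0) == pytest.approx(1.0)
        v = np.linspace(-5, 5, 50)
        r = sigmoid_rate(v, 2.0)
        assert np.all(np.diff(r) > 0) and np.all((r > 0) & (r < 1))


class TestStepMembrane:
    def test_decay_one_step(self):
        assert step_membrane(1.0, 0.0, dt=1.0, tau_m=10.0) == pytest.approx(0.9)

    def test_fixed_point_is_tau_times_input(self):
        V = 0.0
        for _ in range(2000):
            V = step_membrane(V, 0.3, dt=1.0, tau_m=10.0)
        assert V == pytest.approx(3.0, rel=1e-6)

    def test_rest_state_stays(self):
        assert step_membrane(0.0, 0.0, 1.0, 10.0) == 0.0

    def test_rejects_unstable_dt(self):
        with pytest.raises(ValueError):
            step_membrane(1.0, 0.0, dt=10.0, tau_m=10.0)


class TestReadoutAndError:
    def test_zero_weights_give_baseline(self):
        W = np.zeros((3, 5))
        r = readout_rates(W, np.random.default_rng(0).uniform(size=5), b=2.0)
        assert np.allclose(r, 1 / (1 + np.exp(2)))

    def test_matches_dense_loop(self, rng):
        W = rng.normal(size=(3, 6))
        r_str = rng.uniform(size=6)
        r = readout_rates(W, r_str, b=2.0)
        for k in range(3):
            u = sum(W[k, j] * r_str[j] for j in range(6))
            assert r[k] == pytest.approx(phi(u, 2.0), rel=1e-12)

    def test_monotone_in_positive_weight(self, rng):
        W = rng.uniform(0.1, 1.0, size=(2, 4))
        r_str = rng.uniform(0.2, 0.8, size=4)
        r0 = readout_rates(W, r_str)
        W2 = W.copy()
        W2[0, 0] *= 2
        assert readout_rates(W2, r_str)[0] > r0[0]

    def test_loss_examples(self):
        t = np.array([0.1, 0.2, 0.3, 0.4])
        assert loss(t, t) == 0.0
        r = t.copy()
        r[1] += 1.0
        assert loss(r, t) == pytest.approx(0.5)
        assert loss(
            np.array([0.5, 0.5, 0.5, 0.5]), np.array([0.6, 0.4, 0.5, 0.5])
        ) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            loss(np.zeros(3), np.zeros(4))

    def test_snc_error_examples(self):
        t = np.array([0.3, 0.7])
        assert np.allclose(snc_error_rates(t, t), 0.0)
        # saturation kills the sigmoid-derivative factor
        assert np.allclose(snc_error_rates(np.array([0.0, 1.0]), np.array([0.5, 0.2])), 0.0)
        assert snc_error_rates(np.array([0.5]), np.array([0.0]))[0] == pytest.approx(0.125)


class TestBalanceWeights:
    def test_inhibition_scaled_up(self):
        exc, inh = np.array([2.0]), np.array([-1.0])
        b_exc, b_inh = balance_weights([exc, inh])
        assert b_inh[0] == pytest.approx(-2.0)
        assert b_exc[0] == pytest.approx(2.0)

    def test_excitation_scaled_up(self):
        b_exc, b_inh = balance_weights([np.array([1.0, 1.0]), np.array([-3.0])])
        assert np.allclose(b_exc, [1.5, 1.5])
        assert b_inh[0] == pytest.approx(-3.0)

    def test_zero_sum_unchanged(self):
        vecs = [np.array([1.0, -1.0])]
        out = balance_weights(vecs)
        assert np.allclose(out[0], vecs[0])

    def test_single_sign_class_left_alone(self):
        out = balance_weights([np.array([1.0, 2.0])])
        assert np.allclose(out[0], [1.0, 2.0])


class TestInitConnectivity:
    def test_extreme_probabilities(self, tiny_config):
        cfg = tiny_config.replace(
            connection_probabilities={
                "thal_ctx": 0.0,
                "ctx_ctx": 1.0,
                "thal_str": 0.5,
                "ctx_str": 0.5,
                "str_str": 0.5,
                "str_snr": 1.0,
            }
        )
        state = init_connectivity(cfg)
        assert state.projections["thal_ctx"].mask.sum() == 0
        cc = state.projections["ctx_ctx"]
        # full connectivity except the (excluded) autapses
        assert cc.mask.sum() == cfg.n_ctx * (cfg.n_ctx - 1)

    def test_density_matches_probability(self):
        cfg = SimConfig(n_thal=60, n_ctx=80, n_dspn=40, n_ispn=40, seed=11)
        state = init_connectivity(cfg)
        proj = state.projections["ctx_str"]
        n = proj.mask.size
        p = 0.5
        assert abs(proj.density() - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_sign_structure_and_balance(self, desk_config):
        state = init_connectivity(desk_config)
        assert state.check_dale()
        # every neuron's incoming weights sum to ~0 after balancing
        P = state.projections
        inc_ctx = np.hstack([P["thal_ctx"].weights, P["ctx_ctx"].weights])
        inc_str = np.hstack(
            [P["thal_str"].weights, P["ctx_str"].weights, P["str_str"].weights]
        )
        assert np.allclose(inc_ctx.sum(axis=1), 0.0, atol=1e-9)
        assert np.allclose(inc_str.sum(axis=1), 0.0, atol=1e-9)
        assert np.allclose(P["str_snr"].weights.sum(axis=1), 0.0, atol=1e-9)
        assert np.all((state.spn_positions >= 0) & (state.spn_positions <= 1))

    def test_reproducible(self, desk_config):
        a = init_connectivity(desk_config)
        b = init_connectivity(desk_config)
        for name in a.projections:
            assert np.array_equal(a.projections[name].weights, b.projections[name].weights)
        assert np.array_equal(a.spn_positions, b.spn_positions)

    def test_rejects_bad_probability(self, tiny_config):
        probs = dict(tiny_config.connection_probabilities)
        probs["ctx_str"] = 1.5
        with pytest.raises(ValueError):
            tiny_config.replace(connection_probabilities=probs)


class TestStepNetwork:
    def test_zero_weights_decay_to_baseline(self, tiny_config):
        cfg = tiny_config.replace(
            w_max={k: 0.0 for k in tiny_config.w_max}
        )
        state = init_connectivity(cfg)
        state.V["ctx"][:] = 1.0
        state.V["str"][:] = -1.0
        thal_t = np.full(cfg.n_thal, 0.4)
        for _ in range(300):
            step_network(state, thal_t, cfg)
        assert np.allclose(state.V["ctx"], 0.0, atol=1e-9)
        assert np.allclose(state.r["str"], 1 / (1 + np.exp(2)), atol=1e-9)

    def test_matches_scalar_loop_oracle(self, tiny_config):
        from oracles import NaiveNetwork

        state = init_connectivity(tiny_config)
        W = {k: p.weights.copy() for k, p in state.projections.items()}
        masks = {k: state.projections[k].mask for k in ("thal_str", "ctx_str", "str_str", "str_snr")}
        oracle = NaiveNetwork(
            tiny_config,
            W,
            masks,
            state.spn_sign,
            np.zeros(tiny_config.n_str),  # no plasticity here: dynamics only
            np.zeros((tiny_config.n_str, tiny_config.d)),
            tiny_config.n_ctx_exc,
        )
        oracle.cfg = tiny_config.replace(beta=0.0)
        rng = np.random.default_rng(1)
        thal_t = rng.uniform(0.05, 0.9, size=tiny_config.n_thal)
        target = rng.uniform(0.3, 0.7, size=tiny_config.d)
        for _ in range(10):
            step_network(state, thal_t, tiny_config)
            oracle.step(list(thal_t), list(target))
        assert np.allclose(state.V["ctx"], oracle.V_ctx, atol=1e-12)
        assert np.allclose(state.V["str"], oracle.V_str, atol=1e-12)

    def test_nonfinite_aborts(self, tiny_config):
        state = init_connectivity(tiny_config)
        state.V["ctx"][0] = np.inf
        with pytest.raises(FloatingPointError):
            step_network(state, np.full(tiny_config.n_thal, 0.4), tiny_config)


class TestLongRunStability:
    def test_bounded_trajectories_long_run(self):
        """Pre-training dynamics stay finite with rates inside (0,1) over 1e5 steps."""
        from dopanet import BasalGangliaModel

        cfg = SimConfig.desk(n_trials=500, seed=17, feedback_variant="none", beta=0.0)
        res = BasalGangliaModel(cfg).fit()  # 500 trials x 200 steps = 1e5 steps
        assert res.converged
        assert np.all(np.isfinite(res.state.V["ctx"]))
        assert np.all(np.isfinite(res.state.V["str"]))
        r = res.rates_recorded
        assert np.all((r >= 0.0) & (r <= 1.0))
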