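"""Population dynamics, sign-constrained connectivity, readout and error.

The model is a rate network of five populations.  Thalamic rates are imposed
(the sinusoidal clock); cortex and striatum integrate a leaky membrane
potential,

    tau_m dV/dt = -V + sum_Pre sum_pre w^{PrePost} r^{Pre},

with firing rate r = phi(V) = 1 / (1 + exp(-V + b)); the readout population
(SNr/GPi) is memoryless, r_k = phi(sum_j w_kj r_j^Str); and the dopaminergic
population (SNc) carries the d-dimensional output error

    eps_k = (r_k^SNr - T_k) r_k^SNr (1 - r_k^SNr).

Every projection is sign-homogeneous per presynaptic cell (Dale's law) and all
but the readout are sparse.  After construction, each neuron's incoming
excitation and inhibition are balanced to sum exactly to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .config import SimConfig

__all__ = [
    "sigmoid_rate",
    "step_membrane",
    "readout_rates",
    "loss",
    "snc_error_rates",
    "SignedProjection",
    "NetworkState",
    "balance_weights",
    "init_connectivity",
    "step_network",
]


def sigmoid_rate(V, b: float = 2.0):
    """Logistic transfer function ``phi(V) = 1 / (1 + exp(-V + b))``.

    The rightward shift ``b`` keeps rates sparse when inputs are balanced and
    membrane potentials fluctuate around zero.
    """
    return 1.0 / (1.0 + np.exp(-np.asarray(V, dtype=float) + b))


def step_membrane(V, input_current, dt: float, tau_m: float):
    """One forward-Euler step of the leaky membrane equation.

    ``V <- V + dt * (-V / tau_m + input_current)``.  With zero input the
    potential decays geometrically by ``(1 - dt/tau_m)`` per step; with
    constant input ``I`` it converges to ``tau_m * I``.
    """
    if dt >= tau_m:
        raise ValueError(f"dt={dt} >= tau_m={tau_m}: forward-Euler unstable")
    V = np.asarray(V, dtype=float)
    return V + dt * (-V / tau_m + np.asarray(input_current, dtype=float))


def readout_rates(W_str_snr: np.ndarray, r_str: np.ndarray, b: float = 2.0) -> np.ndarray:
    """Memoryless readout rates, ``r_k = phi(sum_j w_kj r_j)``."""
    W = np.asarray(W_str_snr, dtype=float)
    r = np.asarray(r_str, dtype=float)
    if W.shape[1] != r.shape[0]:
        raise ValueError(f"shape mismatch: W {W.shape} vs r_str {r.shape}")
    return sigmoid_rate(W @ r, b)


def loss(r_snr: np.ndarray, target: np.ndarray) -> float:
    """Instantaneous squared output error, ``0.5 * sum_k (r_k - T_k)^2``."""
    r = np.asarray(r_snr, dtype=float)
    T = np.asarray(target, dtype=float)
    if r.shape != T.shape:
        raise ValueError("readout and target must have the same length")
    return 0.5 * float(np.sum((r - T) ** 2))


def snc_error_rates(r_snr: np.ndarray, target: np.ndarray) -> np.ndarray:
    """SNc rates encoding the error, ``eps_k = (r_k - T_k) r_k (1 - r_k)``.

    Negative values are read as deviations below a baseline firing rate.
    """
    r = np.asarray(r_snr, dtype=float)
    T = np.asarray(target, dtype=float)
    return (r - T) * r * (1.0 - r)


@dataclass
class SignedProjection:
    """A sparse, sign-constrained weight matrix between two populations.

    ``sign`` is either a scalar (+1/-1, sign-homogeneous projection) or a
    vector over presynaptic cells (mixed populations such as cortex, or the
    striatal readout where dSPNs are inhibitory and iSPNs excitatory).
    Weights are zero wherever ``mask`` is False and match the declared sign
    at every existing synapse, at all times during learning.
    """

    source: str
    target: str
    mask: np.ndarray  # bool [n_post, n_pre]
    weights: np.ndarray  # float [n_post, n_pre]
    sign: np.ndarray  # scalar or [n_pre] of +-1
    plastic: bool = False

    @property
    def sign_per_pre(self) -> np.ndarray:
        s = np.asarray(self.sign, dtype=float)
        if s.ndim == 0:
            return np.full(self.weights.shape[1], float(s))
        return s

    def check_signs(self, atol: float = 0.0) -> bool:
        """True iff masked weights conform to the projection sign and the
        unmasked entries are exactly zero."""
        w = self.weights
        s = self.sign_per_pre[None, :]
        if np.any(w[~self.mask] != 0.0):
            return False
        return bool(np.all(w * s >= -atol))

    def density(self) -> float:
        return float(self.mask.mean())


@dataclass
class NetworkState:
    """Membrane potentials, rates, connectivity and SPN positions."""

    config: SimConfig
    V: Dict[str, np.ndarray]
    r: Dict[str, np.ndarray]
    projections: Dict[str, SignedProjection]
    spn_positions: np.ndarray  # [n_str, 3] in the unit cube
    is_dspn: np.ndarray  # bool [n_str]; first n_dspn are direct-pathway
    ctx_sign: np.ndarray  # [n_ctx] of +-1 (excitatory / inhibitory subpopulation)
    unbalanced_neurons: list = field(default_factory=list)

    @property
    def spn_sign(self) -> np.ndarray:
        """Readout sign per SPN: -1 for dSPN (inhibitory), +1 for iSPN."""
        return np.where(self.is_dspn, -1.0, 1.0)

    @property
    def alpha_per_spn(self) -> np.ndarray:
        """Class-signed striatal learning rates (-alpha for dSPN, +alpha for iSPN)."""
        a = self.config.alpha
        return np.where(self.is_dspn, -a, a)

    def check_dale(self) -> bool:
        return all(p.check_signs() for p in self.projections.values())


def balance_weights(incoming: list) -> list:
    """Scale one neuron's incoming weights so they sum exactly to zero.

    ``incoming`` is a list of signed weight vectors (one per afferent
    projection).  If the total sum is positive, inhibitory weights are scaled
    up uniformly; if negative, excitatory weights are scaled up.  Signs are
    preserved.  A neuron with only one sign class cannot be balanced and is
    returned unchanged (the caller logs it).
    """
    vecs = [np.asarray(v, dtype=float).copy() for v in incoming]
    total = sum(float(v.sum()) for v in vecs)
    pos = sum(float(v[v > 0].sum()) for v in vecs)
    neg = sum(float(v[v < 0].sum()) for v in vecs)
    if total == 0.0:
        return vecs
    if pos == 0.0 or neg == 0.0:
        return vecs  # unbalanceable; caller records it
    if total > 0:
        scale = -pos / neg  # > 1: inhibition scaled up
        for v in vecs:
            v[v < 0] *= scale
    else:
        scale = -neg / pos
        for v in vecs:
            v[v > 0] *= scale
    return vecs


def _draw_projection(
    rng: np.random.Generator,
    name: str,
    source: str,
    target: str,
    n_post: int,
    n_pre: int,
    p: float,
    w_max: float,
    sign,
    plastic: bool,
) -> SignedProjection:
    mask = rng.random((n_post, n_pre)) < p
    w = rng.uniform(0.0, w_max / n_post, size=(n_post, n_pre))
    w *= mask
    s = np.asarray(sign, dtype=float)
    w *= s if s.ndim else float(s)
    return SignedProjection(
        source=source, target=target, mask=mask, weights=w, sign=s, plastic=plastic
    )


def _balance_population(projections: list, pop: str, n_post: int, log: list) -> None:
    rows_per_proj = [p.weights for p in projections]
    for i in range(n_post):
        rows = [w[i] for w in rows_per_proj]
        total = sum(float(r.sum()) for r in rows)
        pos = sum(float(r[r > 0].sum()) for r in rows)
        neg = sum(float(r[r < 0].sum()) for r in rows)
        if total == 0.0:
            continue
        if pos == 0.0 or neg == 0.0:
            log.append((pop, i))
            continue
        balanced = balance_weights(rows)
        for w, b_row in zip(rows_per_proj, balanced):
            w[i] = b_row


def init_connectivity(config: SimConfig, seed: Optional[int] = None) -> NetworkState:
    """Construct the full network: masks, signed weights, positions, balancing.

    Synapse existence is an independent Bernoulli(p) per ordered cell pair;
    existing weights are Uniform[0, w_max / n_post] times the projection sign.
    SPN positions are uniform in the unit cube.  After construction every
    neuron's incoming excitation/inhibition is balanced to sum to zero.
    """
    seeds = config.stage_seeds()
    rng = np.random.default_rng(seeds["connectivity"] if seed is None else seed)
    pos_rng = np.random.default_rng(seeds["positions"] if seed is None else seed + 1)

    n_ce, n_ci = config.n_ctx_exc, config.n_ctx_inh
    ctx_sign = np.concatenate([np.ones(n_ce), -np.ones(n_ci)])
    is_dspn = np.zeros(config.n_str, dtype=bool)
    is_dspn[: config.n_dspn] = True
    spn_sign = np.where(is_dspn, -1.0, 1.0)

    p = config.connection_probabilities
    wm = config.w_max
    projections = {
        "thal_ctx": _draw_projection(
            rng, "thal_ctx", "thal", "ctx", config.n_ctx, config.n_thal,
            p["thal_ctx"], wm["thal_ctx"], +1.0, plastic=False,
        ),
        "ctx_ctx": _draw_projection(
            rng, "ctx_ctx", "ctx", "ctx", config.n_ctx, config.n_ctx,
            p["ctx_ctx"], wm["ctx_ctx"], ctx_sign, plastic=False,
        ),
        "thal_str": _draw_projection(
            rng, "thal_str", "thal", "str", config.n_str, config.n_thal,
            p["thal_str"], wm["thal_str"], +1.0, plastic=True,
        ),
        # only excitatory cortical cells project out of cortex
        "ctx_str": _draw_projection(
            rng, "ctx_str", "ctx", "str", config.n_str, n_ce,
            p["ctx_str"], wm["ctx_str"], +1.0, plastic=True,
        ),
        "str_str": _draw_projection(
            rng, "str_str", "str", "str", config.n_str, config.n_str,
            p["str_str"], wm["str_str"], -1.0, plastic=True,
        ),
        "str_snr": _draw_projection(
            rng, "str_snr", "str", "snr", config.n_snr, config.n_str,
            p["str_snr"], wm["str_snr"], spn_sign, plastic=True,
        ),
    }
    # no autapses in recurrent projections
    np.fill_diagonal(projections["ctx_ctx"].mask, False)
    np.fill_diagonal(projections["ctx_ctx"].weights, 0.0)
    np.fill_diagonal(projections["str_str"].mask, False)
    np.fill_diagonal(projections["str_str"].weights, 0.0)

    log: list = []
    _balance_population(
        [projections["thal_ctx"], projections["ctx_ctx"]], "ctx", config.n_ctx, log
    )
    _balance_population(
        [projections["thal_str"], projections["ctx_str"], projections["str_str"]],
        "str", config.n_str, log,
    )
    _balance_population([projections["str_snr"]], "snr", config.n_snr, log)

    spn_positions = pos_rng.uniform(0.0, 1.0, size=(config.n_str, 3))

    V = {"ctx": np.zeros(config.n_ctx), "str": np.zeros(config.n_str)}
    r = {
        "thal": np.full(config.n_thal, sigmoid_rate(0.0, config.b)),
        "ctx": sigmoid_rate(V["ctx"], config.b),
        "str": sigmoid_rate(V["str"], config.b),
        "snr": readout_rates(projections["str_snr"].weights, sigmoid_rate(V["str"], config.b), config.b),
    }
    return NetworkState(
        config=config,
        V=V,
        r=r,
        projections=projections,
        spn_positions=spn_positions,
        is_dspn=is_dspn,
        ctx_sign=ctx_sign,
        unbalanced_neurons=log,
    )


def step_network(state: NetworkState, thal_rates_t: np.ndarray, config: SimConfig) -> None:
    """One synchronous simulation step of the dynamics (no plasticity), in place.

    Order: (1) rates from the current membrane potentials (thalamic rates
    imposed), (2) readout, (3) forward-Euler membrane update driven by the
    rates computed in (1).  Rates from the previous step feed all membrane
    updates — a synchronous update.
    """
    P = state.projections
    b, dt, tau_m = config.b, config.dt_ms, config.tau_m_ms

    r_thal = np.asarray(thal_rates_t, dtype=float)
    r_ctx = sigmoid_rate(state.V["ctx"], b)
    r_str = sigmoid_rate(state.V["str"], b)
    r_snr = readout_rates(P["str_snr"].weights, r_str, b)

    I_ctx = P["thal_ctx"].weights @ r_thal + P["ctx_ctx"].weights @ r_ctx
    I_str = (
        P["thal_str"].weights @ r_thal
        + P["ctx_str"].weights @ r_ctx[: config.n_ctx_exc]
        + P["str_str"].weights @ r_str
    )
    V_ctx = step_membrane(state.V["ctx"], I_ctx, dt, tau_m)
    V_str = step_membrane(state.V["str"], I_str, dt, tau_m)

    for name, arr in (("ctx", V_ctx), ("str", V_str)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite membrane potential in {name}")

    state.V["ctx"], state.V["str"] = V_ctx, V_str
    state.r.update(thal=r_thal, ctx=r_ctx, str=r_str, snr=r_snr)
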