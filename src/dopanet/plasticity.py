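"""Three-factor RFLO plasticity and the striatofugal delta rule.

Striatal afferent and recurrent synapses carry an eligibility trace

    tau_str dp_ji/dt = -p_ji + r_j^Str (1 - r_j^Str) r_i^pre,

a low-pass-filtered Hebbian product of pre- and postsynaptic activity.  The
weight change is the eligibility gated by the local dopamine concentration
(the "third factor"):

    dw_ji/dt = -alpha_j p_ji C_j(t),

with alpha_j = -2.5e-2 for direct-pathway (D1) and +2.5e-2 for
indirect-pathway (D2) neurons.  The striatofugal (readout) weights follow the
delta rule dw_kj/dt = -beta eps_k r_j^Str, which is the exact negative
gradient of the instantaneous loss.  All weights are clamped so their signs
match the projection sign throughout learning (Dale's law); a clamped synapse
keeps its mask entry and may regrow.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "update_eligibility",
    "striatal_weight_update",
    "striatofugal_update",
    "apply_sign_constraints",
    "feedforward_gradient_check",
]


def update_eligibility(
    p: np.ndarray,
    r_str: np.ndarray,
    r_pre: np.ndarray,
    dt: float,
    tau_str: float,
    mask: np.ndarray = None,
) -> np.ndarray:
    """One Euler step of the eligibility trace (outer-product drive).

    ``p <- p + (dt / tau_str) * (-p + r_j (1 - r_j) r_i)``.  The fixed point
    for constant rates is ``r_j (1 - r_j) r_i``.
    """
    if tau_str <= 0:
        raise ValueError("tau_str must be > 0")
    r_str = np.asarray(r_str, dtype=float)
    r_pre = np.asarray(r_pre, dtype=float)
    drive = np.outer(r_str * (1.0 - r_str), r_pre)
    if mask is not None:
        drive = drive * mask
    return p + (dt / tau_str) * (-p + drive)


def apply_sign_constraints(W: np.ndarray, sign, mask: np.ndarray = None) -> np.ndarray:
    """Clamp weights that crossed zero back to zero.

    Excitatory weights are floored at 0 from below, inhibitory capped at 0
    from above.  ``sign`` is scalar or per-presynaptic-column.  The mask is
    unchanged; a clamped synapse may regrow later.
    """
    s = np.asarray(sign, dtype=float)
    if s.ndim == 0:
        s = np.full(W.shape[1], float(s))
    W = np.where(W * s[None, :] < 0, 0.0, W)
    if mask is not None:
        W = W * mask
    return W


def striatal_weight_update(
    W: np.ndarray,
    mask: np.ndarray,
    sign,
    p: np.ndarray,
    dopamine_per_spn: np.ndarray,
    alpha_per_spn: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Three-factor update ``dw_ji = -alpha_j p_ji C_j dt`` on masked synapses.

    ``dopamine_per_spn`` is the variant-dependent per-SPN feedback (the
    heterogeneous ``sum_k eps_k d_jk`` or its shuffled / homogeneous / ideal /
    temporally filtered counterpart).  The same rule serves corticostriatal,
    thalamostriatal and striatostriatal synapses.
    """
    dw = -np.asarray(alpha_per_spn)[:, None] * p * np.asarray(dopamine_per_spn)[:, None] * dt
    if not np.all(np.isfinite(dw)):
        raise FloatingPointError("non-finite striatal weight update")
    if dw.shape != W.shape:
        raise ValueError(f"shape mismatch: W {W.shape} vs update {dw.shape}")
    W_new = W + dw * mask
    return apply_sign_constraints(W_new, sign, mask)


def striatofugal_update(
    W_str_snr: np.ndarray,
    mask: np.ndarray,
    spn_sign: np.ndarray,
    epsilon: np.ndarray,
    r_str: np.ndarray,
    beta: float,
    dt: float,
) -> np.ndarray:
    """Delta-rule update of the readout weights, ``dw_kj = -beta eps_k r_j dt``.

    Equal (up to the rate ``beta``) to the exact negative gradient of the
    instantaneous loss with respect to the readout weights.
    """
    eps = np.asarray(epsilon, dtype=float)
    r = np.asarray(r_str, dtype=float)
    dw = -beta * np.outer(eps, r) * dt
    if dw.shape != W_str_snr.shape:
        raise ValueError(f"shape mismatch: W {W_str_snr.shape} vs update {dw.shape}")
    W_new = W_str_snr + dw * mask
    return apply_sign_constraints(W_new, spn_sign, mask)


def feedforward_gradient_check(
    n_in: int = 2,
    n_spn: int = 3,
    d: int = 2,
    tau_m: float = 10.0,
    b: float = 2.0,
    seed: int = 0,
    h: float = 1e-6,
) -> float:
    """Max relative error of the three-factor rule against finite differences.

    In the no-recurrence, fast-eligibility limit the striatum is a static
    feedforward map ``r_j = phi(tau_m sum_i w_ji r_i)``; with ideal feedback
    (gamma_j = sum_k eps_k w_kj) and the eligibility at its fixed point
    ``p*_ji = r_j (1 - r_j) r_i``, the rule's drive ``tau_m gamma_j p*_ji``
    equals the true gradient of the loss with respect to each input weight.
    Signs are left unconstrained here; returns the maximum relative error over
    all input weights.
    """
    rng = np.random.default_rng(seed)
    r_in = rng.uniform(0.1, 0.9, size=n_in)
    W_in = rng.normal(0.0, 0.3, size=(n_spn, n_in))
    W_out = rng.normal(0.0, 1.0, size=(d, n_spn))
    target = rng.uniform(0.2, 0.8, size=d)

    def forward_loss(W):
        r_str = 1.0 / (1.0 + np.exp(-(tau_m * (W @ r_in)) + b))
        r_out = 1.0 / (1.0 + np.exp(-(W_out @ r_str) + b))
        return 0.5 * np.sum((r_out - target) ** 2)

    # analytic drive of the three-factor rule in this limit
    r_str = 1.0 / (1.0 + np.exp(-(tau_m * (W_in @ r_in)) + b))
    r_out = 1.0 / (1.0 + np.exp(-(W_out @ r_str) + b))
    eps = (r_out - target) * r_out * (1.0 - r_out)
    gamma = W_out.T @ eps
    p_star = np.outer(r_str * (1.0 - r_str), r_in)
    analytic = tau_m * gamma[:, None] * p_star

    max_rel = 0.0
    for j in range(n_spn):
        for i in range(n_in):
            Wp, Wm = W_in.copy(), W_in.copy()
            Wp[j, i] += h
            Wm[j, i] -= h
            fd = (forward_loss(Wp) - forward_loss(Wm)) / (2.0 * h)
            denom = max(abs(fd), abs(analytic[j, i]), 1e-12)
            max_rel = max(max_rel, abs(fd - analytic[j, i]) / denom)
    return max_rel
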