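"""Jitted training loop.

One call simulates a whole run: ``n_trials`` consecutive presentations of the
target with no state reset in between, with online plasticity applied every
time step.  Per-step order (fixed convention, mirrored by the plain-numpy
reference path used in the tests):

1. rates from the current membrane potentials (thalamic clock imposed),
2. readout rates, loss and the SNc error vector,
3. per-SPN dopamine feedback (variant-dependent, optionally low-pass
   filtered and high-pass compensated),
4. eligibility and weight updates with sign clamping,
5. forward-Euler membrane update driven by the rates from step 1.

Returns -1 on success or the trial index at which the state became
non-finite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def run_trials_core(
    n_trials,
    n_steps,
    dt,
    tau_m,
    tau_str,
    b,
    thal,  # [n_steps, n_thal] precomputed clock rates
    targets,  # [d, n_steps]
    V_ctx,
    V_str,
    W_tc,
    W_cc,
    W_ts,
    W_cs,
    W_ss,
    W_sn,
    M_ts,
    M_cs,
    M_ss,
    M_sn,
    n_ce,  # number of excitatory cortical cells (they alone project to striatum)
    spn_sign,  # [n_str]: -1 dSPN, +1 iSPN (readout column sign)
    alpha_str,  # [n_str] class-signed striatal learning rates
    beta,
    D_eff,  # [n_str, d] effective feedback (static variants)
    ideal_mode,  # recompute feedback from the readout weights every step
    striatal_on,  # feedback variant is not "none"
    ts_plastic,
    cs_plastic,
    ss_plastic,
    sn_plastic,
    tau_da,  # <= 0 -> instantaneous dopamine
    compensate,
    unnormalized,
    p_ts,
    p_cs,
    p_ss,
    C_filt,
    C_filt_prev,
    losses,  # out [n_trials]
    rec_from,  # record SPN rates for trials >= rec_from
    rates_rec,  # out [n_str, (n_trials - rec_from) * n_steps]
    snr_first,  # out [d, n_steps]
    snr_last,  # out [d, n_steps]
    snap_every,
    W_sn_snaps,  # out [n_snaps, d, n_str]
):
    n_ctx = V_ctx.shape[0]
    n_str = V_str.shape[0]
    n_thal = thal.shape[1]
    d = targets.shape[0]

    r_ctx = np.empty(n_ctx)
    r_str = np.empty(n_str)
    r_snr = np.empty(d)
    eps = np.empty(d)
    C = np.empty(n_str)
    a = np.empty(n_str)

    kfac = dt / tau_str
    slow = tau_da > 0.0
    xi = np.exp(-dt / tau_da) if slow else 0.0
    gain = dt if unnormalized else (1.0 - xi)

    any_striatal = striatal_on and (ts_plastic or cs_plastic or ss_plastic)

    for trial in range(n_trials):
        if snap_every > 0 and trial % snap_every == 0:
            idx = trial // snap_every
            for k in range(d):
                for j in range(n_str):
                    W_sn_snaps[idx, k, j] = W_sn[k, j]

        loss_acc = 0.0
        for t in range(n_steps):
            # (1) rates from current membrane potentials
            for i in range(n_ctx):
                r_ctx[i] = 1.0 / (1.0 + np.exp(-V_ctx[i] + b))
            for j in range(n_str):
                r_str[j] = 1.0 / (1.0 + np.exp(-V_str[j] + b))

            # (2) readout, loss, SNc error
            for k in range(d):
                u = 0.0
                for j in range(n_str):
                    u += W_sn[k, j] * r_str[j]
                rk = 1.0 / (1.0 + np.exp(-u + b))
                r_snr[k] = rk
                e = rk - targets[k, t]
                loss_acc += 0.5 * e * e * dt
                eps[k] = e * rk * (1.0 - rk)

            if trial == 0:
                for k in range(d):
                    snr_first[k, t] = r_snr[k]
            if trial == n_trials - 1:
                for k in range(d):
                    snr_last[k, t] = r_snr[k]

            # (3) per-SPN dopamine feedback
            if any_striatal:
                if ideal_mode:
                    for j in range(n_str):
                        acc = 0.0
                        for k in range(d):
                            acc += W_sn[k, j] * eps[k]
                        C[j] = spn_sign[j] * acc
                else:
                    for j in range(n_str):
                        acc = 0.0
                        for k in range(d):
                            acc += D_eff[j, k] * eps[k]
                        C[j] = acc
                if slow:
                    for j in range(n_str):
                        C_filt_prev[j] = C_filt[j]
                        C_filt[j] = xi * C_filt[j] + gain * C[j]
                        if compensate:
                            a[j] = (C_filt[j] - xi * C_filt_prev[j]) / (1.0 - xi)
                        else:
                            a[j] = C_filt[j]
                else:
                    for j in range(n_str):
                        a[j] = C[j]

                # (4a) striatal eligibility + three-factor weight updates
                for j in range(n_str):
                    drv = r_str[j] * (1.0 - r_str[j])
                    ga = -alpha_str[j] * a[j] * dt
                    if ts_plastic:
                        for m in range(n_thal):
                            if M_ts[j, m]:
                                p_ts[j, m] += kfac * (-p_ts[j, m] + drv * thal[t, m])
                                w = W_ts[j, m] + ga * p_ts[j, m]
                                W_ts[j, m] = w if w > 0.0 else 0.0  # excitatory
                    if cs_plastic:
                        for i in range(n_ce):
                            if M_cs[j, i]:
                                p_cs[j, i] += kfac * (-p_cs[j, i] + drv * r_ctx[i])
                                w = W_cs[j, i] + ga * p_cs[j, i]
                                W_cs[j, i] = w if w > 0.0 else 0.0  # excitatory
                    if ss_plastic:
                        for i in range(n_str):
                            if M_ss[j, i]:
                                p_ss[j, i] += kfac * (-p_ss[j, i] + drv * r_str[i])
                                w = W_ss[j, i] + ga * p_ss[j, i]
                                W_ss[j, i] = w if w < 0.0 else 0.0  # inhibitory

            # (4b) striatofugal delta rule
            if sn_plastic:
                for k in range(d):
                    gb = -beta * eps[k] * dt
                    for j in range(n_str):
                        if M_sn[k, j]:
                            w = W_sn[k, j] + gb * r_str[j]
                            if spn_sign[j] > 0.0:
                                W_sn[k, j] = w if w > 0.0 else 0.0
                            else:
                                W_sn[k, j] = w if w < 0.0 else 0.0

            # (5) forward-Euler membrane update (synchronous: uses step-1 rates)
            for i in range(n_ctx):
                I = 0.0
                for m in range(n_thal):
                    I += W_tc[i, m] * thal[t, m]
                for i2 in range(n_ctx):
                    I += W_cc[i, i2] * r_ctx[i2]
                V_ctx[i] += dt * (-V_ctx[i] / tau_m + I)
            for j in range(n_str):
                I = 0.0
                for m in range(n_thal):
                    I += W_ts[j, m] * thal[t, m]
                for i in range(n_ce):
                    I += W_cs[j, i] * r_ctx[i]
                for j2 in range(n_str):
                    I += W_ss[j, j2] * r_str[j2]
                V_str[j] += dt * (-V_str[j] / tau_m + I)

            if trial >= rec_from:
                col = (trial - rec_from) * n_steps + t
                for j in range(n_str):
                    rates_rec[j, col] = r_str[j]

        losses[trial] = loss_acc
        if not np.isfinite(loss_acc):
            return trial
        ok = True
        for i in range(n_ctx):
            if not np.isfinite(V_ctx[i]):
                ok = False
        for j in range(n_str):
            if not np.isfinite(V_str[j]):
                ok = False
        if not ok:
            return trial
    return -1
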