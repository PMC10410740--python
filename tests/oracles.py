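"""Naive, structurally independent oracle implementations for the tests.

Everything here is written as plain-Python scalar loops over explicit small
data structures, deliberately avoiding the vectorized / jitted code paths of
the package, so agreement between the two is informative.
"""

from __future__ import annotations

import math

import numpy as np


def phi(v: float, b: float) -> float:
    return 1.0 / (1.0 + math.exp(-v + b))


def naive_periodic_covariance(times, tau, T):
    n = len(times)
    K = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            diff = times[i] - times[j]
            delta = min(abs(diff), abs(diff + T), abs(diff - T))
            K[i][j] = 0.15**2 * math.exp(-(delta**2) / (2.0 * tau**2))
    return np.array(K)


def naive_dopamine_matrix(spn_pos, var_pos, lam):
    """D[j][k] by explicit loops (var_pos is [n_snc][n_var][3])."""
    n_str = len(spn_pos)
    n_snc = len(var_pos)
    D = [[0.0] * n_snc for _ in range(n_str)]
    for j in range(n_str):
        for k in range(n_snc):
            for v in range(len(var_pos[k])):
                dist = math.sqrt(
                    sum((spn_pos[j][c] - var_pos[k][v][c]) ** 2 for c in range(3))
                )
                D[j][k] += math.exp(-dist / lam) / lam
    return np.array(D)


def central_difference(f, x0: float, h: float = 1e-6) -> float:
    return (f(x0 + h) - f(x0 - h)) / (2.0 * h)


class NaiveNetwork:
    """Scalar-loop simulator of the full per-step update, including plasticity.

    Mirrors the documented step order: rates from current V -> readout/error ->
    dopamine feedback -> eligibility + weight updates with sign clamping ->
    membrane Euler update using the step's rates and the *updated* weights.
    """

    def __init__(self, cfg, W, masks, spn_sign, alpha_str, D_eff, n_ce):
        self.cfg = cfg
        self.W = {k: [row[:] for row in np.asarray(v).tolist()] for k, v in W.items()}
        self.M = {k: np.asarray(v).tolist() for k, v in masks.items()}
        self.spn_sign = list(np.asarray(spn_sign))
        self.alpha = list(np.asarray(alpha_str))
        self.D = np.asarray(D_eff).tolist()
        self.n_ce = n_ce
        n_ctx = len(self.W["ctx_ctx"])
        n_str = len(self.W["str_str"])
        self.V_ctx = [0.0] * n_ctx
        self.V_str = [0.0] * n_str
        self.p = {
            "thal_str": [[0.0] * len(self.W["thal_str"][0]) for _ in range(n_str)],
            "ctx_str": [[0.0] * len(self.W["ctx_str"][0]) for _ in range(n_str)],
            "str_str": [[0.0] * n_str for _ in range(n_str)],
        }

    def step(self, thal_t, target_t):
        c = self.cfg
        dt, tau_m, tau_str, b = c.dt_ms, c.tau_m_ms, c.tau_str_ms, c.b
        n_ctx = len(self.V_ctx)
        n_str = len(self.V_str)
        n_thal = len(thal_t)
        d = len(target_t)

        r_ctx = [phi(v, b) for v in self.V_ctx]
        r_str = [phi(v, b) for v in self.V_str]
        r_snr = []
        eps = []
        loss = 0.0
        for k in range(d):
            u = sum(self.W["str_snr"][k][j] * r_str[j] for j in range(n_str))
            rk = phi(u, b)
            r_snr.append(rk)
            e = rk - target_t[k]
            loss += 0.5 * e * e * dt
            eps.append(e * rk * (1.0 - rk))

        C = [sum(self.D[j][k] * eps[k] for k in range(d)) for j in range(n_str)]

        pre_rates = {"thal_str": thal_t, "ctx_str": r_ctx[: self.n_ce], "str_str": r_str}
        for name, sign in (("thal_str", 1.0), ("ctx_str", 1.0), ("str_str", -1.0)):
            pre = pre_rates[name]
            for j in range(n_str):
                drv = r_str[j] * (1.0 - r_str[j])
                for i in range(len(pre)):
                    if self.M[name][j][i]:
                        self.p[name][j][i] += (dt / tau_str) * (
                            -self.p[name][j][i] + drv * pre[i]
                        )
                        w = self.W[name][j][i] - self.alpha[j] * C[j] * self.p[name][j][i] * dt
                        if w * sign < 0.0:
                            w = 0.0
                        self.W[name][j][i] = w
        for k in range(d):
            for j in range(n_str):
                if self.M["str_snr"][k][j]:
                    w = self.W["str_snr"][k][j] - c.beta * eps[k] * r_str[j] * dt
                    if w * self.spn_sign[j] < 0.0:
                        w = 0.0
                    self.W["str_snr"][k][j] = w

        for i in range(n_ctx):
            I = sum(self.W["thal_ctx"][i][m] * thal_t[m] for m in range(n_thal))
            I += sum(self.W["ctx_ctx"][i][i2] * r_ctx[i2] for i2 in range(n_ctx))
            self.V_ctx[i] += dt * (-self.V_ctx[i] / tau_m + I)
        for j in range(n_str):
            I = sum(self.W["thal_str"][j][m] * thal_t[m] for m in range(n_thal))
            I += sum(self.W["ctx_str"][j][i] * r_ctx[i] for i in range(self.n_ce))
            I += sum(self.W["str_str"][j][j2] * r_str[j2] for j2 in range(n_str))
            self.V_str[j] += dt * (-self.V_str[j] / tau_m + I)
        return loss
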