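"""Spatial dopamine field and temporal dopamine dynamics.

Each SNc neuron releases dopamine from ``N_var`` varicosities placed uniformly
in the unit cube; concentration falls off exponentially with Euclidean
distance.  Summing over varicosities gives an *effective nigrostriatal weight*

    d_jk = sum_v (1/lambda) exp(-||p_j - q_kv|| / lambda),

so the concentration seen by SPN j is C_j(t) = sum_k r_k^SNc(t) d_jk.  The
matrix D = [d_jk] acts as the (random, nonnegative) feedback matrix of the
RFLO rule; feedback alignment drives the readout weights toward it.  Control
variants replace D by a shuffled, homogeneous, ideal (transposed-readout) or
zero matrix.  Slow dopamine is modeled as an exponential low-pass of C, and a
feed-forward-inhibition motif implements the high-pass compensation that
recovers the instantaneous signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "place_varicosities",
    "effective_feedback_matrix",
    "FeedbackField",
    "dopamine_concentration",
    "make_feedback_variant",
    "DopamineTrace",
    "lowpass_dopamine",
    "highpass_compensate",
    "feedback_independence",
]


def place_varicosities(n_snc: int, n_var: int, seed: int) -> np.ndarray:
    """I.i.d. uniform varicosity positions, shape [n_snc, n_var, 3]."""
    if n_snc < 1 or n_var < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(n_snc, n_var, 3))


def effective_feedback_matrix(
    spn_positions: np.ndarray,
    varicosity_positions: np.ndarray,
    lambda_da: float,
) -> np.ndarray:
    """Effective nigrostriatal weights ``D[j, k] = sum_v (1/l) exp(-dist/l)``.

    Strictly positive and additive over varicosities.  ``lambda_da`` is the
    spatial decay constant measured relative to the side of the unit cube.
    """
    if lambda_da <= 0:
        raise ValueError("lambda_da must be > 0")
    pos = np.asarray(spn_positions, dtype=float)
    q = np.asarray(varicosity_positions, dtype=float)
    n_snc, n_var, _ = q.shape
    dist = cdist(pos, q.reshape(n_snc * n_var, 3))  # [n_str, n_snc*n_var]
    kern = np.exp(-dist / lambda_da) / lambda_da
    return kern.reshape(pos.shape[0], n_snc, n_var).sum(axis=2)


@dataclass
class FeedbackField:
    """Varicosity geometry and the derived effective feedback matrix."""

    varicosity_positions: np.ndarray  # [n_snc, n_var, 3]
    lambda_da: float
    D: np.ndarray  # [n_str, n_snc], raw heterogeneous matrix
    variant: str = "heterogeneous"
    D_effective: Optional[np.ndarray] = None  # variant-transformed (None for ideal)

    @classmethod
    def build(
        cls,
        spn_positions: np.ndarray,
        n_snc: int,
        n_var: int,
        lambda_da: float,
        seed: int,
        variant: str = "heterogeneous",
        shuffle_seed: Optional[int] = None,
    ) -> "FeedbackField":
        q = place_varicosities(n_snc, n_var, seed)
        D = effective_feedback_matrix(spn_positions, q, lambda_da)
        D_eff = None
        if variant != "ideal":
            D_eff = make_feedback_variant(D, variant, seed=shuffle_seed)
        return cls(
            varicosity_positions=q,
            lambda_da=lambda_da,
            D=D,
            variant=variant,
            D_effective=D_eff,
        )


def dopamine_concentration(D: np.ndarray, r_snc: np.ndarray) -> np.ndarray:
    """Concentration per SPN, ``C = D @ r_snc`` (linear in the SNc rates)."""
    D = np.asarray(D, dtype=float)
    r = np.asarray(r_snc, dtype=float)
    if D.shape[1] != r.shape[0]:
        raise ValueError(f"shape mismatch: D {D.shape} vs r_snc {r.shape}")
    return D @ r


def make_feedback_variant(
    D: np.ndarray,
    variant: str,
    W_str_snr: Optional[np.ndarray] = None,
    spn_sign: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Variant-transformed effective feedback matrix.

    - ``heterogeneous``: D unchanged.
    - ``shuffled``: a fixed elementwise random permutation of all entries.
    - ``homogeneous``: every entry replaced by the mean of D, so each SPN
      receives the identical scalar ``mean(D) * sum_k r_k^SNc`` — the
      large-lambda limit where dopamine released anywhere reaches everyone.
    - ``ideal``: the class-sign-adjusted transposed readout weights
      ``spn_sign[j] * W[k, j]`` (time-dependent; callers re-evaluate each
      step).  The sign adjustment (dSPN readout weights are negative) makes
      the three-factor rule reduce exactly to the derived gradient rule.
    - ``none``: zeros, disabling all striatal plasticity.
    """
    D = np.asarray(D, dtype=float)
    if variant == "heterogeneous":
        return D.copy()
    if variant == "shuffled":
        rng = np.random.default_rng(seed)
        flat = D.ravel().copy()
        rng.shuffle(flat)
        return flat.reshape(D.shape)
    if variant == "homogeneous":
        return np.full_like(D, D.mean())
    if variant == "ideal":
        if W_str_snr is None or spn_sign is None:
            raise ValueError("ideal variant requires W_str_snr and spn_sign")
        return np.asarray(spn_sign, dtype=float)[:, None] * np.asarray(W_str_snr).T
    if variant == "none":
        return np.zeros_like(D)
    raise ValueError(f"unknown feedback variant {variant!r}")


@dataclass
class DopamineTrace:
    """State of the temporal dopamine filters for one population of SPNs.

    With ``tau_da=None`` the dopamine is instantaneous and ``a == C`` at
    every step.  Otherwise ``C_filtered`` is the (normalized) exponential
    low-pass of C with per-step factor ``xi = exp(-dt / tau_da)``, and — when
    compensation is active — ``a`` is the high-pass-reconstructed signal
    ``a(t) = A(t) - xi A(t - dt)`` with ``A = C_filtered / (1 - xi)``.
    """

    n_str: int
    tau_da: Optional[float] = None
    unnormalized: bool = False
    C: np.ndarray = field(init=False)
    C_filtered: np.ndarray = field(init=False)
    C_filtered_prev: np.ndarray = field(init=False)
    a: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.C = np.zeros(self.n_str)
        self.C_filtered = np.zeros(self.n_str)
        self.C_filtered_prev = np.zeros(self.n_str)
        self.a = np.zeros(self.n_str)

    def xi(self, dt: float) -> float:
        if self.tau_da is None:
            return 0.0
        return float(np.exp(-dt / self.tau_da))


def lowpass_dopamine(trace: DopamineTrace, C_now: np.ndarray, dt: float) -> DopamineTrace:
    """Advance the exponential low-pass filter by one step (in place).

    Normalized form ``C' <- xi C' + (1 - xi) C`` (unit gain for constant
    input); the literal unnormalized convolution ``C' <- xi C' + dt * C`` is
    available via ``trace.unnormalized`` for comparison.
    """
    C_now = np.asarray(C_now, dtype=float)
    trace.C = C_now.copy()
    trace.C_filtered_prev = trace.C_filtered.copy()
    if trace.tau_da is None:
        trace.C_filtered = C_now.copy()
        trace.a = C_now.copy()
        return trace
    xi = trace.xi(dt)
    gain = dt if trace.unnormalized else (1.0 - xi)
    trace.C_filtered = xi * trace.C_filtered + gain * C_now
    trace.a = trace.C_filtered.copy()
    return trace


def highpass_compensate(trace: DopamineTrace, dt: float) -> np.ndarray:
    """Reconstruct the instantaneous signal from the low-passed one (in place).

    ``a(t) = A(t) - xi A(t - dt)`` with ``A = C' / (1 - xi)``; with the
    normalized low-pass this telescopes to ``a(t) = C(t)`` exactly.
    """
    if trace.tau_da is None:
        trace.a = trace.C.copy()
        return trace.a
    xi = trace.xi(dt)
    if xi >= 1.0:
        raise ValueError("xi = 1 (tau_da = inf): compensation undefined")
    A_now = trace.C_filtered / (1.0 - xi)
    A_prev = trace.C_filtered_prev / (1.0 - xi)
    trace.a = A_now - xi * A_prev
    return trace.a


def feedback_independence(D: np.ndarray) -> float:
    """Scalar in [0, 1] measuring linear independence of the rows of D.

    Ratio of the smallest to the largest singular value of the row-normalized
    matrix: 0 for rank-deficient D (identical rows), approaching 1 when the
    per-SPN feedback vectors spread isotropically over the error dimensions.
    """
    D = np.asarray(D, dtype=float)
    norms = np.linalg.norm(D, axis=1, keepdims=True)
    if np.all(norms == 0):
        raise ValueError("all-zero feedback matrix")
    rows = D / np.where(norms == 0, 1.0, norms)
    s = np.linalg.svd(rows, compute_uv=False)
    if s[0] == 0:
        return 0.0
    return float(s[-1] / s[0])
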