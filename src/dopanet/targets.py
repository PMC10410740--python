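"""Periodic Gaussian-process targets and the clock-coding thalamic input.

The task of the network is to reproduce a fixed d-dimensional periodic
trajectory, one trial being one period of length ``T``.  Each target dimension
is an independent draw from a Gaussian process with mean 0.5 and squared-
exponential covariance on the *circular* distance

    delta(t1, t2) = min(|t1 - t2|, |t1 - t2 + T|, |t1 - t2 - T|),

    k(t1, t2) = 0.15^2 * exp(-delta^2 / (2 * tau_task^2)),

so consecutive trials tile time without discontinuities.  Time within the trial
is signaled to the network by thalamic units whose rates trace a sinusoidal
clock, r_m(t) = phi(A_m cos(2 pi t / T) + B_m sin(2 pi t / T)) with the
coefficient pairs (A_m, B_m) drawn uniformly from a circle of fixed radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import sigmoid_rate

#: Marginal standard deviation of the target process.
TARGET_SD = 0.15

#: Mean of the target process (the sigmoid midpoint output).
TARGET_MEAN = 0.5


@dataclass
class TargetSet:
    """A fixed d-dimensional periodic target trajectory on the simulation grid."""

    values: np.ndarray  # [d, n_steps]
    trial_duration_ms: float
    dt_ms: float
    tau_task_ms: float
    seed: int

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt_ms


@dataclass
class ThalamicCode:
    """Random sinusoidal clock coefficients, one (A, B) pair per thalamic unit."""

    A: np.ndarray
    B: np.ndarray
    radius: float
    trial_duration_ms: float
    seed: int

    @property
    def n_thal(self) -> int:
        return self.A.size


def periodic_distance(t1, t2, T: float):
    """Smallest difference between two trial times including wrap-around.

    Symmetric in its arguments, with values in ``[0, T/2]``.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if T <= 0:
        raise ValueError("period T must be > 0")
    if np.any(t1 < 0) or np.any(t2 < 0) or np.any(t1 > T) or np.any(t2 > T):
        raise ValueError("times must lie in [0, T]")
    diff = t1 - t2
    out = np.minimum(np.abs(diff), np.minimum(np.abs(diff + T), np.abs(diff - T)))
    return out if out.ndim else float(out)


def build_periodic_covariance(times: np.ndarray, tau_task: float, T: float) -> np.ndarray:
    """Covariance matrix of the periodic target kernel on a time grid.

    Entry (i, j) is ``0.15^2 * exp(-delta(t_i, t_j)^2 / (2 tau_task^2))``.
    """
    if tau_task <= 0:
        raise ValueError("tau_task must be > 0")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be a strictly increasing 1-d grid")
    delta = periodic_distance(times[:, None], times[None, :], T)
    return TARGET_SD**2 * np.exp(-(delta**2) / (2.0 * tau_task**2))


def sample_target_set(
    d: int,
    T: float,
    dt: float,
    tau_task: float,
    seed: int,
    jitter: float = 1e-8,
) -> TargetSet:
    """Draw ``d`` independent periodic GP trajectories on the half-open grid.

    The grid is t = 0, dt, ..., T - dt so concatenated trials tile time
    exactly.  A small diagonal jitter regularizes the near-singular periodic
    kernel before the Cholesky factorization.
    """
    n_steps = int(round(T / dt))
    times = np.arange(n_steps) * dt
    K = build_periodic_covariance(times, tau_task, T)
    K = K + jitter * np.eye(n_steps)
    # The squared-exponential kernel on the *circular* distance is only
    # approximately PSD; its spectrum carries tiny negative eigenvalues that
    # jitter alone cannot absorb.  Factor by eigendecomposition and clip the
    # negative part, refusing kernels that are materially indefinite.
    eigval, eigvec = np.linalg.eigh(K)
    if eigval[0] < -1e-2 * eigval[-1]:
        raise np.linalg.LinAlgError(
            "periodic covariance not PSD after jitter regularization"
        )
    L = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_steps, d))
    values = TARGET_MEAN + (L @ z).T
    return TargetSet(
        values=values,
        trial_duration_ms=T,
        dt_ms=dt,
        tau_task_ms=tau_task,
        seed=seed,
    )


def sample_thalamic_code(
    n_thal: int, radius: float, T: float, seed: int
) -> ThalamicCode:
    """Draw (A_m, B_m) uniformly from the circle of given radius."""
    if n_thal < 1:
        raise ValueError("n_thal must be >= 1")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_thal)
    return ThalamicCode(
        A=radius * np.cos(theta),
        B=radius * np.sin(theta),
        radius=radius,
        trial_duration_ms=T,
        seed=seed,
    )


def thalamic_rates(code: ThalamicCode, t, b: float) -> np.ndarray:
    """Clock-coded thalamic rates at time(s) ``t`` (imposed, not integrated).

    For scalar ``t`` returns a vector [n_thal]; for a vector of times returns
    a matrix [n_times, n_thal].  Periodic with the trial duration; identical
    across trials (the clock carries no trial index).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    omega = 2.0 * np.pi / code.trial_duration_ms
    phase = np.multiply.outer(t, omega)
    drive = np.cos(phase)[..., None] * code.A + np.sin(phase)[..., None] * code.B
    return sigmoid_rate(drive, b)


def thalamic_rate_table(code: ThalamicCode, dt: float, b: float) -> np.ndarray:
    """Precomputed clock rates for one trial, shape [n_steps, n_thal]."""
    n_steps = int(round(code.trial_duration_ms / dt))
    return thalamic_rates(code, np.arange(n_steps) * dt, b)
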