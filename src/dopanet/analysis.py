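"""Post-hoc analyses of trained runs.

Spatial correlation of SPN firing rates versus pairwise distance, preferred
target dimensions mapped onto SPN positions, and the feedback-alignment
diagnostic (cosine similarity between the readout weights and the dopamine
feedback matrix over training).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "CorrelationCurve",
    "correlation_vs_distance",
    "PreferenceMap",
    "preferred_dimension",
    "preference_map",
    "alignment_trajectory",
]

_CONST_TOL = 1e-12


@dataclass
class CorrelationCurve:
    """Mean pairwise rate correlation per distance bin (cube-side units)."""

    bin_edges: np.ndarray  # [n_bins + 1]
    mean_correlation: np.ndarray  # [n_bins]; NaN for empty bins
    n_pairs: np.ndarray  # [n_bins]
    n_excluded: int = 0  # constant-rate SPNs dropped from the analysis

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def nearest_bin_mean(self, min_pairs: int = 1) -> float:
        """Mean correlation in the closest nonempty distance bin."""
        for m, n in zip(self.mean_correlation, self.n_pairs):
            if n >= min_pairs:
                return float(m)
        raise ValueError("no bin with enough pairs")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "distance": self.bin_centers,
                "mean_correlation": self.mean_correlation,
                "n_pairs": self.n_pairs,
            }
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = self.n_pairs > 0
        ax.plot(self.bin_centers[ok], self.mean_correlation[ok], **kwargs)
        ax.axhline(0.0, color="gray", lw=0.5)
        ax.set_xlabel("pairwise distance (cube sides)")
        ax.set_ylabel("mean Pearson correlation")
        return ax


def _pair_values(
    rates: np.ndarray, positions: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Pairwise correlations and distances for one run, excluding constant SPNs."""
    rates = np.asarray(rates, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if rates.shape[0] != positions.shape[0]:
        raise ValueError("rates and positions must agree on the number of SPNs")
    sd = rates.std(axis=1)
    keep = sd > _CONST_TOL
    n_excluded = int(np.sum(~keep))
    rates = rates[keep]
    positions = positions[keep]
    if rates.shape[0] < 2:
        return np.empty(0), np.empty(0), n_excluded
    corr = np.corrcoef(rates)
    iu = np.triu_indices(rates.shape[0], k=1)
    return corr[iu], pdist(positions), n_excluded


def correlation_vs_distance(
    rates: Union[np.ndarray, Sequence[np.ndarray]],
    positions: Union[np.ndarray, Sequence[np.ndarray]],
    bin_width: float = 0.05,
) -> CorrelationCurve:
    """Pearson correlation of SPN rate traces, averaged in distance bins.

    ``rates``/``positions`` may be single arrays ([n_str, n_time] /
    [n_str, 3]) or equal-length sequences of arrays from repeated runs, in
    which case *pairs* (not traces) are pooled across runs.  Distances are in
    units of the cube side; bins cover [0, sqrt(3)].  SPNs with constant rate
    traces have undefined correlations and are excluded (counted in
    ``n_excluded``).
    """
    if isinstance(rates, np.ndarray):
        rates = [rates]
        positions = [positions]
    if len(rates) != len(positions):
        raise ValueError("need one position set per rate set")

    all_corr: List[np.ndarray] = []
    all_dist: List[np.ndarray] = []
    n_excluded = 0
    for r, p in zip(rates, positions):
        c_vals, d_vals, n_ex = _pair_values(r, p)
        all_corr.append(c_vals)
        all_dist.append(d_vals)
        n_excluded += n_ex
    corr = np.concatenate(all_corr)
    dist = np.concatenate(all_dist)

    edges = np.arange(0.0, np.sqrt(3.0) + bin_width, bin_width)
    n_bins = edges.size - 1
    mean_corr = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=int)
    idx = np.digitize(dist, edges) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    for i in range(n_bins):
        sel = idx == i
        n_pairs[i] = int(sel.sum())
        if n_pairs[i]:
            mean_corr[i] = corr[sel].mean()
    return CorrelationCurve(
        bin_edges=edges,
        mean_correlation=mean_corr,
        n_pairs=n_pairs,
        n_excluded=n_excluded,
    )


@dataclass
class PreferenceMap:
    """Preferred target dimension per SPN, with positions for plotting.

    ``labels[j]`` is the index of the target dimension SPN j's rate trace is
    most correlated with, or -1 for SPNs with constant (undefined) traces.
    """

    spn_positions: np.ndarray  # [n_str, 3]
    labels: np.ndarray  # [n_str] int
    is_dspn: np.ndarray  # [n_str] bool

    def plot(self, spn_class: str = "dspn", ax=None, cmap: str = "tab10"):
        """Scatter of (x, y) positions colored by preferred dimension, viewed
        orthographically from above (z omitted)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sel = self.is_dspn if spn_class == "dspn" else ~self.is_dspn
        sel = sel & (self.labels >= 0)
        ax.scatter(
            self.spn_positions[sel, 0],
            self.spn_positions[sel, 1],
            c=self.labels[sel],
            cmap=cmap,
            s=25,
        )
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        ax.set_title("dSPN" if spn_class == "dspn" else "iSPN")
        return ax


def preferred_dimension(rates: np.ndarray, target_values: np.ndarray) -> np.ndarray:
    """Index of the target dimension each SPN is most correlated with.

    ``rates`` is [n_str, n_time]; ``target_values`` is [d, n_steps] and is
    tiled to the rate-trace length (recordings may span several trials).
    Ties break toward the lowest index; constant traces get label -1.
    """
    rates = np.asarray(rates, dtype=float)
    T = np.asarray(target_values, dtype=float)
    n_time = rates.shape[1]
    if n_time % T.shape[1] != 0:
        raise ValueError("rate-trace length must be a multiple of the trial length")
    T_tiled = np.tile(T, n_time // T.shape[1])

    labels = np.full(rates.shape[0], -1, dtype=int)
    t_sd = T_tiled.std(axis=1)
    for j in range(rates.shape[0]):
        r = rates[j]
        if r.std() <= _CONST_TOL:
            continue
        rc = r - r.mean()
        corr = (T_tiled - T_tiled.mean(axis=1, keepdims=True)) @ rc
        corr = corr / (t_sd * rc.std() * n_time + _CONST_TOL)
        labels[j] = int(np.argmax(corr))  # argmax takes the lowest index on ties
    return labels


def preference_map(result) -> PreferenceMap:
    """Build a :class:`PreferenceMap` from a :class:`TrainingResult`."""
    labels = preferred_dimension(result.rates_recorded, result.targets.values)
    return PreferenceMap(
        spn_positions=result.state.spn_positions,
        labels=labels,
        is_dspn=result.state.is_dspn,
    )


def alignment_trajectory(
    weight_snapshots: np.ndarray,
    D: np.ndarray,
    spn_sign: np.ndarray,
) -> np.ndarray:
    """Cosine similarity between readout weights and the feedback matrix.

    For each snapshot W [d, n_str], the columns belonging to dSPNs (negative
    readout sign) are negated before comparing with D^T; feedback alignment
    predicts this similarity grows during training.  Zero-norm snapshots give
    NaN.
    """
    snaps = np.asarray(weight_snapshots, dtype=float)
    Dt = np.asarray(D, dtype=float).T  # [d, n_str]
    s = np.asarray(spn_sign, dtype=float)[None, :]
    d_vec = Dt.ravel()
    d_norm = np.linalg.norm(d_vec)
    out = np.empty(snaps.shape[0])
    for i, W in enumerate(snaps):
        w_vec = (s * W).ravel()
        w_norm = np.linalg.norm(w_vec)
        if w_norm == 0 or d_norm == 0:
            out[i] = np.nan
        else:
            out[i] = float(w_vec @ d_vec / (w_norm * d_norm))
    return out
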