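"""Model and results objects.

:class:`BasalGangliaModel` assembles the full simulation from a
:class:`~dopanet.config.SimConfig` — periodic GP targets, the thalamic clock,
sign-constrained connectivity and the dopamine feedback field — and its
:meth:`~BasalGangliaModel.fit` runs online three-factor learning for the
configured number of trials, returning a :class:`TrainingResult` with the
per-trial loss curve, final weights, rate recordings, readout-weight snapshots
and alignment diagnostics.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from ._core import run_trials_core
from .config import SimConfig
from .dopamine import FeedbackField
from .network import NetworkState, init_connectivity
from .targets import (
    TargetSet,
    ThalamicCode,
    sample_target_set,
    sample_thalamic_code,
    thalamic_rate_table,
)

__all__ = ["BasalGangliaModel", "TrainingResult"]


@dataclass
class TrainingResult:
    """Outcome of one training run.

    ``per_trial_loss[i]`` is the squared output error integrated over trial i
    (sum of the instantaneous loss over the trial's time steps, times dt).
    ``rates_recorded`` holds the SPN rate traces of the final
    ``config.record_trials`` trials, concatenated in time.
    """

    config: SimConfig
    per_trial_loss: np.ndarray
    state: NetworkState
    feedback: FeedbackField
    targets: TargetSet
    thal_code: ThalamicCode
    rates_recorded: np.ndarray  # [n_str, record_trials * n_steps]
    snr_first_trial: np.ndarray  # [d, n_steps]
    snr_last_trial: np.ndarray  # [d, n_steps]
    w_snr_snapshots: np.ndarray  # [n_snaps, d, n_str]
    snapshot_trials: np.ndarray  # [n_snaps]
    failed_at: int = -1  # trial index of numerical failure, -1 if none

    @property
    def converged(self) -> bool:
        return self.failed_at < 0

    @property
    def n_trials(self) -> int:
        return self.per_trial_loss.size

    def final_loss(self, window: int = 10) -> float:
        """Median per-trial loss over the last ``window`` trials."""
        return float(np.median(self.per_trial_loss[-window:]))

    @property
    def initial_loss(self) -> float:
        return float(self.per_trial_loss[0])

    def alignment(self) -> np.ndarray:
        """Cosine similarity between the (class-sign-adjusted) readout weights
        and the dopamine feedback matrix, one value per snapshot."""
        from .analysis import alignment_trajectory

        return alignment_trajectory(
            self.w_snr_snapshots, self.feedback.D, self.state.spn_sign
        )

    def summary(self, window: int = 10) -> str:
        c = self.config
        align = self.alignment()
        lines = [
            "Basal-ganglia RFLO training result",
            "=" * 50,
            f"feedback variant      {c.feedback_variant}",
            f"populations           Thal={c.n_thal} Ctx={c.n_ctx} "
            f"dSPN={c.n_dspn} iSPN={c.n_ispn} d={c.d}",
            f"dopamine field        lambda={c.lambda_da} N_var={c.n_varicosities}",
            f"dopamine dynamics     tau_da={c.tau_da_ms} "
            f"compensation={c.highpass_compensation}",
            f"lesions               {c.lesions or 'none'}",
            f"trials                {self.n_trials} x {c.trial_duration_ms:.0f} ms",
            f"seed                  {c.seed}",
            "-" * 50,
            f"initial trial loss    {self.initial_loss:.3f}",
            f"final trial loss      {self.final_loss(window):.3f}  "
            f"(median of last {window} trials)",
            f"loss reduction        "
            f"{100.0 * (1.0 - self.final_loss(window) / self.initial_loss):.1f}%",
            f"feedback alignment    {align[0]:.3f} -> {align[-1]:.3f}",
            f"Dale's law            {'ok' if self.state.check_dale() else 'VIOLATED'}",
            f"numerical status      "
            f"{'ok' if self.converged else f'diverged at trial {self.failed_at}'}",
        ]
        return "\n".join(lines)

    def plot_loss(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.per_trial_loss, **kwargs)
        ax.set_xlabel("trial")
        ax.set_ylabel("trial loss (L2)")
        return ax


class BasalGangliaModel:
    """A basal-ganglia-like recurrent rate network trained with dopamine feedback.

    Parameters
    ----------
    config
        Full simulation configuration.  All randomness (targets, clock,
        connectivity, varicosities, shuffling) derives from ``config.seed``.

    Examples
    --------
    >>> from dopanet import SimConfig, BasalGangliaModel
    >>> model = BasalGangliaModel(SimConfig.desk(n_trials=50, seed=1))
    >>> result = model.fit()
    >>> print(result.summary())  # doctest: +SKIP
    """

    def __init__(self, config: SimConfig):
        self.config = config
        self._built = False
        self.state: Optional[NetworkState] = None
        self.targets: Optional[TargetSet] = None
        self.thal_code: Optional[ThalamicCode] = None
        self.feedback: Optional[FeedbackField] = None

    # ------------------------------------------------------------------ build
    def build(self) -> "BasalGangliaModel":
        """Construct targets, clock, connectivity and the dopamine field."""
        c = self.config
        seeds = c.stage_seeds()
        self.targets = sample_target_set(
            c.d, c.trial_duration_ms, c.dt_ms, c.tau_task_ms, seeds["targets"]
        )
        self.thal_code = sample_thalamic_code(
            c.n_thal, c.thal_radius, c.trial_duration_ms, seeds["thal_code"]
        )
        self.state = init_connectivity(c)
        self.feedback = FeedbackField.build(
            self.state.spn_positions,
            c.n_snc,
            c.n_varicosities,
            c.lambda_da,
            seeds["varicosities"],
            variant=c.feedback_variant,
            shuffle_seed=seeds["shuffle"],
        )
        self._apply_lesions()
        self._built = True
        return self

    def _apply_lesions(self) -> None:
        for proj, mode in self.config.lesions.items():
            projection = self.state.projections[proj]
            if mode == "static":
                projection.plastic = False
            elif mode == "absent":
                projection.weights[:] = 0.0
                projection.mask[:] = False

    # -------------------------------------------------------------------- fit
    def fit(self, raise_on_instability: bool = True) -> TrainingResult:
        """Run online training and return the results object.

        Always (re)builds from the config seeds first, so repeated calls are
        reproducible and independent.  A numerical divergence aborts with the
        trial index unless ``raise_on_instability`` is False.
        """
        self.build()
        c = self.config
        state = self.state
        P = state.projections

        thal = np.ascontiguousarray(thalamic_rate_table(self.thal_code, c.dt_ms, c.b))
        targets = np.ascontiguousarray(self.targets.values)

        W = {name: np.ascontiguousarray(P[name].weights) for name in P}
        M = {
            name: np.ascontiguousarray(P[name].mask)
            for name in ("thal_str", "ctx_str", "str_str", "str_snr")
        }

        variant = c.feedback_variant
        ideal_mode = variant == "ideal"
        striatal_on = variant != "none"
        D_eff = (
            np.zeros((c.n_str, c.d))
            if self.feedback.D_effective is None
            else np.ascontiguousarray(self.feedback.D_effective)
        )

        rec_trials = min(c.record_trials, c.n_trials)
        rec_from = c.n_trials - rec_trials
        rates_rec = np.zeros((c.n_str, rec_trials * c.n_steps))
        losses = np.zeros(c.n_trials)
        snr_first = np.zeros((c.d, c.n_steps))
        snr_last = np.zeros((c.d, c.n_steps))

        snap_every = max(int(c.snapshot_every), 0)
        if snap_every > 0:
            n_snaps = (c.n_trials - 1) // snap_every + 1
            snapshot_trials = np.arange(n_snaps) * snap_every
        else:
            n_snaps = 1
            snapshot_trials = np.array([0])
        W_sn_snaps = np.zeros((n_snaps, c.d, c.n_str))
        if snap_every == 0:
            W_sn_snaps[0] = W["str_snr"]

        p_ts = np.zeros_like(W["thal_str"])
        p_cs = np.zeros_like(W["ctx_str"])
        p_ss = np.zeros_like(W["str_str"])
        C_filt = np.zeros(c.n_str)
        C_filt_prev = np.zeros(c.n_str)

        tau_da = float(c.tau_da_ms) if c.tau_da_ms is not None else -1.0

        failed_at = run_trials_core(
            c.n_trials,
            c.n_steps,
            c.dt_ms,
            c.tau_m_ms,
            c.tau_str_ms,
            c.b,
            thal,
            targets,
            state.V["ctx"],
            state.V["str"],
            W["thal_ctx"],
            W["ctx_ctx"],
            W["thal_str"],
            W["ctx_str"],
            W["str_str"],
            W["str_snr"],
            M["thal_str"],
            M["ctx_str"],
            M["str_str"],
            M["str_snr"],
            c.n_ctx_exc,
            state.spn_sign,
            state.alpha_per_spn,
            c.beta,
            D_eff,
            ideal_mode,
            striatal_on,
            P["thal_str"].plastic,
            P["ctx_str"].plastic,
            P["str_str"].plastic,
            P["str_snr"].plastic,
            tau_da,
            c.highpass_compensation,
            c.unnormalized_lowpass,
            p_ts,
            p_cs,
            p_ss,
            C_filt,
            C_filt_prev,
            losses,
            rec_from,
            rates_rec,
            snr_first,
            snr_last,
            snap_every,
            W_sn_snaps,
        )

        if failed_at >= 0 and raise_on_instability:
            raise FloatingPointError(
                f"simulation became non-finite at trial {int(failed_at)}"
            )

        # write trained weights back into the state's projections
        for name in P:
            P[name].weights = W[name]

        return TrainingResult(
            config=c,
            per_trial_loss=losses,
            state=state,
            feedback=self.feedback,
            targets=self.targets,
            thal_code=self.thal_code,
            rates_recorded=rates_rec,
            snr_first_trial=snr_first,
            snr_last_trial=snr_last,
            w_snr_snapshots=W_sn_snaps,
            snapshot_trials=snapshot_trials,
            failed_at=int(failed_at),
        )
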