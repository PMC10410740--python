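"""Simulation configuration.

A single :class:`SimConfig` carries every structural, dynamical, plasticity and
experiment parameter of the basal-ganglia model, plus the master seed from which
all per-stage random streams are derived.  Three ready-made profiles are
provided: :meth:`SimConfig.paper` (full-scale conditions), :meth:`SimConfig.desk`
(reduced populations and trial counts for interactive work and CI) and
:meth:`SimConfig.correlation` (the profile used for the spatial-correlation
analysis).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

#: Projection identifiers, ordered source -> target.
PROJECTIONS = ("thal_ctx", "ctx_ctx", "thal_str", "ctx_str", "str_str", "str_snr")

#: Projections whose weights are subject to dopamine-modulated / delta-rule plasticity.
PLASTIC_PROJECTIONS = ("thal_str", "ctx_str", "str_str", "str_snr")

FEEDBACK_VARIANTS = ("heterogeneous", "homogeneous", "shuffled", "ideal", "none")

LESION_MODES = ("static", "absent")

#: Random stages with independent substreams derived from the master seed.
SEED_STAGES = ("connectivity", "positions", "varicosities", "targets", "thal_code", "shuffle")


def _default_conn_prob() -> dict:
    # All projections sparse at p=0.5 except the dense readout.
    p = {name: 0.5 for name in PROJECTIONS}
    p["str_snr"] = 1.0
    return p


def _default_w_max() -> dict:
    # Scales chosen so the untrained balanced network sits close to the edge of
    # chaos (perturbation-growth checked) with an unsaturated readout; see
    # docs/methods.md.
    return {
        "thal_ctx": 15.0,
        "ctx_ctx": 20.0,
        "thal_str": 15.0,
        "ctx_str": 15.0,
        "str_str": 20.0,
        "str_snr": 2.0,
    }


@dataclass
class SimConfig:
    """All parameters of a training run.

    Counts
    ------
    The readout (SNr/GPi) and dopaminergic (SNc) populations both have ``d``
    units — one per output dimension — so that the SNc can carry the
    d-dimensional error vector.
    """

    # populations
    n_thal: int = 40
    n_ctx: int = 100
    ctx_exc_frac: float = 0.5
    n_dspn: int = 50
    n_ispn: int = 50
    d: int = 4

    # dynamics
    tau_m_ms: float = 10.0
    b: float = 2.0
    dt_ms: float = 1.0
    trial_duration_ms: float = 200.0

    # task
    n_trials: int = 5000
    tau_task_ms: float = 20.0
    thal_radius: float = 4.0

    # connectivity
    connection_probabilities: dict = field(default_factory=_default_conn_prob)
    w_max: dict = field(default_factory=_default_w_max)

    # plasticity (alpha is the magnitude; dSPNs use -alpha, iSPNs +alpha)
    alpha: float = 2.5e-2
    beta: float = 1e-3
    tau_str_ms: float = 10.0

    # dopamine field
    lambda_da: float = 0.1
    n_varicosities: int = 10
    tau_da_ms: Optional[float] = None
    highpass_compensation: bool = False
    unnormalized_lowpass: bool = False

    feedback_variant: str = "heterogeneous"

    # lesions: projection name -> "static" | "absent"
    lesions: dict = field(default_factory=dict)

    # recording
    record_trials: int = 5
    snapshot_every: int = 50

    seed: int = 0

    # ------------------------------------------------------------------ derived
    @property
    def n_str(self) -> int:
        return self.n_dspn + self.n_ispn

    @property
    def n_ctx_exc(self) -> int:
        return int(round(self.n_ctx * self.ctx_exc_frac))

    @property
    def n_ctx_inh(self) -> int:
        return self.n_ctx - self.n_ctx_exc

    @property
    def n_snr(self) -> int:
        return self.d

    @property
    def n_snc(self) -> int:
        return self.d

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_duration_ms / self.dt_ms))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = (self.n_thal, self.n_ctx, self.n_dspn, self.n_ispn, self.d)
        if any(c < 1 for c in counts):
            raise ValueError("all population counts must be >= 1")
        if abs(self.trial_duration_ms / self.dt_ms - self.n_steps) > 1e-9:
            raise ValueError("dt_ms must divide trial_duration_ms exactly")
        if self.dt_ms >= self.tau_m_ms:
            raise ValueError(
                f"dt={self.dt_ms} >= tau_m={self.tau_m_ms}: forward-Euler unstable"
            )
        for name, p in self.connection_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"connection probability {name}={p} outside [0, 1]")
        for name, w in self.w_max.items():
            if w < 0:
                raise ValueError(f"w_max {name}={w} must be nonnegative")
        if self.feedback_variant not in FEEDBACK_VARIANTS:
            raise ValueError(f"unknown feedback variant {self.feedback_variant!r}")
        for proj, mode in self.lesions.items():
            if proj not in PLASTIC_PROJECTIONS:
                raise ValueError(f"cannot lesion unknown projection {proj!r}")
            if mode not in LESION_MODES:
                raise ValueError(f"unknown lesion mode {mode!r}")
        if self.lambda_da <= 0:
            raise ValueError("lambda_da must be > 0")
        if self.tau_da_ms is not None and self.tau_da_ms <= 0:
            raise ValueError("tau_da_ms must be > 0 (or None for instantaneous)")

    # ------------------------------------------------------------------- seeds
    def stage_seeds(self) -> dict:
        """Independent 31-bit seeds for each random stage, derived from ``seed``."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(SEED_STAGES))
        return {
            name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for name, child in zip(SEED_STAGES, children)
        }

    # ---------------------------------------------------------------- profiles
    @classmethod
    def paper(cls, **overrides) -> "SimConfig":
        """Full-scale conditions: 5,000 trials, 100 SPNs."""
        return cls(**overrides)

    @classmethod
    def desk(cls, **overrides) -> "SimConfig":
        """Reduced profile for interactive work and CI: 60 SPNs, 600 trials."""
        params = dict(
            n_thal=30,
            n_ctx=60,
            n_dspn=30,
            n_ispn=30,
            n_trials=600,
            record_trials=3,
            snapshot_every=25,
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def correlation(cls, **overrides) -> "SimConfig":
        """Profile for the spatial-correlation analysis: 100 SPNs, 1,000 trials."""
        params = dict(
            n_thal=40,
            n_ctx=100,
            n_dspn=50,
            n_ispn=50,
            n_trials=1000,
            record_trials=5,
        )
        params.update(overrides)
        return cls(**params)

    # --------------------------------------------------------------------- io
    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
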