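"""Run archives (HDF5).

One archive per training run: per-trial losses, final weights with masks,
SPN positions, the feedback matrix and varicosity geometry, target and clock
definitions (with their seeds as attributes), rate recordings and
readout-weight snapshots, plus the full configuration echoed as JSON.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .config import SimConfig
from .dopamine import FeedbackField
from .model import TrainingResult
from .network import init_connectivity
from .targets import TargetSet, ThalamicCode

__all__ = ["save_result", "load_result"]


def save_result(result: TrainingResult, path) -> None:
    c = result.config
    with h5py.File(path, "w") as f:
        f.attrs["config_json"] = json.dumps(c.to_dict())
        f.attrs["failed_at"] = result.failed_at

        f.create_dataset("per_trial_loss", data=result.per_trial_loss)
        g = f.create_group("weights")
        for name, proj in result.state.projections.items():
            g.create_dataset(name, data=proj.weights)
            g.create_dataset(name + "_mask", data=proj.mask)
        f.create_dataset("spn_positions", data=result.state.spn_positions)
        f.create_dataset("is_dspn", data=result.state.is_dspn)

        gf = f.create_group("feedback")
        gf.create_dataset("D", data=result.feedback.D)
        gf.create_dataset(
            "varicosity_positions", data=result.feedback.varicosity_positions
        )
        gf.attrs["lambda_da"] = result.feedback.lambda_da
        gf.attrs["variant"] = result.feedback.variant
        if result.feedback.D_effective is not None:
            gf.create_dataset("D_effective", data=result.feedback.D_effective)

        gt = f.create_group("targets")
        gt.create_dataset("values", data=result.targets.values)
        gt.attrs.update(
            seed=result.targets.seed,
            trial_duration_ms=result.targets.trial_duration_ms,
            dt_ms=result.targets.dt_ms,
            tau_task_ms=result.targets.tau_task_ms,
        )
        gc = f.create_group("thal_code")
        gc.create_dataset("A", data=result.thal_code.A)
        gc.create_dataset("B", data=result.thal_code.B)
        gc.attrs.update(
            seed=result.thal_code.seed,
            radius=result.thal_code.radius,
            trial_duration_ms=result.thal_code.trial_duration_ms,
        )

        f.create_dataset("rates_recorded", data=result.rates_recorded)
        f.create_dataset("snr_first_trial", data=result.snr_first_trial)
        f.create_dataset("snr_last_trial", data=result.snr_last_trial)
        f.create_dataset("w_snr_snapshots", data=result.w_snr_snapshots)
        f.create_dataset("snapshot_trials", data=result.snapshot_trials)


def load_result(path) -> TrainingResult:
    with h5py.File(path, "r") as f:
        config = SimConfig.from_dict(json.loads(f.attrs["config_json"]))
        # rebuild the state skeleton, then overwrite with the stored weights
        state = init_connectivity(config)
        for name, proj in state.projections.items():
            proj.weights = f["weights"][name][()]
            proj.mask = f["weights"][name + "_mask"][()]
        state.spn_positions = f["spn_positions"][()]
        state.is_dspn = f["is_dspn"][()]

        gf = f["feedback"]
        feedback = FeedbackField(
            varicosity_positions=gf["varicosity_positions"][()],
            lambda_da=float(gf.attrs["lambda_da"]),
            D=gf["D"][()],
            variant=str(gf.attrs["variant"]),
            D_effective=gf["D_effective"][()] if "D_effective" in gf else None,
        )
        gt = f["targets"]
        targets = TargetSet(
            values=gt["values"][()],
            trial_duration_ms=float(gt.attrs["trial_duration_ms"]),
            dt_ms=float(gt.attrs["dt_ms"]),
            tau_task_ms=float(gt.attrs["tau_task_ms"]),
            seed=int(gt.attrs["seed"]),
        )
        gc = f["thal_code"]
        thal_code = ThalamicCode(
            A=gc["A"][()],
            B=gc["B"][()],
            radius=float(gc.attrs["radius"]),
            trial_duration_ms=float(gc.attrs["trial_duration_ms"]),
            seed=int(gc.attrs["seed"]),
        )
        return TrainingResult(
            config=config,
            per_trial_loss=f["per_trial_loss"][()],
            state=state,
            feedback=feedback,
            targets=targets,
            thal_code=thal_code,
            rates_recorded=f["rates_recorded"][()],
            snr_first_trial=f["snr_first_trial"][()],
            snr_last_trial=f["snr_last_trial"][()],
            w_snr_snapshots=f["w_snr_snapshots"][()],
            snapshot_trials=f["snapshot_trials"][()],
            failed_at=int(f.attrs["failed_at"]),
        )
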