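"""Plain-text persistence: waveform CSVs with JSON sidecars, cohort and
session tables, and the run report.

Waveforms are one CSV per breath or oscillometry replicate (columns
``time_s, flow_L_per_s`` for occlusion breaths; ``time_s, pressure_kPa,
flow_L_per_s`` for multisine replicates) with a JSON sidecar recording
participant, modality, seed and settings.  No binary formats are used.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Participant
from .simulate import Breath, FotReplicate, ReomTestRecording

__all__ = [
    "write_reom_recording",
    "read_reom_recording",
    "write_fot_replicate",
    "read_fot_replicate",
    "cohort_to_frame",
    "write_cohort_csv",
    "write_json",
]


def _sidecar(path: Path, meta: dict) -> None:
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def write_reom_recording(directory, participant_id: str, test_index: int,
                         rec: ReomTestRecording, meta: dict | None = None) -> list[Path]:
    """One CSV per breath plus a sidecar per test; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, b in enumerate(rec.breaths, start=1):
        path = directory / f"{participant_id}_reom_t{test_index}_b{i:02d}.csv"
        pd.DataFrame({"time_s": b.t, "flow_L_per_s": b.flow}).to_csv(path, index=False)
        _sidecar(path, {
            "participant_id": participant_id, "modality": "reom",
            "test_index": test_index, "breath_index": i,
            "P_peak_kPa": b.P_peak, "release_index": b.release_index,
            "injected_artifact": b.injected_artifact, **(meta or {}),
        })
        paths.append(path)
    return paths


def read_reom_recording(directory, participant_id: str,
                        test_index: int) -> ReomTestRecording:
    directory = Path(directory)
    breaths = []
    pattern = f"{participant_id}_reom_t{test_index}_b*.csv"
    for path in sorted(directory.glob(pattern)):
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        breaths.append(Breath(
            t=df["time_s"].to_numpy(), flow=df["flow_L_per_s"].to_numpy(),
            P_peak=float(meta["P_peak_kPa"]),
            release_index=int(meta["release_index"]),
            injected_artifact=bool(meta["injected_artifact"]),
        ))
    if not breaths:
        raise FileNotFoundError(f"no breaths matching {pattern} in {directory}")
    return ReomTestRecording(breaths=breaths)


def write_fot_replicate(directory, participant_id: str, rep_index: int,
                        rep: FotReplicate, meta: dict | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{participant_id}_fot_r{rep_index}.csv"
    pd.DataFrame({
        "time_s": rep.t, "pressure_kPa": rep.pressure, "flow_L_per_s": rep.flow,
    }).to_csv(path, index=False)
    _sidecar(path, {"participant_id": participant_id, "modality": "fot",
                    "replicate_index": rep_index, "duration_s": rep.duration,
                    **(meta or {})})
    return path


def read_fot_replicate(directory, participant_id: str, rep_index: int) -> FotReplicate:
    path = Path(directory) / f"{participant_id}_fot_r{rep_index}.csv"
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return FotReplicate(t=df["time_s"].to_numpy(),
                        pressure=df["pressure_kPa"].to_numpy(),
                        flow=df["flow_L_per_s"].to_numpy(),
                        duration=float(meta["duration_s"]))


def cohort_to_frame(participants: list[Participant]) -> pd.DataFrame:
    """Flatten a cohort (truth targets, latent mechanics, covariates)."""
    rows = []
    for p in participants:
        rows.append({
            "participant_id": p.id, "group": p.group,
            "age_y": p.demographics.age, "sex": p.demographics.sex,
            "bmi_kg_m2": p.demographics.bmi,
            "pack_years": p.demographics.pack_years,
            "R5_true": p.targets["R5"], "R19_true": p.targets["R19"],
            "Reos_true": p.targets["Reo_s"], "Reof_true": p.targets["Reo_f"],
            "Raw": p.model.Raw, "Rve": p.model.Rve,
            "tau_ve_s": p.model.tau_ve, "Crs": p.model.Crs,
            "sensor_fc_Hz": p.device.sensor_fc,
            "p_overshoot": p.device.p_overshoot,
            "C0_shunt": p.c0_shunt,
            "calibration_residual": p.calibration_residual,
            "calibration_ok": p.calibration_ok,
        })
    return pd.DataFrame(rows)


def write_cohort_csv(path, participants: list[Participant]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort_to_frame(participants).to_csv(path, index=False)
    return path


def write_json(path, obj) -> Path:
    """JSON dump tolerant of numpy scalars/arrays and dataclasses."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=default))
    return path
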