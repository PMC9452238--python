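"""Plain-text persistence for epoch sets and averaged responses.

An epoch set is stored as ``<base>.csv`` (rows = epochs, columns = samples,
values in uV, no header) plus a JSON sidecar ``<base>.json`` with the
recording metadata.  An averaged response is stored as a two-column CSV
(time_ms, microvolts) plus a sidecar with n_epochs_used, residual_noise and
quality.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AveragedResponse, EpochSet, QualityTier, StimulusConfig

__all__ = [
    "save_epoch_set",
    "load_epoch_set",
    "save_averaged_response",
    "load_averaged_response",
]


def _paths(base: str | Path) -> tuple[Path, Path]:
    base = Path(base)
    if base.suffix in {".csv", ".json"}:
        base = base.with_suffix("")
    return base.with_suffix(".csv"), base.with_suffix(".json")


def save_epoch_set(epochs: EpochSet, base: str | Path, seed: int | None = None) -> Path:
    """Write ``<base>.csv`` + ``<base>.json``; returns the CSV path."""
    csv_path, json_path = _paths(base)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(csv_path, epochs.data, delimiter=",", fmt="%.6g")
    meta: dict = {
        "subject_id": epochs.subject_id,
        "fs": epochs.fs,
        "t_start_ms": epochs.t_start_ms,
        "n_epochs": epochs.n_epochs,
        "n_samples": epochs.n_samples,
        "seed": seed,
    }
    if epochs.stimulus is not None:
        meta["frequency_hz"] = epochs.stimulus.frequency_hz
        meta["intensity_dbhl"] = epochs.stimulus.intensity_dbhl
        meta["isi_s"] = epochs.stimulus.isi_s
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path


def load_epoch_set(base: str | Path) -> EpochSet:
    """Read the CSV + JSON pair written by :func:`save_epoch_set`."""
    csv_path, json_path = _paths(base)
    meta = json.loads(json_path.read_text())
    data = pd.read_csv(csv_path, header=None).to_numpy(dtype=float)
    if data.ndim == 1:
        data = data[None, :]
    stimulus = None
    if "frequency_hz" in meta:
        stimulus = StimulusConfig(
            frequency_hz=meta["frequency_hz"],
            intensity_dbhl=meta["intensity_dbhl"],
            isi_s=meta.get("isi_s", 1.125),
        )
    return EpochSet(
        data=data,
        fs=meta["fs"],
        t_start_ms=meta["t_start_ms"],
        stimulus=stimulus,
        subject_id=meta.get("subject_id"),
    )


def save_averaged_response(avg: AveragedResponse, base: str | Path) -> Path:
    """Write the average as two-column CSV plus a JSON sidecar."""
    csv_path, json_path = _paths(base)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame({"time_ms": avg.times(), "microvolts": avg.waveform})
    frame.to_csv(csv_path, index=False, float_format="%.6g")
    meta = {
        "subject_id": avg.subject_id,
        "fs": avg.fs,
        "t_start_ms": avg.t_start_ms,
        "n_epochs_used": avg.n_epochs_used,
        "residual_noise": None if np.isnan(avg.residual_noise) else avg.residual_noise,
        "quality": avg.quality.value if avg.quality is not None else None,
    }
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path


def load_averaged_response(base: str | Path) -> AveragedResponse:
    """Read the CSV + JSON pair written by :func:`save_averaged_response`."""
    csv_path, json_path = _paths(base)
    meta = json.loads(json_path.read_text())
    frame = pd.read_csv(csv_path)
    rn = meta.get("residual_noise")
    quality = meta.get("quality")
    return AveragedResponse(
        waveform=frame["microvolts"].to_numpy(dtype=float),
        fs=meta["fs"],
        t_start_ms=meta["t_start_ms"],
        n_epochs_used=meta["n_epochs_used"],
        residual_noise=float("nan") if rn is None else float(rn),
        quality=QualityTier(quality) if quality else None,
        subject_id=meta.get("subject_id"),
    )
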