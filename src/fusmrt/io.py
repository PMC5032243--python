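"""Artifact I/O: NIfTI volumes, HDF5 k-space stacks, CSV/JSON metrics."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .mracq import KSpaceFrame, SamplingMask

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_temperature_series",
    "save_kspace",
    "load_kspace",
    "save_phases_csv",
    "save_experiment",
]


def _affine(spacing_m, origin_m=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.eye(4)
    for a in range(3):
        aff[a, a] = spacing_m[a] * 1e3       # NIfTI headers are in mm
        aff[a, 3] = origin_m[a] * 1e3
    return aff


def save_nifti(volume: np.ndarray, spacing_m, path, origin_m=(0.0, 0.0, 0.0)) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                          _affine(spacing_m, origin_m))
    img.to_filename(str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj), tuple(z * 1e-3 for z in zooms)


def save_temperature_series(series, path_nii, path_json=None) -> None:
    """4D NIfTI (x, y, z, frame) plus a JSON sidecar with frame times (s)."""
    vol = np.moveaxis(np.asarray(series.frames, dtype=np.float32), 0, -1)
    img = nib.Nifti1Image(vol, _affine(series.spacing, series.origin))
    img.to_filename(str(path_nii))
    if path_json is None:
        path_json = str(path_nii).replace(".nii.gz", "").replace(".nii", "") + "_times.json"
    Path(path_json).write_text(json.dumps({"frame_times_s": series.times.tolist()}))


def save_kspace(frames: list[KSpaceFrame], path, attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.stack([fr.data for fr in frames]).astype(np.complex64))
        f.create_dataset("mask", data=np.stack([fr.mask.pattern for fr in frames]))
        f.create_dataset("t_start", data=[fr.t_start for fr in frames])
        f.create_dataset("t_acq", data=[fr.t_acq for fr in frames])
        f.create_dataset("R", data=[fr.mask.R for fr in frames])
        f.create_dataset("etl", data=[fr.mask.etl for fr in frames])
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_kspace(path) -> list[KSpaceFrame]:
    frames = []
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        mask = f["mask"][...]
        t_start = f["t_start"][...]
        t_acq = f["t_acq"][...]
        R = f["R"][...]
        etl = f["etl"][...]
    for i in range(data.shape[0]):
        m = SamplingMask(pattern=mask[i], R=float(R[i]), etl=int(etl[i]),
                         frame_index=i)
        frames.append(KSpaceFrame(data=data[i].astype(complex), mask=m,
                                  t_start=float(t_start[i]), t_acq=float(t_acq[i])))
    return frames


def save_phases_csv(phases: np.ndarray, path) -> None:
    pd.DataFrame({"element_id": np.arange(len(phases)),
                  "phase_rad": phases}).to_csv(path, index=False)


def save_experiment(result, out_dir) -> None:
    """Write the standard artifact bundle of one experiment run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    med = result.medium
    save_nifti(result.q.q, med.spacing, out / "q.nii.gz", med.origin)
    save_temperature_series(result.truth_mr, out / "truth_temps.nii.gz")
    if result.corrected_phases is not None:
        save_phases_csv(result.corrected_phases, out / "phases.csv")
    rows = []
    for method, agg in result.metrics.items():
        row = {"method": method}
        for k, v in agg.items():
            if isinstance(v, (int, float)):
                row[k] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    summary = {
        "name": result.config["name"],
        "focal_intensity_w_m2": result.focal_intensity,
        "q_offset_mm": np.asarray(result.q_offset_mm).tolist(),
        "extras": {k: v for k, v in result.extras.items()
                   if isinstance(v, (int, float, str))},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
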