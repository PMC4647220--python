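"""On-disk formats: MEG epoch containers, NIfTI PET volumes, truth tables.

MEG epochs are stored as a NumPy ``.npz`` archive (``data`` trials x sensors
x samples, ``eog`` trials x samples) with a JSON sidecar holding the
sampling rate, epoch start and sensor geometry.  PET volumes and ROI masks
are NIfTI-1 with voxel sizes in the header; masks are 0/1 volumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import HeadModel, PETDynamic, PETGeometry, TrialSet
from .geometry import CohortGeometry
from .synthetic_cohort import truth_total_v1_bmax


def save_trialset(path, trials: TrialSet, head: HeadModel = None) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), data=trials.data, eog=trials.eog)
    sidecar = {"srate": trials.srate, "t0": trials.t0,
               "n_rejected": trials.n_rejected}
    if head is not None:
        sidecar["sensor_positions"] = head.sensor_positions.tolist()
        sidecar["sensor_orientations"] = head.sensor_orientations.tolist()
        sidecar["sphere_center"] = head.sphere_center.tolist()
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_trialset(path) -> TrialSet:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return TrialSet(arrays["data"], arrays["eog"], meta["srate"], meta["t0"],
                    n_rejected=meta.get("n_rejected", 0))


def _affine(geometry: PETGeometry) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(geometry.voxel_size)
    aff[:3, 3] = 0.5 * geometry.voxel_size  # voxel centres at (i+0.5)*size
    return aff


def save_volume(path, values: np.ndarray, geometry: PETGeometry) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, np.float32),
                             _affine(geometry)), str(path))


def save_mask(path, voxel_indices: np.ndarray, geometry: PETGeometry) -> None:
    mask = np.zeros(geometry.n_voxels, np.uint8)
    mask[np.asarray(voxel_indices, int)] = 1
    nib.save(nib.Nifti1Image(mask.reshape(geometry.shape), _affine(geometry)),
             str(path))


def load_volume(path):
    img = nib.load(str(path))
    geometry = PETGeometry(img.shape[:3], img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, float), geometry


def load_mask_indices(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.nonzero(np.asarray(img.dataobj).ravel() > 0)[0]


def save_pet_dynamic(path, dyn: PETDynamic) -> None:
    """4D NIfTI (x, y, z, frames) plus a JSON sidecar of frame times."""
    path = Path(path)
    vol = np.moveaxis(dyn.frames, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, _affine(dyn.geometry)), str(path))
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(
        {"frame_times_min": dyn.frame_times.tolist()}))


def truth_table(subjects: list, geometry: CohortGeometry) -> pd.DataFrame:
    """Cohort ground-truth table in the documented CSV layout."""
    return pd.DataFrame([{
        "subject_id": s.subject_id,
        "gamma_peak_freq_hz": s.gamma_peak_freq,
        "gamma_amp": s.gamma_amp,
        "gamma_latency_ms": s.gamma_latency * 1e3,
        "total_v1_bmax": truth_total_v1_bmax(s, geometry),
        "v1_surface_area_mm2": s.v1_surface_area,
        "gm_density": s.gm_density,
    } for s in subjects])
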