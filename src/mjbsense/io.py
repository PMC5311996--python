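"""HDF5 containers for PROPELLER data sets and NIfTI image export.

Layout of the HDF5 container (schema version 1):

    /kspace      complex64, (blade, coil, line, readout)
    /geometry    group: angles_deg, blade_width_lines, n_readout,
                 accel_factor, acquired_line_indices
    /csm         complex64, (coil, y, x)           [optional]
    /truth       float32, (y, x)                   [optional]
    /motion      float64, (blade, 3) rot/dx/dy     [optional]
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .containers import BladeSet, CoilMaps, GroundTruthImage, MotionParams

SCHEMA_VERSION = 1

__all__ = ["save_dataset", "load_dataset", "export_nifti", "save_motion_csv"]


def save_dataset(
    path: str | Path,
    blades: BladeSet,
    csm: CoilMaps | None = None,
    truth: GroundTruthImage | None = None,
    motion: MotionParams | None = None,
    attrs: dict | None = None,
) -> None:
    """Write a PROPELLER data set (and optional ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset(
            "kspace", data=blades.kspace.astype(np.complex64), compression="gzip"
        )
        g = f.create_group("geometry")
        g.create_dataset("angles_deg", data=blades.blade_angles_deg)
        g.attrs["blade_width_lines"] = blades.blade_width_lines
        g.attrs["n_readout"] = blades.n_readout
        g.attrs["accel_factor"] = blades.accel_factor
        g.create_dataset(
            "acquired_line_indices", data=blades.acquired_line_indices
        )
        if csm is not None:
            f.create_dataset(
                "csm", data=csm.maps.astype(np.complex64), compression="gzip"
            )
        if truth is not None:
            f.create_dataset(
                "truth", data=truth.pixels.astype(np.float32), compression="gzip"
            )
        if motion is not None:
            f.create_dataset("motion", data=motion.as_array())
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def load_dataset(path: str | Path) -> dict:
    """Load a PROPELLER data set; returns a dict with ``blades`` plus any
    of ``csm``, ``truth``, ``motion`` that are present."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        g = f["geometry"]
        out["blades"] = BladeSet(
            kspace=np.asarray(f["kspace"], dtype=complex),
            blade_angles_deg=np.asarray(g["angles_deg"]),
            blade_width_lines=int(g.attrs["blade_width_lines"]),
            n_readout=int(g.attrs["n_readout"]),
            accel_factor=int(g.attrs["accel_factor"]),
            acquired_line_indices=np.asarray(g["acquired_line_indices"]),
        )
        if "csm" in f:
            out["csm"] = CoilMaps(np.asarray(f["csm"], dtype=complex))
        if "truth" in f:
            out["truth"] = GroundTruthImage(np.asarray(f["truth"], dtype=float))
        if "motion" in f:
            m = np.asarray(f["motion"])
            out["motion"] = MotionParams(m[:, 0], m[:, 1], m[:, 2])
    return out


def export_nifti(
    path: str | Path, images: np.ndarray, voxel_mm: float = 1.0
) -> None:
    """Save magnitude image(s) as NIfTI; a stack's first axis becomes the
    volume dimension."""
    arr = np.abs(np.asarray(images)).astype(np.float32)
    if arr.ndim == 2:
        arr = arr[..., None]
    elif arr.ndim == 3:
        arr = np.moveaxis(arr, 0, -1)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def save_motion_csv(path: str | Path, motion: MotionParams) -> None:
    """Plain CSV table of per-blade motion parameters."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["blade", "rot_deg", "dx_px", "dy_px"])
        for i in range(motion.n_blades):
            w.writerow(
                [
                    i,
                    f"{motion.rotations_deg[i]:.6f}",
                    f"{motion.shifts_x_px[i]:.6f}",
                    f"{motion.shifts_y_px[i]:.6f}",
                ]
            )
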