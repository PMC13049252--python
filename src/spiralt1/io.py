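"""File containers: HDF5 k-space/trajectory layout, NIfTI series, CSV fits.

The k-space container layout::

    /traj/coords        frames x samples x 2   float64, cycles/FOV
    /traj/dcf           samples                float64
    /traj  attrs: fov_mm, res_mm, readout_ms
    /traj/angles_deg    frames (optional)
    /kspace/data        frames x coils x samples   complex128
    /kspace/frame_signs frames                     int
    /kspace attrs: first_ti_ms, delta_ti_ms, n_acquired, n_appended,
                   n_prepended, frame_roles (comma-joined)

Image series are written as 4D NIfTI (Ny, Nx, 1, frames) with the voxel
size in the header; complex series are written as separate magnitude and
signed-real volumes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .analysis import T1FitResults
from .series import ImageSeries, KSpaceSeries, TISchedule
from .trajectory import Trajectory


def save_trajectory(group: h5py.Group, traj: Trajectory) -> None:
    g = group.create_group("traj") if "traj" not in group else group["traj"]
    g.create_dataset("coords", data=traj.coords)
    g.create_dataset("dcf", data=traj.dcf)
    if traj.angles_deg is not None:
        g.create_dataset("angles_deg", data=traj.angles_deg)
    g.attrs["fov_mm"] = traj.fov_mm
    g.attrs["res_mm"] = traj.res_mm
    g.attrs["readout_ms"] = traj.readout_ms


def load_trajectory(group: h5py.Group) -> Trajectory:
    g = group["traj"]
    return Trajectory(
        coords=g["coords"][()],
        dcf=g["dcf"][()],
        fov_mm=float(g.attrs["fov_mm"]),
        res_mm=float(g.attrs["res_mm"]),
        readout_ms=float(g.attrs.get("readout_ms", 12.0)),
        angles_deg=g["angles_deg"][()] if "angles_deg" in g else None,
    )


def save_kspace(path: str | Path, kspace: KSpaceSeries) -> None:
    with h5py.File(path, "w") as f:
        save_trajectory(f, kspace.traj)
        g = f.create_group("kspace")
        g.create_dataset("data", data=kspace.data)
        g.create_dataset("frame_signs", data=np.asarray(kspace.frame_signs))
        sch = kspace.schedule
        g.attrs["first_ti_ms"] = sch.first_ti_ms
        g.attrs["delta_ti_ms"] = sch.delta_ti_ms
        g.attrs["n_acquired"] = sch.n_acquired
        g.attrs["n_appended"] = sch.n_appended
        g.attrs["n_prepended"] = sch.n_prepended
        g.attrs["frame_roles"] = ",".join(kspace.frame_roles)


def load_kspace(path: str | Path) -> KSpaceSeries:
    with h5py.File(path, "r") as f:
        traj = load_trajectory(f)
        g = f["kspace"]
        sch = TISchedule(
            first_ti_ms=float(g.attrs["first_ti_ms"]),
            delta_ti_ms=float(g.attrs["delta_ti_ms"]),
            n_acquired=int(g.attrs["n_acquired"]),
            n_appended=int(g.attrs["n_appended"]),
            n_prepended=int(g.attrs["n_prepended"]),
        )
        return KSpaceSeries(
            data=g["data"][()],
            schedule=sch,
            traj=traj,
            frame_signs=g["frame_signs"][()],
            frame_roles=str(g.attrs["frame_roles"]).split(","),
        )


def save_coil_maps(path: str | Path, maps: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("maps", data=maps)


def load_coil_maps(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["maps"][()]


def _nifti(series_data: np.ndarray, res_mm: float) -> nib.Nifti1Image:
    # frames last, singleton z; voxel size in mm
    vol = np.transpose(series_data, (1, 2, 0))[:, :, None, :]
    affine = np.diag([res_mm, res_mm, 1.0, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(vol, dtype=np.float64), affine)
    img.header.set_zooms((res_mm, res_mm, 1.0, 1.0))
    return img


def save_image_series(
    path_prefix: str | Path, series: ImageSeries
) -> dict[str, Path]:
    """Write magnitude and signed-real NIfTI volumes; returns their paths."""
    prefix = Path(path_prefix)
    out = {}
    for tag, data in (
        ("mag", np.abs(series.data)),
        ("real", series.data.real),
    ):
        p = prefix.with_name(prefix.name + f"_{tag}.nii.gz")
        nib.save(_nifti(data, series.res_mm), p)
        out[tag] = p
    return out


def load_image_series(path: str | Path, fov_mm: float | None = None) -> ImageSeries:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    data = np.transpose(vol[:, :, 0, :], (2, 0, 1)).astype(complex)
    res_mm = float(img.header.get_zooms()[0])
    return ImageSeries(
        data=data,
        fov_mm=fov_mm if fov_mm is not None else res_mm * vol.shape[0],
        res_mm=res_mm,
    )


def fits_to_dataframe(fits: list[T1FitResults]) -> pd.DataFrame:
    rows = []
    for i, f in enumerate(fits, start=1):
        rows.append(
            {
                "vessel": f.label or f"vessel_{i}",
                "t1_ms": f.t1_ms,
                "m0": f.m0,
                "minit": f.minit,
                "r_squared": f.r_squared,
                "ci95_halfwidth_ms": f.ci95_halfwidth_ms,
                "excluded": f.excluded,
            }
        )
    return pd.DataFrame(rows)
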