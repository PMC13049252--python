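"""Synthetic inflow phantom and forward simulation of the acquisition.

Emulates the physics that the single-shot spiral Look-Locker measurement
relies on:

* flowing blood in the vessels is fully refreshed between TIs (the inflow
  condition ``delta_TI > THK / v``), so every frame sees freshly inverted
  spins relaxing from the single non-selective inversion — the full
  inversion-recovery curve ``M0 * (1 - (1 + eps) * exp(-TI/T1))``;
* static background tissue is re-saturated by every 90-degree excitation
  (plus the pre-saturation train before the inversion), so it sits on a
  near-constant saturation-recovery plateau ``M0 * (1 - exp(-dTI/T1))``;
* one variable-density spiral arm is acquired per TI, golden-angle rotated,
  with complex Gaussian noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nufft import GriddingNUFFT
from .series import ImageSeries, KSpaceSeries, TISchedule, default_frame_roles
from .trajectory import Trajectory

__all__ = [
    "TISchedule",
    "KSpaceSeries",
    "DigitalPhantom",
    "AcqParams",
    "CoilMaps",
    "make_phantom",
    "simulate_ir_series",
    "make_coil_maps",
    "simulate_kspace",
]


@dataclass
class DigitalPhantom:
    """Digital 2D vessel phantom: T1 map, M0 map, and vessel labels.

    ``vessel_labels`` is 0 for static background and ``v >= 1`` for the
    flowing-blood vessel ``v``; each vessel is a filled circle.
    """

    t1_map_ms: np.ndarray
    m0_map: np.ndarray
    vessel_labels: np.ndarray
    matrix: tuple[int, int]
    fov_mm: float

    @property
    def res_mm(self) -> float:
        return self.fov_mm / self.matrix[0]

    @property
    def n_vessels(self) -> int:
        return int(self.vessel_labels.max())

    def vessel_mask(self, label: int) -> np.ndarray:
        return self.vessel_labels == label


@dataclass
class AcqParams:
    """Acquisition/simulation parameters for the synthetic experiment.

    ``noise_sigma`` is the standard deviation of the complex Gaussian noise
    added to every k-space sample (per real/imaginary component it is
    ``noise_sigma / sqrt(2)``).  If None, it is derived at simulation time
    as ``noise_fraction`` times the RMS of the noiseless k-space of the
    last frame — a fixed, documented signal-relative noise level.
    """

    slice_thickness_mm: float = 5.0
    blood_velocity_cm_s: float = 10.0
    inversion_efficiency: float = 1.0
    noise_sigma: float | None = None
    noise_fraction: float = 0.02
    seed: int = 0

    def inflow_condition(self, delta_ti_ms: float) -> bool:
        """True when every TI interval fully refreshes the slice with
        upstream blood: delta_TI > THK / v."""
        transit_s = (self.slice_thickness_mm / 10.0) / self.blood_velocity_cm_s
        return delta_ti_ms / 1000.0 > transit_s


@dataclass
class CoilMaps:
    """Complex coil sensitivity maps, coils x Ny x Nx."""

    maps: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))


def make_phantom(
    matrix: tuple[int, int],
    fov_mm: float,
    vessel_spec: list[tuple[tuple[float, float], float, float]],
    background_t1_ms: float = 1200.0,
    background_m0: float = 1.0,
    vessel_m0: float = 1.0,
) -> DigitalPhantom:
    """Build a labeled vessel phantom inside a smooth background ellipse.

    Parameters
    ----------
    vessel_spec : list of ((cy_mm, cx_mm), radius_mm, blood_t1_ms) with
        centers in mm relative to the FOV center.  Vessels are rasterized
        by the pixel-center-in-circle rule and may not overlap.
    """
    ny, nx = matrix
    res = fov_mm / ny
    y = (np.arange(ny) - ny // 2) * res
    x = (np.arange(nx) - nx // 2) * res
    yy, xx = np.meshgrid(y, x, indexing="ij")

    # background: a neck-like ellipse filling ~80% of the FOV
    ell = (yy / (0.42 * fov_mm)) ** 2 + (xx / (0.42 * fov_mm)) ** 2 <= 1.0
    t1 = np.where(ell, background_t1_ms, 1.0)
    m0 = np.where(ell, background_m0, 0.0).astype(float)
    labels = np.zeros(matrix, dtype=int)

    for i, ((cy, cx), radius_mm, blood_t1) in enumerate(vessel_spec, start=1):
        if radius_mm <= 0:
            raise ValueError(f"vessel {i}: radius must be > 0")
        if abs(cy) + radius_mm > fov_mm / 2 or abs(cx) + radius_mm > fov_mm / 2:
            raise ValueError(f"vessel {i}: extends outside the FOV")
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_mm**2
        if np.any(labels[inside] != 0):
            raise ValueError(f"vessel {i} overlaps vessel {labels[inside].max()}")
        labels[inside] = i
        t1[inside] = blood_t1
        m0[inside] = vessel_m0

    return DigitalPhantom(
        t1_map_ms=t1, m0_map=m0, vessel_labels=labels, matrix=matrix, fov_mm=fov_mm
    )


def simulate_ir_series(
    phantom: DigitalPhantom,
    schedule: TISchedule,
    acq: AcqParams,
    exact_first_frame: bool = False,
    presat_delay_ms: float = 150.0,
) -> ImageSeries:
    """Ground-truth signed longitudinal signal at every measured TI.

    Vessel pixels follow full inversion recovery
    ``M(TI) = M0 * (1 - (1 + eps) * exp(-TI/T1))`` with ``eps`` the
    inversion efficiency (1 = perfect inversion, Minit = -M0).  Background
    pixels sit on the saturation-recovery plateau
    ``M0 * (1 - exp(-delta_TI/T1))`` in every frame; with
    ``exact_first_frame`` the first frame instead reflects recovery since
    the pre-saturation train ``presat_delay_ms`` before the inversion.
    """
    if not acq.inflow_condition(schedule.delta_ti_ms):
        warnings.warn(
            "inflow condition delta_TI > THK/v violated: vessel spins are "
            "not fully refreshed between excitations",
            stacklevel=2,
        )
    tis = schedule.ti_values_ms
    t1 = phantom.t1_map_ms
    m0 = phantom.m0_map
    vessel = phantom.vessel_labels > 0
    eps = acq.inversion_efficiency

    frames = np.empty((len(tis),) + phantom.matrix)
    plateau = m0 * (1.0 - np.exp(-schedule.delta_ti_ms / t1))
    for i, ti in enumerate(tis):
        ir = m0 * (1.0 - (1.0 + eps) * np.exp(-ti / t1))
        bg = plateau
        if exact_first_frame and i == 0:
            bg = m0 * (1.0 - np.exp(-(presat_delay_ms + ti) / t1))
        frames[i] = np.where(vessel, ir, bg)
    frames *= m0 > 0

    return ImageSeries(
        data=frames.astype(complex),
        fov_mm=phantom.fov_mm,
        res_mm=phantom.res_mm,
        frame_roles=default_frame_roles(schedule, padded=False),
    )


def make_coil_maps(
    matrix: tuple[int, int], n_coils: int, fov_fraction: float = 0.75
) -> CoilMaps:
    """Smooth complex Gaussian-lobe coil sensitivities around the FOV.

    Coils are centered on a ring just outside the object with broad
    Gaussian magnitude lobes and coil-specific smooth phase ramps, giving a
    root-sum-of-squares that varies by less than a factor ~2 over the FOV.
    ``n_coils=1`` returns a uniform unit sensitivity.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    ny, nx = matrix
    if n_coils == 1:
        return CoilMaps(maps=np.ones((1, ny, nx), dtype=complex))
    y = np.linspace(-0.5, 0.5, ny)
    x = np.linspace(-0.5, 0.5, nx)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    maps = np.empty((n_coils, ny, nx), dtype=complex)
    ring = 0.5 * fov_fraction
    sigma = 0.9
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils
        cy, cx = ring * np.sin(ang), ring * np.cos(ang)
        mag = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)))
        phase = np.pi * (np.cos(ang) * yy - np.sin(ang) * xx) + ang / 3.0
        maps[c] = mag * np.exp(1j * phase)
    return CoilMaps(maps=maps)


def simulate_kspace(
    truth: ImageSeries,
    coils: CoilMaps,
    traj: Trajectory,
    acq: AcqParams,
    schedule: TISchedule | None = None,
    oversamp: float = 3.0,
    width: int = 6,
) -> KSpaceSeries:
    """Forward-simulate multi-coil spiral k-space: one arm per frame.

    ``data[f, c, :] = NUFFT_f(S_c * I_f) + noise``.  The simulation NUFFT
    uses a finer gridding (3x oversampling, width-6 kernel) than the
    reconstruction default so that simulated data are not generated by the
    exact operator later inverted.
    """
    if schedule is None:
        schedule = TISchedule(
            n_acquired=truth.n_frames, n_appended=0, n_prepended=0
        )
    if traj.n_frames != truth.n_frames:
        raise ValueError(
            f"trajectory has {traj.n_frames} frames, images {truth.n_frames}"
        )
    shape = truth.shape
    if coils.maps.shape[1:] != shape:
        raise ValueError("coil map matrix does not match image matrix")

    n_frames, n_coils = truth.n_frames, coils.n_coils
    data = np.empty((n_frames, n_coils, traj.n_samples), dtype=complex)
    for f in range(n_frames):
        op = GriddingNUFFT(traj.coords[f], shape, oversamp=oversamp, width=width)
        for c in range(n_coils):
            data[f, c] = op.forward(coils.maps[c] * truth.data[f])

    sigma = acq.noise_sigma
    if sigma is None:
        sigma = acq.noise_fraction * float(
            np.sqrt(np.mean(np.abs(data[-1]) ** 2))
        )
    if sigma > 0:
        root = np.random.SeedSequence(acq.seed)
        streams = root.spawn(n_frames)
        for f in range(n_frames):
            rng = np.random.default_rng(streams[f])
            noise = rng.standard_normal(
                (n_coils, traj.n_samples, 2)
            ) @ np.array([1.0, 1j])
            data[f] += noise * (sigma / np.sqrt(2.0))

    return KSpaceSeries(data=data, schedule=schedule, traj=traj)
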