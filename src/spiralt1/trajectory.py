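"""Golden-angle schedules and variable-density spiral k-space trajectories.

The acquisition samples one center-out spiral arm per inversion time (TI),
rotating the arm by the golden angle (137.51 deg) between consecutive TIs.
The spiral is variable-density: the central 15% of k-space radius is fully
sampled, the outer 50% is undersampled 5-fold, and the reduction factor
ramps linearly in between.

Conventions
-----------
k-space coordinates are in cycles per field of view, so the Nyquist radius
for an ``N x N`` matrix is ``N / 2`` and the fully sampled radial pitch
between successive spiral revolutions is exactly 1.  Rotations are applied
counter-clockwise in the (kx, ky) plane; angles are stored in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GOLDEN_ANGLE_DEG = 137.51


@dataclass(frozen=True)
class GoldenAngleSchedule:
    """Cumulative golden-angle rotation schedule, one angle per frame.

    Frame 1 is unrotated; frame ``i`` (1-based) sits at
    ``increment_deg * (i - 1)`` degrees.
    """

    n_frames: int
    increment_deg: float = GOLDEN_ANGLE_DEG
    angles_deg: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        angles = self.increment_deg * np.arange(self.n_frames, dtype=float)
        object.__setattr__(self, "angles_deg", angles)

    def angle_mod_360(self, frame: int) -> float:
        """Rotation angle of 1-based ``frame`` folded into [0, 360)."""
        return float(self.angles_deg[frame - 1] % 360.0)

    def distance_to_zero_deg(self, frame: int) -> float:
        """Minimal angular distance of ``frame`` to 0 deg, in [0, 180]."""
        a = self.angle_mod_360(frame)
        return min(a, 360.0 - a)


def golden_angle_schedule(
    n_frames: int, increment_deg: float = GOLDEN_ANGLE_DEG
) -> GoldenAngleSchedule:
    """Build the cumulative rotation schedule for ``n_frames`` frames."""
    return GoldenAngleSchedule(n_frames=n_frames, increment_deg=increment_deg)


@dataclass(frozen=True)
class VDSpiralProfile:
    """Radial undersampling profile of the variable-density spiral.

    ``reduction(r)`` is 1 (fully sampled) up to ``full_sample_fraction`` of
    the Nyquist radius, ``outer_reduction`` beyond ``outer_fraction``, and
    linear in radius in between (continuous at both knots).
    """

    full_sample_fraction: float = 0.15
    outer_fraction: float = 0.50
    outer_reduction: float = 5.0
    inner_reduction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.full_sample_fraction < self.outer_fraction <= 1.0:
            raise ValueError("require 0 <= full_sample_fraction < outer_fraction <= 1")
        if self.outer_reduction < self.inner_reduction:
            raise ValueError("outer_reduction must be >= inner_reduction")

    def reduction(self, r_fraction: np.ndarray | float) -> np.ndarray | float:
        """Undersampling factor at radius fraction ``r_fraction`` in [0, 1]."""
        r = np.asarray(r_fraction, dtype=float)
        if np.any(r < 0.0) or np.any(r > 1.0):
            raise ValueError("r_fraction must lie in [0, 1]")
        slope = (self.outer_reduction - self.inner_reduction) / (
            self.outer_fraction - self.full_sample_fraction
        )
        out = np.clip(
            self.inner_reduction + slope * (r - self.full_sample_fraction),
            self.inner_reduction,
            self.outer_reduction,
        )
        if np.isscalar(r_fraction):
            return float(out)
        return out


def reduction_factor(r_fraction: float, profile: VDSpiralProfile) -> float:
    """Piecewise-linear undersampling factor at a radius fraction."""
    return float(profile.reduction(r_fraction))


@dataclass
class Trajectory:
    """Per-frame spiral-arm k-space coordinates with density compensation.

    ``coords`` has shape (n_frames, n_samples, 2) in cycles/FOV; every frame
    is the base arm rotated by ``angles_deg[frame]``.  ``dcf`` is shared by
    all frames (rotation does not change sampling density).
    """

    coords: np.ndarray
    dcf: np.ndarray
    fov_mm: float
    res_mm: float
    readout_ms: float = 12.0
    angles_deg: np.ndarray | None = None
    profile: VDSpiralProfile | None = None

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_samples(self) -> int:
        return self.coords.shape[1]

    @property
    def matrix(self) -> int:
        return int(round(self.fov_mm / self.res_mm))

    @property
    def kmax(self) -> float:
        return self.matrix / 2.0

    def sample_times_ms(self) -> np.ndarray:
        """Readout time of each sample, uniform dwell over the readout."""
        return np.linspace(0.0, self.readout_ms, self.n_samples)

    def frame_subset(self, frame_indices: np.ndarray | list[int]) -> "Trajectory":
        """Trajectory restricted to (0-based) ``frame_indices``, in order."""
        idx = np.asarray(frame_indices, dtype=int)
        angles = None if self.angles_deg is None else self.angles_deg[idx]
        return Trajectory(
            coords=self.coords[idx],
            dcf=self.dcf,
            fov_mm=self.fov_mm,
            res_mm=self.res_mm,
            readout_ms=self.readout_ms,
            angles_deg=angles,
            profile=self.profile,
        )

    def effective_acceleration(self) -> float:
        """Nyquist sample count divided by acquired sample count per frame.

        The Nyquist count is the number of unit (1 cycle/FOV)^2 cells in the
        sampled k-space disk, pi * kmax**2 — the samples a fully sampled
        single-shot acquisition of the same coverage would need.
        """
        return float(np.pi * self.kmax**2 / self.n_samples)


def _integrate_arm_radius(kmax: float, profile: VDSpiralProfile, n_fine: int = 20_000):
    """Integrate dk/dtheta = reduction(k/kmax) / (2 pi) from k=0 to kmax.

    Returns (theta_fine, k_fine) with k_fine[-1] == kmax exactly.
    """
    # integrate theta(k) = 2 pi * int_0^k dk' / R(k'/kmax) on a fine k grid;
    # R is piecewise linear so trapezoid on a dense grid is plenty accurate
    k_fine = np.linspace(0.0, kmax, n_fine)
    inv_r = 1.0 / np.asarray(profile.reduction(k_fine / kmax))
    theta = 2.0 * np.pi * np.concatenate(
        ([0.0], np.cumsum((inv_r[1:] + inv_r[:-1]) / 2.0 * np.diff(k_fine)))
    )
    return theta, k_fine


def design_vd_spiral(
    fov_mm: float,
    res_mm: float,
    n_samples: int | None = None,
    profile: VDSpiralProfile | None = None,
    schedule: GoldenAngleSchedule | None = None,
    readout_ms: float = 12.0,
    dwell_us: float = 2.5,
) -> Trajectory:
    """Design the center-out variable-density Archimedean spiral.

    The arm is parameterized at constant angular velocity with a
    radius-dependent pitch: the local radial gap between successive
    revolutions equals ``reduction(r)`` times the Nyquist gap (1 cycle/FOV).
    Gradient-hardware constraints are deliberately not modeled.

    Parameters
    ----------
    n_samples : number of readout samples; defaults to readout_ms / dwell_us
        (12 ms at 2.5 us -> 4800).
    schedule : golden-angle schedule; one rotated copy of the arm is stored
        per frame (default: a single unrotated frame).
    """
    if profile is None:
        profile = VDSpiralProfile()
    if schedule is None:
        schedule = golden_angle_schedule(1)
    if n_samples is None:
        n_samples = int(round(readout_ms * 1000.0 / dwell_us))
    matrix = int(round(fov_mm / res_mm))
    kmax = matrix / 2.0

    theta_fine, k_fine = _integrate_arm_radius(kmax, profile)
    theta_max = theta_fine[-1]
    theta = np.linspace(0.0, theta_max, n_samples)
    k_r = np.interp(theta, theta_fine, k_fine)
    k_r[-1] = kmax  # |k| must reach the Nyquist radius exactly

    # feasibility: consecutive radial spacing may not exceed the local
    # allowed pitch reduction(r) * Nyquist spacing (= reduction(r) here)
    dk = np.diff(k_r)
    allowed = np.asarray(profile.reduction(k_r[:-1] / kmax))
    bad = dk > allowed + 1e-12
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"n_samples={n_samples} too small: radial spacing {dk[i]:.3f} "
            f"exceeds allowed {allowed[i]:.3f} cycles/FOV near "
            f"|k|/kmax={k_r[i] / kmax:.2f}"
        )

    base = np.stack([k_r * np.cos(theta), k_r * np.sin(theta)], axis=-1)
    coords = np.empty((schedule.n_frames, n_samples, 2))
    for f in range(schedule.n_frames):
        coords[f] = rotate_arm(base, schedule.angles_deg[f])

    traj = Trajectory(
        coords=coords,
        dcf=np.ones(n_samples),
        fov_mm=fov_mm,
        res_mm=res_mm,
        readout_ms=readout_ms,
        angles_deg=schedule.angles_deg.copy(),
        profile=profile,
    )
    traj.dcf = density_compensation(traj)
    return traj


def rotate_arm(arm: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate (n_samples, 2) k-space coordinates counter-clockwise."""
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return arm @ rot.T


def density_compensation(traj: Trajectory) -> np.ndarray:
    """Analytic density-compensation weights for a center-out spiral arm.

    Each sample's Voronoi cell is approximated as (arc length between
    samples) x (radial gap between revolutions), giving weights proportional
    to |k| * dk/dtheta.  Near the origin the cell degenerates, so weights
    are floored at the area of the central disk divided by the samples in
    it.  Weights are normalized so their sum equals matrix**2, which makes
    the density-compensated adjoint point-spread function peak ~1 even
    though the spiral disk does not cover the corners of the k-space square.
    """
    arm = traj.coords[0]
    k_r = np.hypot(arm[:, 0], arm[:, 1])
    if np.allclose(k_r, 0.0):
        raise ValueError("degenerate trajectory: all samples at k = 0")
    theta = np.unwrap(np.arctan2(arm[:, 1], arm[:, 0]))
    dtheta = np.gradient(theta)
    dk_dtheta = np.gradient(k_r) / np.where(dtheta == 0, 1e-30, dtheta)
    w = np.abs(k_r * dk_dtheta * dtheta) * 2.0 * np.pi
    # floor: share the innermost annulus area among the first-revolution samples
    first_rev = theta < theta[0] + 2.0 * np.pi
    n_first = max(int(np.count_nonzero(first_rev)), 1)
    k_first = max(k_r[first_rev].max(), 1e-9)
    floor = np.pi * k_first**2 / n_first
    w = np.maximum(w, floor * (k_r <= k_first))
    w = np.maximum(w, 1e-12)
    w *= traj.matrix**2 / w.sum()
    return w


def uniform_cartesian_trajectory(matrix: int, fov_mm: float) -> Trajectory:
    """Fully sampled Cartesian grid expressed as a one-frame point list.

    Used as the trivial limit in which gridding reconstruction is exact and
    all density-compensation weights are equal.
    """
    half = matrix // 2
    ky, kx = np.meshgrid(
        np.arange(-half, matrix - half, dtype=float),
        np.arange(-half, matrix - half, dtype=float),
        indexing="ij",
    )
    coords = np.stack([kx.ravel(), ky.ravel()], axis=-1)[None]
    return Trajectory(
        coords=coords,
        dcf=np.ones(matrix * matrix),
        fov_mm=fov_mm,
        res_mm=fov_mm / matrix,
        angles_deg=np.zeros(1),
    )
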