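"""Shared dynamic-series containers: image frames and multi-coil k-space."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

ROLE_PREPENDED = "prepended"
ROLE_ACQUIRED = "acquired"
ROLE_APPENDED = "appended"


@dataclass
class TISchedule:
    """Inversion-time grid: acquired TIs plus appended and prepended frames.

    The acquired+appended TIs are ``first_ti_ms + (i - 1) * delta_ti_ms``
    for 1-based ``i``.  Prepended frames are pseudo-frames (sign-inverted
    copies of late frames used only during reconstruction); they carry no
    TI of their own and are excluded from fitting.
    """

    first_ti_ms: float = 50.0
    delta_ti_ms: float = 200.0
    n_acquired: int = 50
    n_appended: int = 5
    n_prepended: int = 4

    @property
    def n_measured(self) -> int:
        """Frames actually acquired in one shot (acquired + appended)."""
        return self.n_acquired + self.n_appended

    @property
    def n_padded(self) -> int:
        """Total frame count after periodic padding."""
        return self.n_prepended + self.n_measured

    @property
    def ti_values_ms(self) -> np.ndarray:
        """TIs of the measured (acquired + appended) frames, in order."""
        i = np.arange(1, self.n_measured + 1, dtype=float)
        return self.first_ti_ms + (i - 1.0) * self.delta_ti_ms

    @property
    def acquired_ti_ms(self) -> np.ndarray:
        """TIs entering the T1 fit (the first ``n_acquired`` frames)."""
        return self.ti_values_ms[: self.n_acquired]


def default_frame_roles(schedule: TISchedule, padded: bool) -> list[str]:
    roles = [ROLE_ACQUIRED] * schedule.n_acquired + [ROLE_APPENDED] * schedule.n_appended
    if padded:
        roles = [ROLE_PREPENDED] * schedule.n_prepended + roles
    return roles


@dataclass
class ImageSeries:
    """Complex image frames (frames x Ny x Nx) with per-frame role tags."""

    data: np.ndarray
    fov_mm: float
    res_mm: float
    frame_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frame_roles:
            self.frame_roles = [ROLE_ACQUIRED] * self.data.shape[0]
        if len(self.frame_roles) != self.data.shape[0]:
            raise ValueError("frame_roles length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def acquired_only(self) -> "ImageSeries":
        """Drop prepended/appended frames, keeping the acquired ones."""
        keep = [i for i, r in enumerate(self.frame_roles) if r == ROLE_ACQUIRED]
        return ImageSeries(
            data=self.data[keep],
            fov_mm=self.fov_mm,
            res_mm=self.res_mm,
            frame_roles=[ROLE_ACQUIRED] * len(keep),
        )


@dataclass
class KSpaceSeries:
    """Multi-coil spiral k-space: frames x coils x samples complex data.

    ``frame_signs`` is +1 for measured frames and -1 for the prepended
    pseudo-frames whose data were sign-inverted during periodic padding.
    """

    data: np.ndarray
    schedule: TISchedule
    traj: Trajectory
    frame_signs: np.ndarray | None = None
    frame_roles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_signs is None:
            self.frame_signs = np.ones(self.data.shape[0], dtype=int)
        if not self.frame_roles:
            padded = self.data.shape[0] == self.schedule.n_padded
            self.frame_roles = default_frame_roles(self.schedule, padded)[
                : self.data.shape[0]
            ]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]
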