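"""Shared fixtures.

The expensive session fixture runs the scaled-down study once: a 96 x 96
matrix (FOV 180 mm), 55-frame single-arm golden-angle acquisition with
1360 samples per arm — chosen to preserve the full protocol's per-frame
effective acceleration (pi * 48^2 / 1360 = 5.3, equal to
pi * 90^2 / 4800 at the 180 x 180 protocol matrix) — 4 coils, 2% complex
Gaussian k-space noise, and three vessels with venous-blood T1 values
1650, 1850 and 2000 ms.  Both the padded 59-frame and the unpadded
50-frame reconstructions of the identical data are produced.
"""

from __future__ import annotations

import numpy as np
import pytest

from spiralt1.analysis import fit_ir_t1, segment_fwhm
from spiralt1.phantom import (
    AcqParams,
    make_coil_maps,
    make_phantom,
    simulate_ir_series,
    simulate_kspace,
)
from spiralt1.recon import align_global_phase, pad_frames, solve_ktsparse
from spiralt1.series import KSpaceSeries, TISchedule
from spiralt1.trajectory import design_vd_spiral, golden_angle_schedule

STUDY_SEED = 7
STUDY_MATRIX = 96
STUDY_FOV_MM = 180.0
STUDY_N_SAMPLES = 1360
STUDY_VESSELS = [
    ((-20.0, -30.0), 4.0, 1650.0),
    ((-20.0, 30.0), 4.0, 1850.0),
    ((25.0, 0.0), 4.0, 2000.0),
]


def run_study(seed: int = STUDY_SEED, with_unpadded: bool = True) -> dict:
    """Simulate and reconstruct the scaled-down single-shot experiment."""
    n = STUDY_MATRIX
    res = STUDY_FOV_MM / n
    sch = TISchedule()
    phantom = make_phantom((n, n), STUDY_FOV_MM, STUDY_VESSELS)
    acq = AcqParams(seed=seed)
    truth = simulate_ir_series(phantom, sch, acq)
    coils = make_coil_maps((n, n), 4)
    traj = design_vd_spiral(
        STUDY_FOV_MM,
        res,
        n_samples=STUDY_N_SAMPLES,
        schedule=golden_angle_schedule(sch.n_measured),
    )
    kspace = simulate_kspace(truth, coils, traj, acq, schedule=sch)

    rec59 = align_global_phase(solve_ktsparse(pad_frames(kspace), coils))
    out = {
        "schedule": sch,
        "phantom": phantom,
        "truth": truth,
        "coils": coils,
        "traj": traj,
        "kspace": kspace,
        "recon59": rec59,
        "meas59": rec59.data[sch.n_prepended :],
        "res_mm": res,
    }
    if with_unpadded:
        sch50 = TISchedule(n_appended=0, n_prepended=0)
        ks50 = KSpaceSeries(
            data=kspace.data[: sch50.n_acquired],
            schedule=sch50,
            traj=traj.frame_subset(np.arange(sch50.n_acquired)),
        )
        rec50 = align_global_phase(solve_ktsparse(ks50, coils))
        out["recon50"] = rec50
        out["meas50"] = rec50.data
    return out


def study_seed_pixels() -> list[tuple[int, int]]:
    n = STUDY_MATRIX
    res = STUDY_FOV_MM / n
    return [
        (int(round(cy / res)) + n // 2, int(round(cx / res)) + n // 2)
        for (cy, cx), _r, _t1 in STUDY_VESSELS
    ]


def fit_study_vessels(meas: np.ndarray, sch: TISchedule) -> list:
    """Segment each vessel on the last acquired frame and fit T1."""
    tis = sch.acquired_ti_ms
    fits = []
    for seed in study_seed_pixels():
        roi = segment_fwhm(np.abs(meas[sch.n_acquired - 1]), seed)
        sig = np.array([f[roi.mask].mean() for f in meas[: sch.n_acquired].real])
        fits.append(fit_ir_t1(sig, tis))
    return fits


@pytest.fixture(scope="session")
def gassp_study() -> dict:
    return run_study()
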