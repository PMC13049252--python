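# spiralt1

Ultrafast measurement of flowing-blood T1 from a **single-shot golden-angle
spiral Look–Locker acquisition**, implemented end to end on a synthetic
inflow phantom: trajectory design, k-t sparse SENSE reconstruction with
temporal total-variation regularization and sign-inverted periodic frame
padding, and downstream vessel segmentation + inversion-recovery fitting.

## The problem

Blood T1 enters directly into cerebral blood flow and blood volume
quantification and into the arterial input function of contrast-enhanced
MRI, and it varies between individuals (hematocrit, oxygenation,
gadolinium concentration). A fast way to measure it in vivo exploits
inflow: after a non-selective adiabatic inversion, a slice through the
neck is excited by a 90° pulse every ΔTI = 200 ms. Blood flowing into the
slice (internal jugular vein / carotid) is always "fresh" — it carries the
full inversion-recovery curve

    M(TI) = M0 + (Minit − M0) · e^(−TI/T1),   Minit ≈ −M0,

sampled at TI = 50, 250, …, while static tissue, saturated by every
excitation (and pre-saturated by a WET pulse train before the inversion),
sits at a constant plateau M0·(1 − e^(−ΔTI/T1)). Fitting the three
parameters (T1, M0, Minit) to the vessel signal yields blood T1 in ~10 s
of scanning — if each TI frame can be imaged from a *single spiral arm*.

That is the reconstruction problem this package solves:

    I = argmin_I ‖k − S F I‖₂² + λ‖TV_TI(I)‖₁ ,  λ = 0.1,

where F is the non-uniform Fourier transform of one variable-density
spiral arm per frame (central 15% of k-space fully sampled, outer 50%
undersampled 5×, linear ramp between), rotated by the golden angle
(137.51°) between frames; S are coil sensitivities; TV_TI is the temporal
total-variation transform, kept sparse by the constant background. Because
the 55th frame's rotation folds to 134.46° ≈ the golden angle, the series
is nearly periodic: the last four frames are prepended *with inverted
k-space sign* (their magnetization is near +M0, the pre-inversion state is
−M0 away), giving 59 frames and suppressing the temporal-TV boundary
artifacts that otherwise bias the first and last TIs.

## Worked example

Run the full synthetic experiment — phantom, one golden-angle spiral arm
per TI, noise, padded reconstruction, segmentation, fitting — at a small
matrix:

```python
from spiralt1 import PipelineConfig, run_pipeline
from spiralt1.pipeline import VesselSpec

cfg = PipelineConfig(
    res_mm=180 / 48, n_samples=340,
    n_acquired=30, n_appended=5, n_prepended=4,
    vessels=[VesselSpec((0, -25), 8.0, 1650.0),
             VesselSpec((0, 25), 8.0, 1850.0)],
    n_coils=4, max_iters=40, register=False, seed=3,
)
result = run_pipeline(cfg, out_dir="out")
for v in result.report["vessels"]:
    print(f"{v['label']}: T1 fit {v['t1_fit_ms']:.1f} ms "
          f"(true {v['t1_true_ms']:.0f} ms, err {v['t1_error_percent']:+.2f}%, "
          f"R^2 {v['r_squared']:.4f})")
```

prints

```
vessel_1: T1 fit 1655.8 ms (true 1650 ms, err +0.35%, R^2 0.9999)
vessel_2: T1 fit 1872.3 ms (true 1850 ms, err +1.20%, R^2 0.9999)
```

i.e. both vessels' blood T1 is recovered within ~1% from a single-arm-per-
frame acquisition, and `out/` holds the k-space container (HDF5), the
reconstructed series (NIfTI, magnitude + signed-real), the per-vessel fit
table (CSV) and a JSON report with the objective trace.

The same stages are available as subcommands of the `spiralt1` CLI
(`simulate`, `recon`, `deblur`, `fit`, `compare`, `bloch`, `pipeline`).
For instance the preparation-pulse physics:

```
$ spiralt1 bloch --t1 1650
HS inversion efficiency (-Mz/M0, on-res, nominal B1): 0.9996
WET residual Mz/M0 (instantaneous, closed form):      3.112e-04
WET residual Mz/M0 (Bloch, T1 = 1650 ms):          -1.112e-03
```

The adiabatic hyperbolic-secant inversion (13.3 ms, 13.5 µT, 1202 Hz)
inverts blood essentially completely, and the WET train (89°, 98°, 82°,
157°) leaves ≲0.1% longitudinal magnetization — the two assumptions behind
Minit = −M0 and the flat background plateau.

The T1 fit itself follows the statsmodels convention — a model object fit
to data returning a results object:

```python
from spiralt1 import InversionRecoveryModel
res = InversionRecoveryModel(signal, ti_ms).fit()
print(res.summary())   # T1 ± 95% CI, M0, Minit, R², exclusion flag
```

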