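"""Registration, segmentation, T1 fitting, exclusion, method comparison."""

import numpy as np
import pytest
from scipy import ndimage

from spiralt1.analysis import (
    InversionRecoveryModel,
    T1FitResults,
    compare_methods,
    exclude_low_confidence,
    fit_ir_t1,
    register_frames,
    segment_fwhm,
)
from spiralt1.series import ImageSeries, TISchedule


def ir_signal(ti_ms, t1=1700.0, m0=1.0, minit=-1.0):
    return m0 + (minit - m0) * np.exp(-np.asarray(ti_ms) / t1)


def anatomy_frame(n=64):
    """Asymmetric two-blob pattern with identifiable rotation."""
    y, x = np.indices((n, n)) - n // 2
    img = (
        1.0 * np.exp(-((y - 4) ** 2 + (x + 6) ** 2) / 18.0)
        + 0.7 * np.exp(-((y + 5) ** 2 + (x - 3) ** 2) / 8.0)
        + 0.1
    )
    return img


class TestRegistration:
    def _series(self, frames):
        return ImageSeries(
            data=np.asarray(frames, dtype=complex), fov_mm=64.0, res_mm=1.0
        )

    def test_motion_free_series_gives_identity(self):
        base = anatomy_frame()
        rng = np.random.default_rng(0)
        frames = [base * s + rng.normal(0, 0.002, base.shape) for s in (1.0, 0.8, 1.2)]
        transforms, _ = register_frames(self._series(frames), (32, 32))
        assert np.abs(transforms[:, :2]).max() < 0.05
        assert np.abs(transforms[:, 2]).max() < 0.05

    def test_translation_recovered(self):
        base = anatomy_frame()
        moved = ndimage.shift(base, (2.0, 0.0), order=1)
        transforms, aligned = register_frames(self._series([base, moved]), (32, 32))
        # recovered translation cancels the injected 2-px row shift
        assert abs(abs(transforms[1, 1]) - 2.0) < 0.2
        resid = np.abs(aligned.data[1].real - base)[22:42, 22:42]
        assert resid.mean() < 0.02

    def test_rotation_recovered(self):
        base = anatomy_frame()
        moved = ndimage.rotate(base, 2.0, reshape=False, order=1)
        transforms, _ = register_frames(self._series([base, moved]), (32, 32))
        assert abs(abs(transforms[1, 2]) - 2.0) < 0.3

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValueError):
            register_frames(self._series([anatomy_frame()] * 2), (2, 2))

    def test_noop_on_motion_free_reconstruction(self, gassp_study):
        # registration + segmentation + fitting equals fitting raw means
        from conftest import study_seed_pixels

        sch = gassp_study["schedule"]
        meas = gassp_study["meas59"]
        seeds = study_seed_pixels()
        series = ImageSeries(
            data=meas.copy(), fov_mm=180.0, res_mm=gassp_study["res_mm"]
        )
        _, registered = register_frames(series, seeds[0])
        tis = sch.acquired_ti_ms
        roi = segment_fwhm(np.abs(meas[sch.n_acquired - 1]), seeds[1])
        sig_raw = np.array([f[roi.mask].mean() for f in meas[: sch.n_acquired].real])
        roi_r = segment_fwhm(
            np.abs(registered.data[sch.n_acquired - 1]), seeds[1]
        )
        sig_reg = np.array(
            [f[roi_r.mask].mean() for f in registered.data[: sch.n_acquired].real]
        )
        t_raw = fit_ir_t1(sig_raw, tis).t1_ms
        t_reg = fit_ir_t1(sig_reg, tis).t1_ms
        assert t_reg == pytest.approx(t_raw, rel=1e-6)


class TestSegmentation:
    def test_uniform_disk_segmented_exactly(self):
        n = 48
        y, x = np.indices((n, n)) - n // 2
        disk = (y**2 + x**2 <= 64).astype(float)
        roi = segment_fwhm(disk, (n // 2, n // 2))
        assert np.array_equal(roi.mask, disk.astype(bool))

    def test_gaussian_blob_radius_matches_level_set(self):
        # threshold 0.7 of the peak cuts a Gaussian at r = sigma*sqrt(2 ln(1/0.7))
        n, sigma = 64, 5.0
        y, x = np.indices((n, n)) - n // 2
        blob = np.exp(-(y**2 + x**2) / (2 * sigma**2))
        roi = segment_fwhm(blob, (n // 2, n // 2))
        r_eff = np.sqrt(roi.n_pixels / np.pi)
        expected = sigma * np.sqrt(2.0 * np.log(1.0 / 0.7))
        assert abs(r_eff - expected) < 1.0

    def test_threshold_recorded_in_roi(self):
        img = np.ones((8, 8))
        roi = segment_fwhm(img, (4, 4), threshold=0.7)
        assert roi.fwhm_threshold == 0.7

    def test_zero_intensity_seed_rejected(self):
        img = np.zeros((8, 8))
        img[1, 1] = 1.0
        with pytest.raises(ValueError):
            segment_fwhm(img, (4, 4))

    def test_mask_is_connected_and_contains_seed(self):
        # two bright blobs: only the seeded one is segmented
        n = 48
        y, x = np.indices((n, n)) - n // 2
        img = np.exp(-((y - 10) ** 2 + x**2) / 20.0) + np.exp(
            -((y + 10) ** 2 + x**2) / 20.0
        )
        roi = segment_fwhm(img, (n // 2 + 10, n // 2))
        assert roi.mask[n // 2 + 10, n // 2]
        assert not roi.mask[n // 2 - 10, n // 2]


class TestInversionRecoveryFit:
    SCH = TISchedule()

    def test_noiseless_closure(self):
        tis = self.SCH.acquired_ti_ms
        fit = fit_ir_t1(ir_signal(tis), tis)
        assert fit.t1_ms == pytest.approx(1700.0, rel=1e-3)
        assert fit.m0 == pytest.approx(1.0, abs=1e-6)
        assert fit.minit == pytest.approx(-1.0, abs=1e-6)
        assert fit.r_squared > 0.999999

    def test_zero_crossing_at_t1_ln2(self):
        tis = self.SCH.acquired_ti_ms
        fit = fit_ir_t1(ir_signal(tis), tis)
        assert fit.zero_crossing_ms == pytest.approx(1700.0 * np.log(2.0), rel=1e-3)
        assert fit.zero_crossing_ms == pytest.approx(1178.3, abs=1.0)

    def test_agrees_with_grid_search_oracle_on_noisy_data(self):
        # brute-force 1 ms grid over T1 with the linear (M0, Minit)
        # subproblem solved exactly per candidate
        tis = self.SCH.acquired_ti_ms
        rng = np.random.default_rng(6)
        sig = ir_signal(tis) + rng.normal(0, 0.02, tis.size)
        fit = fit_ir_t1(sig, tis)
        t1_grid = np.arange(1500.0, 1900.0, 1.0)
        best_t1, best_sse = None, np.inf
        for t1 in t1_grid:
            e = np.exp(-tis / t1)
            design = np.stack([1.0 - e, e], axis=1)  # [M0, Minit]
            coef, res, *_ = np.linalg.lstsq(design, sig, rcond=None)
            sse = float(res[0]) if res.size else float(
                np.sum((design @ coef - sig) ** 2)
            )
            if sse < best_sse:
                best_t1, best_sse = t1, sse
        assert abs(fit.t1_ms - best_t1) <= 2.0

    def test_scale_invariance(self):
        tis = self.SCH.acquired_ti_ms
        rng = np.random.default_rng(7)
        sig = ir_signal(tis) + rng.normal(0, 0.01, tis.size)
        t_a = fit_ir_t1(sig, tis).t1_ms
        t_b = fit_ir_t1(1e4 * sig, tis).t1_ms
        assert t_b == pytest.approx(t_a, rel=1e-9)

    def test_magnitude_mode_restores_polarity(self):
        tis = self.SCH.acquired_ti_ms
        fit = fit_ir_t1(np.abs(ir_signal(tis)), tis, magnitude=True)
        assert fit.t1_ms == pytest.approx(1700.0, rel=1e-3)
        assert fit.minit == pytest.approx(-1.0, abs=1e-3)

    def test_summary_table_contains_estimates(self):
        tis = self.SCH.acquired_ti_ms
        res = InversionRecoveryModel(ir_signal(tis), tis).fit()
        text = res.summary()
        assert "T1" in text and "R^2" in text and "excluded" in text

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ir_t1(np.array([1.0, 2.0, 3.0]), np.array([50.0, 250.0, 450.0]))


class TestExclusionRule:
    def _fit(self, half):
        return T1FitResults(
            t1_ms=1700.0, m0=1.0, minit=-1.0, r_squared=0.999,
            ci95_halfwidth_ms=half,
        )

    def test_wide_interval_excluded(self):
        assert self._fit(60.0).excluded  # width 120 ms >= 100 ms

    def test_narrow_interval_retained(self):
        assert not self._fit(49.5).excluded  # width 99 ms < 100 ms

    def test_report_counts_15_retained_3_excluded(self):
        fits = [self._fit(20.0) for _ in range(15)] + [self._fit(80.0)] * 3
        retained, report = exclude_low_confidence(fits)
        assert len(retained) == 15
        assert report["n_retained"] == 15
        assert report["n_excluded"] == 3
        assert report["n_total"] == 18


class TestRepeatability:
    def test_two_noise_realizations_agree(self):
        # two independent noise draws of a six-vessel phantom, each
        # reconstructed and fitted: paired T1s correlate strongly with
        # negligible bias (synthetic analogue of an intra-scan repeat)
        from spiralt1.phantom import (
            AcqParams, make_coil_maps, make_phantom, simulate_ir_series,
            simulate_kspace,
        )
        from spiralt1.recon import align_global_phase, pad_frames, solve_ktsparse
        from spiralt1.trajectory import design_vd_spiral, golden_angle_schedule

        n, fov = 64, 180.0
        res = fov / n
        sch = TISchedule()
        t1s = [1550.0, 1650.0, 1750.0, 1850.0, 1950.0, 2050.0]
        ring = 28.0
        vessels = [
            (
                (ring * np.sin(2 * np.pi * i / 6), ring * np.cos(2 * np.pi * i / 6)),
                6.0,
                t1,
            )
            for i, t1 in enumerate(t1s)
        ]
        phantom = make_phantom((n, n), fov, vessels)
        truth_seeds = [
            (int(round(cy / res)) + n // 2, int(round(cx / res)) + n // 2)
            for (cy, cx), _r, _t in vessels
        ]
        coils = make_coil_maps((n, n), 4)
        traj = design_vd_spiral(
            fov, res, n_samples=610, schedule=golden_angle_schedule(sch.n_measured)
        )
        runs = []
        for seed in (101, 202):
            acq = AcqParams(seed=seed)
            truth = simulate_ir_series(phantom, sch, acq)
            ks = simulate_kspace(truth, coils, traj, acq, schedule=sch)
            rec = align_global_phase(solve_ktsparse(pad_frames(ks), coils))
            meas = rec.data[sch.n_prepended :]
            t1_fit = []
            for seed_px in truth_seeds:
                roi = segment_fwhm(np.abs(meas[sch.n_acquired - 1]), seed_px)
                sig = np.array(
                    [f[roi.mask].mean() for f in meas[: sch.n_acquired].real]
                )
                t1_fit.append(fit_ir_t1(sig, sch.acquired_ti_ms).t1_ms)
            runs.append(np.array(t1_fit))
        stats = compare_methods(runs[0], runs[1])
        assert stats.pearson_r >= 0.9
        assert abs(stats.bias_percent) <= 3.0


class TestMethodComparison:
    def test_identical_lists(self):
        stats = compare_methods([1700.0, 1800.0, 1900.0], [1700.0, 1800.0, 1900.0])
        assert stats.pearson_r == pytest.approx(1.0)
        assert stats.bias_percent == pytest.approx(0.0)
        assert stats.loa_percent == pytest.approx((0.0, 0.0))

    def test_collinear_lists(self):
        stats = compare_methods([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert stats.pearson_r == pytest.approx(1.0)
        assert stats.slope == pytest.approx(2.0)

    def test_pearson_matches_textbook_formula(self):
        a = np.array([1700.0, 1800.0, 1900.0, 2000.0])
        b = np.array([1750.0, 1790.0, 1920.0, 1980.0])
        stats = compare_methods(a, b)
        da, db = a - a.mean(), b - b.mean()
        r_hand = np.sum(da * db) / np.sqrt(np.sum(da**2) * np.sum(db**2))
        assert stats.pearson_r == pytest.approx(r_hand, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_plot_helpers_render(self):
        import matplotlib

        matplotlib.use("Agg")
        from spiralt1.plotting import plot_bland_altman, plot_fit_curve

        tis = TISchedule().acquired_ti_ms
        sig = ir_signal(tis)
        ax = plot_fit_curve(fit_ir_t1(sig, tis), sig, tis)
        assert ax.get_xlabel() == "TI (ms)"
        ax2 = plot_bland_altman(
            [1700.0, 1800.0, 1900.0, 2000.0], [1710.0, 1790.0, 1910.0, 1985.0]
        )
        assert ax2.get_ylabel() == "difference (%)"
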