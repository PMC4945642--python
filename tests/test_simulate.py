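import numpy as np
import pytest
from scipy import stats

from hrfboost.design import build_design
from hrfboost.first_level import fit_ols
from hrfboost.simulate import (
    CohortSpec,
    VoxelSimSpec,
    periodic_event_timeline,
    simulate_cohort,
    simulate_smooth_field,
    simulate_voxel_series,
)


class TestPeriodicTimeline:
    def test_default_rate_is_point_05_hz(self):
        tl = periodic_event_timeline()
        periods = np.diff(tl.onsets)
        assert np.allclose(periods, 20.0)
        assert 1.0 / periods[0] == pytest.approx(0.05)

    def test_events_alternate_with_equal_rests(self):
        tl = periodic_event_timeline()
        gaps = tl.onsets[1:] - (tl.onsets[:-1] + tl.durations[:-1])
        assert np.allclose(tl.durations, 10.0)
        assert np.allclose(gaps, 10.0)


class TestVoxelSimulation:
    def test_zero_shift_noiseless_perfect_fit(self, params):
        spec = VoxelSimSpec(shift=0.0, amplitude=2.5, noise_sd=0.0)
        y, truth = simulate_voxel_series(spec)
        X = build_design(spec.events, spec.tr, spec.n_scans, params, basis="canonical")
        fit = fit_ols(y, X)
        assert fit.r_squared[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.beta("task_canonical")[0] == pytest.approx(2.5, abs=1e-8)
        assert truth["shift"] == 0.0

    def test_shifted_fit_degrades_then_derivative_restores(self, params):
        spec0 = VoxelSimSpec(shift=0.0)
        spec2 = VoxelSimSpec(shift=2.0)
        y0, _ = simulate_voxel_series(spec0)
        y2, _ = simulate_voxel_series(spec2)
        Xc = build_design(spec0.events, spec0.tr, spec0.n_scans, params, basis="canonical")
        Xi = build_design(spec0.events, spec0.tr, spec0.n_scans, params, basis="informed")
        r2_can_0 = fit_ols(y0, Xc).r_squared[0]
        r2_can_2 = fit_ols(y2, Xc).r_squared[0]
        r2_inf_2 = fit_ols(y2, Xi).r_squared[0]
        assert r2_can_2 < r2_can_0
        assert abs(r2_inf_2 - r2_can_0) < 0.02

    def test_seeded_reproducibility(self):
        spec = VoxelSimSpec(shift=1.0, noise_sd=0.8, seed=42)
        y1, _ = simulate_voxel_series(spec)
        y2, _ = simulate_voxel_series(spec)
        np.testing.assert_array_equal(y1, y2)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            VoxelSimSpec(noise_sd=-1.0)
        with pytest.raises(ValueError):
            VoxelSimSpec(shift=5.0)


class TestCohortSimulation:
    def test_degenerate_latency_gives_exact_time_to_peak(self, params):
        from hrfboost.boost import time_to_peak

        spec = CohortSpec(
            n_subjects=3,
            volume_shape=(4, 4, 2),
            active_mask=np.ones((4, 4, 2), dtype=bool),
            latency_mean=0.5,
            latency_sd=0.0,
            amplitude_sd=0.0,
            noise_sd=0.0,
            smoothing_fwhm=0.0,
            n_scans=60,
        )
        cohort = simulate_cohort(spec)
        X = build_design(spec.events, spec.tr, spec.n_scans, params, basis="informed")
        for vol in cohort.data:
            fit = fit_ols(vol, X, mask=spec.active_mask)
            ttp = time_to_peak(fit.beta("task_canonical"), fit.beta("task_derivative"))
            assert np.all(np.abs(ttp - (5.0 + 0.5)) <= params.microtime_dt + 1e-6)

    def test_truth_table_and_determinism(self):
        spec = CohortSpec(n_subjects=4, volume_shape=(4, 4, 2), n_scans=40, seed=9)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        assert list(a.truth.columns) == ["subject", "latency_s", "amplitude"]
        assert len(a.truth) == 4
        np.testing.assert_array_equal(a.data[2], b.data[2])
        np.testing.assert_array_equal(a.truth.latency_s.values, b.truth.latency_s.values)
        assert np.all(np.abs(a.truth.latency_s.values) <= 2.0)

    def test_empty_active_mask_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(volume_shape=(4, 4, 2), active_mask=np.zeros((4, 4, 2), dtype=bool))

    def test_group_mean_matches_attenuation_oracle(self, params):
        # theory: canonical-regressor coefficient of a latency-shifted response,
        # averaged over the truncated latency distribution
        from hrfboost.design import boxcar, convolve_to_scans
        from hrfboost.hrf import canonical_hrf, shifted_hrf

        tr, n_scans = 2.0, 40
        tl = periodic_event_timeline(4)
        u = boxcar(tl, params.microtime_dt, n_scans * tr + params.kernel_length)
        x1 = convolve_to_scans(u, canonical_hrf(params), tr, n_scans)
        pinv = np.linalg.pinv(np.column_stack([x1, np.ones(n_scans)]))
        deltas = np.arange(-2.0, 2.001, 0.05)
        coefs = np.array(
            [(pinv @ convolve_to_scans(u, shifted_hrf(params, d), tr, n_scans))[0] for d in deltas]
        )
        lat_sd = 0.5
        pdf = stats.truncnorm.pdf(deltas, -2.0 / lat_sd, 2.0 / lat_sd, scale=lat_sd)
        theory = np.trapezoid(coefs * pdf, deltas) / np.trapezoid(pdf, deltas)

        X = build_design(tl, tr, n_scans, params, basis="canonical")
        w = X.contrast_for({"task": 1.0})
        shape = (3, 3, 2)
        means = []
        for rep in range(200):
            spec = CohortSpec(
                n_subjects=20,
                volume_shape=shape,
                active_mask=np.ones(shape, dtype=bool),
                latency_sd=lat_sd,
                amplitude_mean=1.0,
                amplitude_sd=0.1,
                noise_sd=0.5,
                smoothing_fwhm=0.0,
                seed=rep,
                tr=tr,
                n_scans=n_scans,
            )
            cohort = simulate_cohort(spec)
            subject_means = [
                float(np.mean(w @ fit_ols(v, X, mask=spec.active_mask).betas)) for v in cohort.data
            ]
            means.append(np.mean(subject_means))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - theory) < 3.0 * se + 1e-3

    def test_inactive_voxel_false_positive_rate(self, params):
        # Monte-Carlo null calibration of the one-sample t over cohort pipelines
        from hrfboost.first_level import contrast_image
        from hrfboost.group import one_sample_t

        tr, n_scans = 2.0, 60
        shape = (20, 20, 10)
        active = np.zeros(shape, dtype=bool)
        active[0, 0, 0] = True  # minimal active region; evaluate the rest as null
        null_mask = ~active
        X = build_design(periodic_event_timeline(5), tr, n_scans, params, basis="canonical")
        w = X.contrast_for({"task": 1.0})
        n_subjects = 8
        rejections = 0
        total = 0
        for rep in range(26):
            spec = CohortSpec(
                n_subjects=n_subjects,
                volume_shape=shape,
                active_mask=active,
                amplitude_mean=0.0,
                amplitude_sd=0.0,
                noise_sd=1.0,
                smoothing_fwhm=0.0,
                seed=rep,
                tr=tr,
                n_scans=n_scans,
            )
            cohort = simulate_cohort(spec)
            images = np.asarray(
                [contrast_image(fit_ols(v, X, mask=null_mask), w).values for v in cohort.data]
            )
            group = one_sample_t(images)
            crit = stats.t.isf(0.001, group.df)
            rejections += int(np.sum(group.t_values > crit))
            total += group.t_values.size
        assert total >= 1e5
        p = 0.001
        half = 2.576 * np.sqrt(p * (1 - p) / total)
        assert abs(rejections / total - p) < half


class TestSmoothField:
    def test_white_noise_uncorrelated(self):
        f = simulate_smooth_field((40, 40, 40), fwhm=0.0, seed=3)
        a, b = f[:-1].ravel(), f[1:].ravel()
        rho = np.corrcoef(a, b)[0, 1]
        assert abs(rho) < 3.0 / np.sqrt(a.size)

    def test_unit_variance(self):
        f = simulate_smooth_field((64, 64, 64), voxel_size=3.0, fwhm=8.0, seed=5)
        assert abs(f.var() - 1.0) < 0.02

    def test_lag1_autocorrelation_matches_closed_form(self):
        # ACF of a Gaussian-smoothed white field: rho(d) = exp(-2 ln2 d^2 / fwhm^2)
        fwhm, vox = 8.0, 3.0
        rhos = []
        for seed in range(5):
            f = simulate_smooth_field((64, 64, 64), voxel_size=vox, fwhm=fwhm, seed=seed)
            a, b = f[:-1].ravel(), f[1:].ravel()
            rhos.append(np.corrcoef(a, b)[0, 1])
        expected = np.exp(-2.0 * np.log(2.0) * vox**2 / fwhm**2)
        assert abs(np.mean(rhos) - expected) < 0.02

    def test_seeded_determinism(self):
        a = simulate_smooth_field((16, 16, 16), fwhm=4.0, seed=11)
        b = simulate_smooth_field((16, 16, 16), fwhm=4.0, seed=11)
        np.testing.assert_array_equal(a, b)


class TestCohortIO:
    def test_write_outputs(self, tmp_path):
        import nibabel as nib

        spec = CohortSpec(n_subjects=2, volume_shape=(4, 4, 2), n_scans=30)
        cohort = simulate_cohort(spec)
        out = tmp_path / "cohort"
        cohort.write(out)
        img = nib.load(out / "sub-01_bold.nii")
        assert img.shape == (4, 4, 2, 30)
        assert (out / "truth.tsv").exists()
        assert (out / "cohort_spec.json").exists()
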