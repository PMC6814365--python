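"""Synthetic-data generator: IRF, histograms, scenes, cubes, series."""

import numpy as np
import pytest

from vflim.decay import weighted_mean_lifetime
from vflim.fitting import FitConfig, fit_decay
from vflim.synthetic import (
    GeneratorConfig,
    ResponseProfile,
    amplitude_fraction_for_mean,
    expected_histogram,
    frame_schedule,
    make_irf,
    make_scene,
    render_flim_cube,
    render_ratio_pair,
    render_timeseries,
    simulate_decay_histogram,
)

BIEXP = [(0.59, 0.9), (0.41, 2.6)]


class TestMakeIrf:
    def test_normalization_and_peak_placement(self, axis):
        irf = make_irf(axis, center=1.0, fwhm=0.2)
        assert irf.values.sum() == pytest.approx(1.0)
        assert irf.peak_bin == round(1.0 / axis.bin_width)  # bin 20

    def test_narrow_fwhm_degenerates_to_delta(self, axis):
        irf = make_irf(axis, center=1.0, fwhm=1e-9)
        assert np.count_nonzero(irf.values > 1e-12) == 1
        assert irf.peak_bin == round(1.0 / axis.bin_width)

    def test_second_moment_matches_gaussian_sigma(self, axis):
        fwhm = 0.3
        irf = make_irf(axis, center=1.0, fwhm=fwhm)
        t = axis.times() + axis.bin_width / 2
        mean = (irf.values * t).sum()
        var = (irf.values * (t - mean) ** 2).sum()
        sigma2 = (fwhm / 2.355) ** 2
        assert var == pytest.approx(sigma2, rel=0.02)

    def test_unimodal(self, axis):
        irf = make_irf(axis, center=2.0, fwhm=0.5)
        peak = irf.peak_bin
        assert np.all(np.diff(irf.values[: peak + 1]) >= -1e-15)
        assert np.all(np.diff(irf.values[peak:]) <= 1e-15)

    def test_invalid_parameters_rejected(self, axis):
        with pytest.raises(ValueError):
            make_irf(axis, center=-1.0)
        with pytest.raises(ValueError):
            make_irf(axis, center=1.0, fwhm=7.0)  # >= period/2


class TestSimulateDecayHistogram:
    def test_expectation_converges_to_analytic_model(self, axis, gauss_irf):
        # mean of many Poisson draws must approach the analytic curve
        n_rep, photons = 1000, 2e4
        mu = expected_histogram(axis, BIEXP, gauss_irf, photons)
        rng = np.random.default_rng(7)
        total = np.zeros(axis.n_bins)
        for _ in range(n_rep):
            total += rng.poisson(mu)
        mean = total / n_rep
        se = np.sqrt(mu / n_rep)
        assert np.all(np.abs(mean - mu) <= 3 * np.maximum(se, 1e-9) + 1e-9)

    def test_ground_truth_mean_lifetime(self):
        assert weighted_mean_lifetime(BIEXP) == pytest.approx(1.597)

    def test_zero_photons_gives_dark_or_empty(self, axis, gauss_irf):
        dark = simulate_decay_histogram(axis, BIEXP, gauss_irf, 0, dark_rate=5.0, seed=1)
        assert dark.sum() > 0
        empty = simulate_decay_histogram(axis, BIEXP, gauss_irf, 0, dark_rate=0.0, seed=1)
        assert empty.sum() == 0

    def test_reproducible_given_seed(self, axis, gauss_irf):
        a = simulate_decay_histogram(axis, BIEXP, gauss_irf, 1e4, seed=42)
        b = simulate_decay_histogram(axis, BIEXP, gauss_irf, 1e4, seed=42)
        assert np.array_equal(a, b)

    def test_invalid_inputs_rejected(self, axis, gauss_irf):
        with pytest.raises(ValueError):
            simulate_decay_histogram(axis, BIEXP, gauss_irf, -1)
        with pytest.raises(ValueError):
            simulate_decay_histogram(axis, [(0.5, 0.9)], gauss_irf, 100)


class TestAmplitudeRule:
    def test_round_trip_through_mean_lifetime(self):
        for target in (1.0, 1.597, 2.2):
            f = amplitude_fraction_for_mean(target, 0.9, 2.6)
            assert weighted_mean_lifetime([(f, 0.9), (1 - f, 2.6)]) == pytest.approx(target)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            amplitude_fraction_for_mean(3.0, 0.9, 2.6)


class TestMakeScene:
    def test_disjoint_cells_get_distinct_groups(self):
        cfg = GeneratorConfig(shape=(64, 64), n_cells=2, radius_range=(6, 8))
        # search a few seeds for a disjoint placement, then assert exactness
        for seed in range(20):
            scene = make_scene(cfg, seed=seed)
            if scene.label_map.max() == 2:
                break
        assert scene.label_map.max() == 2
        assert set(scene.vmem_truth) == {1, 2}

    def test_determinism(self):
        cfg = GeneratorConfig(n_cells=5, n_debris=3)
        a = make_scene(cfg, seed=11)
        b = make_scene(cfg, seed=11)
        assert np.array_equal(a.label_map, b.label_map)
        assert a.vmem_truth == b.vmem_truth
        assert np.array_equal(a.intensity_map, b.intensity_map)

    def test_membranes_are_hollow_annuli(self):
        cfg = GeneratorConfig(shape=(64, 64), n_cells=1, radius_range=(10, 10))
        scene = make_scene(cfg, seed=3)
        n_membrane = (scene.label_map > 0).sum()
        # a filled disk of r=10 has ~314 px; a 2-px ring only ~120
        assert 0 < n_membrane < 200

    def test_oversized_cells_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(shape=(16, 16), radius_range=(6, 10))


class TestRenderFlimCube:
    def test_truth_lifetime_follows_calibration(self):
        cfg = GeneratorConfig(shape=(48, 48), n_cells=2, radius_range=(6, 8))
        scene = make_scene(cfg, seed=1)
        scene.vmem_truth = {g: 0.0 for g in scene.vmem_truth}
        cube = render_flim_cube(scene, seed=1, noise=False)
        taus = cube.truth["tau_m_ns"][scene.label_map > 0]
        assert np.allclose(taus, 1.770)  # b = 1770 ps at 0 mV

        scene.vmem_truth = {g: -60.0 for g in scene.vmem_truth}
        cube = render_flim_cube(scene, seed=1, noise=False)
        taus = cube.truth["tau_m_ns"][scene.label_map > 0]
        assert np.allclose(taus, 1.560)  # 1770 - 60 * 3.50 ps

    def test_noiseless_pixel_fit_recovers_truth_within_1ps(self, axis):
        cfg = GeneratorConfig(shape=(48, 48), n_cells=1, radius_range=(8, 8),
                              photons_per_pixel=1e6)
        scene = make_scene(cfg, seed=5)
        cube = render_flim_cube(scene, axis, noise=False)
        irf = make_irf(axis, cfg.irf_center, cfg.irf_fwhm)
        y, x = np.argwhere(scene.label_map > 0)[0]
        summary = fit_decay(cube.counts[y, x], irf, axis,
                            FitConfig(n_components=2, shift=cfg.irf_shift))
        truth = cube.truth["tau_m_ns"][y, x]
        assert abs(summary.tau_m - truth) < 1e-3  # < 1 ps

    def test_background_carries_only_dark_counts(self):
        cfg = GeneratorConfig(shape=(48, 48), n_cells=1, dark_rate=0.25)
        scene = make_scene(cfg, seed=2)
        cube = render_flim_cube(scene, seed=2, noise=False)
        bg = cube.counts[scene.label_map == 0]
        assert np.allclose(bg, cfg.dark_rate)

    def test_determinism(self):
        cfg = GeneratorConfig(shape=(48, 48), n_cells=3)
        scene = make_scene(cfg, seed=9)
        a = render_flim_cube(scene, seed=9)
        b = render_flim_cube(scene, seed=9)
        assert np.array_equal(a.counts, b.counts)


@pytest.fixture()
def timeseries_scene():
    cfg = GeneratorConfig(shape=(48, 48), n_cells=3, photons_per_pixel=500)
    return make_scene(cfg, seed=4)


@pytest.fixture()
def ratio_scene():
    cfg = GeneratorConfig(shape=(48, 48), n_cells=2, radius_range=(6, 8))
    return make_scene(cfg, seed=6)


class TestRenderTimeseries:

    def test_null_response_gives_identical_truth(self, timeseries_scene):
        profile = ResponseProfile(delta_mv=0.0, responder_fraction=1.0)
        frames, truth = render_timeseries(timeseries_scene, profile, frame_schedule(3),
                                          noise=False, seed=1)
        for deltas in truth.values():
            assert deltas == [0.0, 0.0, 0.0]
        assert np.array_equal(frames[0].counts, frames[1].counts)

    def test_step_shifts_all_frames_after_onset(self, timeseries_scene):
        # frames start at 0, 30, ..., 150 s; a step at 30 s (just after the
        # first exposure begins) shifts the truth of frames 2-6
        profile = ResponseProfile(delta_mv=-15.0, onset_s=30.0, responder_fraction=1.0)
        frames, truth = render_timeseries(timeseries_scene, profile, frame_schedule(6),
                                          noise=False, seed=1)
        for deltas in truth.values():
            assert deltas[0] == 0.0
            assert deltas[1:] == [-15.0] * 5

    def test_gap_schedule_start_times(self):
        assert frame_schedule(3, 30.0, 150.0) == [0.0, 180.0, 360.0]

    def test_overlapping_frames_rejected(self, timeseries_scene):
        with pytest.raises(ValueError):
            render_timeseries(timeseries_scene, ResponseProfile(), [0.0, 10.0], exposure_s=30.0)


class TestRenderRatioPair:

    def test_expected_ratio_at_0mv(self, ratio_scene):
        ratio_scene.vmem_truth = {g: 0.0 for g in ratio_scene.vmem_truth}
        blue, green = render_ratio_pair(ratio_scene, background=100.0, noise=False)
        mask = ratio_scene.label_map > 0
        ratio = (blue[mask] - 100.0) / (green[mask] - 100.0)
        assert np.allclose(ratio, 1.8)

    def test_expected_ratio_at_plus_100mv(self, ratio_scene):
        ratio_scene.vmem_truth = {g: 100.0 for g in ratio_scene.vmem_truth}
        blue, green = render_ratio_pair(ratio_scene, background=100.0, noise=False)
        mask = ratio_scene.label_map > 0
        ratio = (blue[mask] - 100.0) / (green[mask] - 100.0)
        assert np.allclose(ratio, 1.8 + 0.39)

    def test_background_pixels_carry_background_level(self, ratio_scene):
        blue, green = render_ratio_pair(ratio_scene, background=150.0, noise=False)
        bg = ratio_scene.label_map == 0
        assert np.allclose(blue[bg], 150.0)
        assert np.allclose(green[bg], 150.0)
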