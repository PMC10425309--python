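"""Quantification chain: segmentation, ROI statistics, calibration, cells."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpitrack import (
    CalibrationLine,
    ReconImage,
    ScanConfig,
    acquire_scan,
    build_calibration,
    corner_background_mask,
    fit_calibration,
    ideal_image,
    iron_to_cells,
    make_cell_pellet,
    make_point_scene,
    measure_per_cell_iron,
    measure_roi,
    quantify_roi,
    reconstruct_joint,
    segment_roi,
    signal_to_iron,
)
from mpitrack.phantoms import PhantomScene


def flat_image(values: np.ndarray, voxel_mm: float = 1.0) -> ReconImage:
    return ReconImage(values, voxel_mm, np.zeros(3), "ideal")


class TestSegmentRoi:
    def test_all_zero_image_empty_mask(self):
        img = flat_image(np.zeros((8, 8, 8)))
        assert not segment_roi(img, (4, 4, 4)).any()

    def test_seed_outside_grid_rejected(self):
        img = flat_image(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            segment_roi(img, (8, 0, 0))

    def test_half_max_oracle_single_source(self, tiny_config):
        scene = make_point_scene(50.0, position=(0.0, 0.0, 0.0))
        img = ideal_image(scene, tiny_config)
        seed = img.world_to_index((0.0, 0.0, 0.0))
        mask = segment_roi(img, seed, 0.5)
        # single centered source: global threshold oracle
        oracle = img.values >= 0.5 * img.values.max()
        assert np.array_equal(mask, oracle)

    def test_hill_climb_reaches_peak_from_flank(self, tiny_config):
        scene = make_point_scene(50.0, position=(0.0, 0.0, 0.0))
        img = ideal_image(scene, tiny_config)
        peak_seed = img.world_to_index((0.0, 0.0, 0.0))
        flank_seed = img.world_to_index((3.0, 1.0, 0.0))
        assert np.array_equal(
            segment_roi(img, flank_seed), segment_roi(img, peak_seed)
        )

    def test_two_distant_sources_stay_separate(self):
        cfg = ScanConfig(
            fov_z_mm=60.0, fov_x_mm=20.0, fov_y_mm=20.0, voxel_mm=1.0,
            psf_fwhm_mm=2.0, noise_abs_sd=0.0, noise_rel_coeff=0.0, name="sep",
        )
        a = make_point_scene(50.0, position=(-15.0, 0.0, 0.0))
        b = make_point_scene(50.0, position=(15.0, 0.0, 0.0))
        scene = PhantomScene(a.sources + b.sources)
        img = ideal_image(scene, cfg)
        mask = segment_roi(img, img.world_to_index((-15.0, 0.0, 0.0)))
        zz = cfg.axis_coords(0)
        near_b = np.abs(zz - 15.0) < 3 * cfg.psf_fwhm_mm
        assert not mask[near_b, :, :].any()


class TestMeasureRoi:
    def test_uniform_roi_total(self):
        values = np.zeros((6, 6, 6))
        mask = np.zeros_like(values, dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        values[mask] = 7.0
        bg = np.zeros_like(mask)
        bg[4:, 4:, 4:] = True
        values[bg] = np.linspace(-0.1, 0.1, bg.sum())
        img = flat_image(values, voxel_mm=0.5)
        roi = measure_roi(img, mask, bg)
        assert roi.voxel_count == 8
        assert roi.total_signal == pytest.approx(7.0 * 8 * 0.125)
        assert roi.total_signal == pytest.approx(roi.volume_mm3 * roi.mean_signal)

    def test_snr_exactly_five_is_not_detectable(self):
        values = np.zeros((4, 4, 4))
        bg = np.zeros_like(values, dtype=bool)
        bg[2:, :, :] = True
        rng = np.random.default_rng(0)
        values[bg] = rng.normal(0, 1, bg.sum())
        sd = values[bg].std(ddof=1)
        mask = np.zeros_like(bg)
        mask[0, :, :] = True
        values[mask] = 5.0 * sd  # ROI mean lands exactly on the gate
        img = flat_image(values)
        roi = measure_roi(img, mask, bg)
        assert roi.snr == pytest.approx(5.0, abs=1e-12)
        assert not roi.detectable
        assert measure_roi(img, mask, bg, inclusive_gate=True).detectable

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_total_equals_voxel_sum_identity(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, (6, 5, 4))
        mask = rng.random((6, 5, 4)) < 0.4
        bg = ~mask & (rng.random((6, 5, 4)) < 0.5)
        if not mask.any() or bg.sum() < 2:
            return
        img = flat_image(values, voxel_mm=0.7)
        roi = measure_roi(img, mask, bg)
        oracle = values[mask].sum() * 0.7 ** 3
        assert roi.total_signal == pytest.approx(oracle, rel=1e-9)

    def test_mask_errors(self):
        values = np.ones((4, 4, 4))
        mask = np.zeros_like(values, dtype=bool)
        mask[0] = True
        img = flat_image(values)
        with pytest.raises(ValueError):
            measure_roi(img, np.zeros_like(mask), mask)  # empty ROI
        with pytest.raises(ValueError):
            measure_roi(img, mask, np.zeros_like(mask))  # empty background
        with pytest.raises(ValueError):
            measure_roi(img, mask, mask)  # overlap
        bg = np.zeros_like(mask)
        bg[2] = True  # constant background -> SD 0
        with pytest.raises(ValueError):
            measure_roi(img, mask, bg)


class TestCalibration:
    def test_exact_line(self):
        samples = [(m, 100.0 * m) for m in (1.0, 2.0, 4.0, 8.0)]
        line = fit_calibration(samples)
        assert line.slope == pytest.approx(100.0)
        assert line.intercept == pytest.approx(0.0, abs=1e-9)
        assert line.r2 == pytest.approx(1.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(4.4, 440.0)])

    def test_identical_iron_values_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(4.4, 440.0), (4.4, 441.0)])

    def test_noise_free_series_slope_matches_forward_oracle(self, focused_config):
        cfg = replace(focused_config, noise_abs_sd=0.0, noise_rel_coeff=0.0, name="nf")
        line = build_calibration(cfg, "joint", seed=0)
        assert line.r2 >= 0.999
        # forward-model oracle: ROI-captured fraction of one simulated source
        scene = make_point_scene(
            1000.0, position=cfg.fov_center, extent_sigma_mm=0.5
        )
        img = ideal_image(scene, cfg)
        mask = segment_roi(img, img.world_to_index(cfg.fov_center))
        captured = img.values[mask].sum() * cfg.voxel_volume_mm3 / 1000.0
        assert line.slope == pytest.approx(captured, rel=0.01)

    def test_signal_to_iron(self):
        line = CalibrationLine(100.0, 3.0, 1.0)
        assert signal_to_iron(440.0, line) == pytest.approx(4.4)
        assert signal_to_iron(0.0, line) == 0.0
        assert signal_to_iron(443.0, line, use_intercept=True) == pytest.approx(4.4)
        with pytest.raises(ValueError):
            signal_to_iron(1.0, CalibrationLine(0.0, 0.0, 1.0))

    def test_iron_to_cells(self):
        assert iron_to_cells(4.4, 4.4) == pytest.approx(1000.0)
        assert iron_to_cells(0.0, 4.4) == 0.0
        assert iron_to_cells(44.0, 4.4) == pytest.approx(10_000.0)
        with pytest.raises(ValueError):
            iron_to_cells(4.4, 0.0)


class TestPerCellIron:
    def test_round_trip_default_noise(self, focused_config):
        line = build_calibration(focused_config, "joint", seed=5)
        pellet = make_cell_pellet(1e6, 4.4, position=focused_config.fov_center)
        raw = acquire_scan(pellet, focused_config, seed=6)
        img = reconstruct_joint(raw)
        per_cell = measure_per_cell_iron(
            img, 1e6, line, img.world_to_index(focused_config.fov_center)
        )
        assert per_cell == pytest.approx(4.4, rel=0.05)

    def test_known_iron_arithmetic(self):
        # a pellet quantified at 4,400 ng across 1e6 cells is 4.4 pg/cell
        assert 4400.0 * 1e3 / 1e6 == pytest.approx(4.4)

    def test_zero_cells_rejected(self, tiny_config):
        img = flat_image(np.ones((4, 4, 4)))
        line = CalibrationLine(100.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            measure_per_cell_iron(img, 0, line, (0, 0, 0))

    def test_undetectable_pellet_rejected(self, focused_config):
        noisy = replace(focused_config, noise_abs_sd=50.0, name="loud")
        pellet = make_cell_pellet(1000, 4.4, position=noisy.fov_center)
        img = reconstruct_joint(acquire_scan(pellet, noisy, seed=1))
        line = CalibrationLine(100.0, 0.0, 1.0, noisy.config_id)
        with pytest.raises(ValueError):
            measure_per_cell_iron(
                img, 1000, line, img.world_to_index(noisy.fov_center)
            )


class TestEndToEnd:
    def test_snr_decreases_with_noise(self, focused_config):
        scene = make_point_scene(
            50.0, position=focused_config.fov_center, extent_sigma_mm=0.5
        )
        snrs = []
        for sd in (0.05, 0.5, 2.0):
            cfg = replace(
                focused_config, noise_abs_sd=sd, noise_rel_coeff=0.0, name=f"sd{sd}"
            )
            img = reconstruct_joint(acquire_scan(scene, cfg, seed=11))
            seed_vox = img.world_to_index(cfg.fov_center)
            mask = segment_roi(img, seed_vox)
            roi = measure_roi(img, mask, corner_background_mask(img, [seed_vox]))
            snrs.append(roi.snr)
        assert snrs[0] > snrs[1] > snrs[2]

    def test_iron_recovery_within_15pct_over_replicates(self, focused_config):
        """Detectable ROIs recover known iron within 15% at default noise."""
        line = build_calibration(focused_config, "joint", seed=21)
        true_iron = 50.0
        scene = make_point_scene(
            true_iron, position=focused_config.fov_center, extent_sigma_mm=0.5
        )
        errs = []
        for seed in range(20):
            img = reconstruct_joint(acquire_scan(scene, focused_config, seed=seed))
            q = quantify_roi(
                img, img.world_to_index(focused_config.fov_center), line, 4.4
            )
            assert q.roi.detectable
            errs.append(abs(q.iron_ng - true_iron) / true_iron)
        assert max(errs) <= 0.15

    def test_gate_blocks_iron_and_cells(self, focused_config):
        noisy = replace(focused_config, noise_abs_sd=200.0, name="swamp")
        scene = make_point_scene(4.4, position=noisy.fov_center, extent_sigma_mm=0.5)
        img = reconstruct_joint(acquire_scan(scene, noisy, seed=2))
        line = CalibrationLine(11.5, 0.0, 1.0, noisy.config_id)
        q = quantify_roi(img, img.world_to_index(noisy.fov_center), line, 4.4)
        if q.roi.voxel_count:  # whatever got segmented must fail the gate
            assert not q.roi.detectable
        assert np.isnan(q.iron_ng) and np.isnan(q.cell_estimate)

    def test_calibration_sequence_mismatch_rejected(self, focused_config, full_config):
        scene = make_point_scene(
            100.0, position=focused_config.fov_center, extent_sigma_mm=0.5
        )
        img = reconstruct_joint(acquire_scan(scene, focused_config, seed=3))
        wrong_line = CalibrationLine(100.0, 0.0, 1.0, full_config.config_id)
        with pytest.raises(ValueError):
            quantify_roi(
                img, img.world_to_index(focused_config.fov_center), wrong_line, 4.4
            )
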