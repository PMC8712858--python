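"""Synthetic-data generator tests: determinism, ground-truth consistency,
and the analytic forward model."""

from __future__ import annotations

import numpy as np
import pytest
from skimage.measure import label

from cryoraman.bands import DEFAULT_BANDS, validate_separability
from cryoraman.synth import (
    CalciumMovieSpec,
    CellPhantomSpec,
    FreezeProfile,
    make_calcium_movie,
    make_freeze_log,
    make_micrograph,
    make_raman_phantom,
    make_viability_table,
)


class TestPhantomSpecs:
    def test_band_registry_is_separable(self):
        validate_separability(DEFAULT_BANDS)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            CellPhantomSpec(ice_fraction=1.2)
        with pytest.raises(ValueError):
            CellPhantomSpec(partition_ratio_true=0.0)
        with pytest.raises(ValueError):
            CellPhantomSpec(chunky=True, ice_fraction=0.3)

    def test_cell_too_large_for_field_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            make_raman_phantom(CellPhantomSpec(cell_diameter=40.0), image_size=96)


class TestRamanPhantom:
    def test_deterministic_across_calls(self):
        spec = CellPhantomSpec(ice_fraction=0.3, seed=42)
        cube1, t1 = make_raman_phantom(spec)
        cube2, t2 = make_raman_phantom(spec)
        assert np.array_equal(cube1.intensities, cube2.intensities)
        assert np.array_equal(t1.segmentation.ice_mask, t2.segmentation.ice_mask)

    def test_different_seeds_differ(self):
        cube1, _ = make_raman_phantom(CellPhantomSpec(seed=1))
        cube2, _ = make_raman_phantom(CellPhantomSpec(seed=2))
        assert not np.array_equal(cube1.intensities, cube2.intensities)

    def test_null_contrast_case(self):
        """No ice, unit partitioning, zero noise: the solute band is
        spatially uniform and no ice pixels exist in the cell."""
        spec = CellPhantomSpec(
            ice_fraction=0.0, partition_ratio_true=1.0, noise_level=0.0, seed=0
        )
        cube, truth = make_raman_phantom(spec)
        solute = next(c for c in truth.components if c.name == "glycerol")
        assert np.allclose(solute.amplitude_map, solute.amplitude_map.flat[0], rtol=1e-5)
        assert not truth.segmentation.ice_mask.any()

    def test_largest_cell_stage_area_matches_disk_formula(self):
        """A 19.8-um cell at 333-nm pitch has mask area within 2% of
        pi * 9.9^2 um^2."""
        spec = CellPhantomSpec(cell_diameter=19.8, seed=0)
        _, truth = make_raman_phantom(spec, image_size=96, pixel_pitch=0.333)
        area = truth.segmentation.cell_area_um2
        assert area == pytest.approx(np.pi * 9.9**2, rel=0.02)

    def test_chunky_ice_is_single_large_component(self):
        spec = CellPhantomSpec(ice_fraction=0.8, chunky=True, seed=5)
        _, truth = make_raman_phantom(spec)
        ice = truth.segmentation.ice_mask
        cell = truth.segmentation.cell_mask
        lab = label(ice, connectivity=2)
        assert lab.max() == 1
        assert ice.sum() / cell.sum() >= 0.75

    def test_dispersed_ice_has_many_small_components(self):
        spec = CellPhantomSpec(ice_fraction=0.3, chunky=False, seed=5)
        _, truth = make_raman_phantom(spec)
        ice = truth.segmentation.ice_mask
        cell = truth.segmentation.cell_mask
        lab = label(ice, connectivity=2)
        assert lab.max() >= 4
        sizes = np.bincount(lab.ravel())[1:]
        assert sizes.max() / cell.sum() < 0.75

    def test_requested_ice_fraction_realized_on_mask(self):
        for f, chunky in [(0.3, False), (0.6, False), (0.8, True)]:
            _, truth = make_raman_phantom(
                CellPhantomSpec(ice_fraction=f, chunky=chunky, seed=9)
            )
            assert truth.ice_area_fraction == pytest.approx(f, abs=0.05)

    def test_solute_amplitude_ratio_is_partition_ratio(self):
        spec = CellPhantomSpec(partition_ratio_true=2.4, noise_level=0.0, seed=3)
        _, truth = make_raman_phantom(spec)
        solute = next(c for c in truth.components if c.name == "glycerol")
        seg = truth.segmentation
        inner = seg.cell_mask.copy()
        inner[np.gradient(seg.cell_mask.astype(float))[0] != 0] = False
        from scipy import ndimage as ndi

        core = ndi.binary_erosion(seg.cell_mask, iterations=3)
        far = ~ndi.binary_dilation(seg.cell_mask, iterations=3)
        ratio = solute.amplitude_map[far].mean() / solute.amplitude_map[core].mean()
        assert ratio == pytest.approx(2.4, rel=0.02)

    def test_noise_free_cube_reproducible_from_components(self):
        """Oracle: re-evaluate the band-sum forward model pixel-wise."""
        cube, truth = make_raman_phantom(CellPhantomSpec(noise_level=0.0, seed=8))
        recon = np.zeros_like(cube.intensities)
        for comp in truth.components:
            prof = comp.line_profile(cube.wavenumbers).astype(np.float32)
            recon += prof[:, None, None] * comp.amplitude_map.astype(np.float32)[None]
        assert np.allclose(recon, cube.intensities, rtol=1e-5, atol=1e-4)


class TestCalciumMovie:
    def test_frame_count_is_duration_times_rate(self):
        movie, _ = make_calcium_movie(
            CalciumMovieSpec(n_responders=2, n_nonresponders=2, seed=0)
        )
        assert movie.n_frames == 740  # 185 s x 4 frames/s

    def test_zero_noise_zero_responders_is_static(self):
        movie, _ = make_calcium_movie(
            CalciumMovieSpec(n_responders=0, n_nonresponders=3, noise_sd=0.0, seed=1)
        )
        assert np.ptp(movie.frames, axis=0).max() == 0.0

    def test_deterministic(self):
        spec = CalciumMovieSpec(seed=7)
        m1, t1 = make_calcium_movie(spec)
        m2, t2 = make_calcium_movie(spec)
        assert np.array_equal(m1.frames, m2.frames)
        assert np.array_equal(t1.centers, t2.centers)

    def test_overdense_request_names_density_limit(self):
        with pytest.raises(ValueError, match="density"):
            make_calcium_movie(
                CalciumMovieSpec(n_responders=100, n_nonresponders=100, seed=0),
                image_size=64,
            )

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CalciumMovieSpec(stimulus_time=200.0, duration=185.0)


class TestViabilityTable:
    def test_rate_one_gives_all_viable(self):
        t = make_viability_table({"c": [1.0, 1.0, 1.0]}, n_cells=500, seed=0)
        assert (t["viable"] == 500).all()
        assert (t["nonviable"] == 0).all()

    def test_timepoints_emitted_exactly(self):
        t = make_viability_table({"c": [0.9, 0.8, 0.7]}, n_cells=100, seed=0)
        assert list(t["timepoint_min"]) == [0.0, 30.0, 60.0]

    def test_half_rate_concentrates_at_large_n(self):
        t = make_viability_table({"c": [0.5]}, n_cells=10_000, timepoints=[0.0], seed=3)
        frac = t["viable"].iloc[0] / 10_000
        assert abs(frac - 0.5) < 0.02

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            make_viability_table({"c": [1.5]}, n_cells=10, timepoints=[0.0])


class TestFreezeLog:
    def test_post_nucleation_ramp_duration(self):
        """T_NUC = -4 C, B = -1 C/min: the -4 -> -60 segment lasts 56 min."""
        prof = FreezeProfile(t_nuc=-4.0, cooling_rate=-1.0, hold_min=15.0)
        log = make_freeze_log(prof, sampling_dt=1.0)
        at_tnuc_end = (20 - -4) / 10 * 60 + 15 * 60  # ramp-in + hold, s
        at_minus60 = at_tnuc_end + 56 * 60
        assert np.interp(at_tnuc_end, log["time_s"], log["temperature_C"]) == pytest.approx(-4.0)
        assert np.interp(at_minus60, log["time_s"], log["temperature_C"]) == pytest.approx(-60.0)

    def test_degenerate_single_rate_is_straight_ramp(self):
        prof = FreezeProfile(t_nuc=-4.0, cooling_rate=-10.0, hold_min=0.0)
        log = make_freeze_log(prof, sampling_dt=1.0)
        # constant -10 C/min throughout: temperature is linear in time
        expected = 20.0 - 10.0 * log["time_s"] / 60.0
        assert np.allclose(log["temperature_C"], expected, atol=1e-9)

    def test_six_condition_grid(self):
        """The two nucleation temperatures and three rates form the
        study's full freezing-condition grid."""
        for t_nuc in (-4.0, -8.0):
            for b in (-1.0, -3.0, -5.0):
                log = make_freeze_log(FreezeProfile(t_nuc=t_nuc, cooling_rate=b))
                temps = log["temperature_C"].to_numpy()
                assert temps[0] == 20.0
                assert temps[-1] == pytest.approx(-100.0)
                hold = np.isclose(temps, t_nuc).sum()
                assert hold >= 15 * 60  # 15-min hold at T_NUC
                after_hold = temps[np.argmax(np.isclose(temps, t_nuc)):]
                assert np.all(np.diff(after_hold) <= 1e-9)  # monotone after nucleation

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            FreezeProfile(t_nuc=5.0)
        with pytest.raises(ValueError):
            FreezeProfile(cooling_rate=1.0)
        with pytest.raises(ValueError):
            FreezeProfile(segments=((-1.0, -60.0), (-10.0, -50.0)))


class TestMicrograph:
    def test_disks_have_requested_diameters(self):
        img = make_micrograph([10.0, 16.0], image_size=128, pixel_pitch=0.5, noise_sd=0.0, seed=0)
        from cryoraman.cytometry import fresh_diameter

        ds = sorted(fresh_diameter(img, 0.5))
        assert ds == pytest.approx([10.0, 16.0], rel=0.05)
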