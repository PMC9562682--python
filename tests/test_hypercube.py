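"""Hypercube I/O, reflectance calibration and artifact repair."""

import numpy as np
import pytest

from hypertender import (Hypercube, ReferencePair, calibrate_reflectance,
                         detect_dead_pixels, read_cube, remove_spikes,
                         repair_dead_pixels, write_cube)
from hypertender.hypercube import CalibrationReferenceError, find_spikes


def small_cube(rng, rows=4, cols=5, bands=6):
    return Hypercube(values=rng.uniform(0.1, 0.9, (rows, cols, bands)),
                     wavelengths=np.linspace(900, 1700, bands),
                     sample_id="toy")


class TestEnviIO:
    def test_round_trip_preserves_values_and_wavelengths(self, rng, tmp_path):
        cube = small_cube(rng)
        write_cube(cube, tmp_path / "toy", dtype=np.float64)
        back = read_cube(tmp_path / "toy")
        np.testing.assert_array_equal(back.values, cube.values)
        np.testing.assert_array_equal(back.wavelengths, cube.wavelengths)
        assert back.sample_id == "toy"

    def test_payload_shorter_than_header_raises(self, rng, tmp_path):
        cube = small_cube(rng)
        write_cube(cube, tmp_path / "toy")
        raw = tmp_path / "toy.raw"
        raw.write_bytes(raw.read_bytes()[:-16])
        with pytest.raises(ValueError, match="does not match header shape"):
            read_cube(tmp_path / "toy")

    def test_missing_wavelength_field_is_named_in_error(self, rng, tmp_path):
        cube = small_cube(rng)
        write_cube(cube, tmp_path / "toy")
        hdr = tmp_path / "toy.hdr"
        text = "\n".join(l for l in hdr.read_text().splitlines()
                         if not (l.startswith("wavelength =") or l.startswith("  ")
                                 or l.startswith("}")))
        hdr.write_text(text)
        with pytest.raises(ValueError, match="wavelength"):
            read_cube(tmp_path / "toy")

    def test_missing_header_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_cube(tmp_path / "nope")


class TestCalibration:
    @pytest.fixture
    def refs(self):
        white = np.full((5, 6), 3000.0)
        black = np.full((5, 6), 100.0)
        return ReferencePair(white=white, black=black)

    def wl(self):
        return np.linspace(900, 1700, 6)

    def test_raw_at_black_maps_to_zero(self, refs):
        raw = Hypercube(np.full((4, 5, 6), 100.0), self.wl())
        np.testing.assert_allclose(calibrate_reflectance(raw, refs).values, 0.0)

    def test_raw_at_white_maps_to_one(self, refs):
        raw = Hypercube(np.full((4, 5, 6), 3000.0), self.wl())
        np.testing.assert_allclose(calibrate_reflectance(raw, refs).values, 1.0)

    def test_midpoint_maps_to_half(self, refs):
        raw = Hypercube(np.full((4, 5, 6), 1550.0), self.wl())
        np.testing.assert_allclose(calibrate_reflectance(raw, refs).values, 0.5)

    def test_affine_in_raw_signal(self, refs, rng):
        base = rng.uniform(200, 800, (4, 5, 6))
        raw1 = Hypercube(100.0 + base, self.wl())
        raw2 = Hypercube(100.0 + 2 * base, self.wl())
        c1 = calibrate_reflectance(raw1, refs).values
        c2 = calibrate_reflectance(raw2, refs).values
        np.testing.assert_allclose(c2, 2 * c1)

    def test_white_not_exceeding_black_raises(self):
        refs = ReferencePair(white=np.full((5, 6), 100.0),
                             black=np.full((5, 6), 100.0))
        raw = Hypercube(np.full((4, 5, 6), 50.0), self.wl())
        with pytest.raises(CalibrationReferenceError):
            calibrate_reflectance(raw, refs)

    def test_scan_references_are_row_averaged(self, rng):
        scan_white = 3000.0 + rng.normal(0, 5, (8, 5, 6))
        scan_black = 100.0 + rng.normal(0, 1, (8, 5, 6))
        refs = ReferencePair(white=scan_white, black=scan_black)
        w, b = refs.averaged()
        np.testing.assert_allclose(w, scan_white.mean(axis=0))
        np.testing.assert_allclose(b, scan_black.mean(axis=0))


class TestDeadPixelRepair:
    def wl(self, n):
        return np.linspace(900, 1700, n)

    def test_constant_band_repairs_to_constant(self):
        values = np.full((6, 6, 3), 0.4)
        mask = np.zeros((6, 6), bool)
        mask[2, 3] = True
        cube = Hypercube(values.copy(), self.wl(3))
        cube.values[2, 3] = -1.0
        out = repair_dead_pixels(cube, mask)
        np.testing.assert_allclose(out.values[2, 3], 0.4)

    def test_planar_band_repairs_to_plane_value(self):
        r = np.arange(8)[:, None] * np.ones((1, 8))
        c = np.ones((8, 1)) * np.arange(8)[None, :]
        plane = 0.3 * r + 0.1 * c
        cube = Hypercube(plane[:, :, None].repeat(3, axis=2), self.wl(3))
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = True
        cube.values[4, 4] = 99.0
        out = repair_dead_pixels(cube, mask)
        np.testing.assert_allclose(out.values[4, 4], plane[4, 4], atol=1e-10)

    def test_all_false_mask_returns_cube_unchanged(self, rng):
        cube = small_cube(rng)
        assert repair_dead_pixels(cube, np.zeros((4, 5), bool)) is cube

    def test_live_pixels_are_bit_identical(self, rng):
        cube = small_cube(rng, 8, 8, 4)
        mask = np.zeros((8, 8), bool)
        mask[3, 3] = mask[6, 1] = True
        out = repair_dead_pixels(cube, mask)
        np.testing.assert_array_equal(out.values[~mask], cube.values[~mask])

    def test_edge_dead_pixel_falls_back_to_nearest_neighbour(self, rng):
        cube = small_cube(rng, 5, 5, 3)
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        out = repair_dead_pixels(cube, mask)
        assert np.all(np.isfinite(out.values[0, 0]))

    def test_all_dead_is_unrepairable(self, rng):
        cube = small_cube(rng)
        with pytest.raises(ValueError, match="every pixel"):
            repair_dead_pixels(cube, np.ones((4, 5), bool))

    def test_repair_is_idempotent(self, calibrated_scene):
        _, cal, _, truth = calibrated_scene
        once = repair_dead_pixels(cal, truth.dead_mask)
        twice = repair_dead_pixels(once, truth.dead_mask)
        np.testing.assert_array_equal(once.values, twice.values)


class TestDeadPixelDetection:
    def test_recall_and_precision_are_perfect_on_default_scene(self, default_scene):
        _, cube, refs, truth = default_scene
        mask = detect_dead_pixels(cube, refs)
        assert truth.dead_mask.sum() > 0
        np.testing.assert_array_equal(mask, truth.dead_mask)

    def test_black_level_pixel_flagged_white_level_not(self):
        white = np.full((5, 6), 3000.0)
        black = np.full((5, 6), 100.0)
        refs = ReferencePair(white=white, black=black)
        values = np.full((4, 5, 6), 3000.0)
        values[1, 2] = 100.0
        cube = Hypercube(values, np.linspace(900, 1700, 6))
        mask = detect_dead_pixels(cube, refs)
        assert mask[1, 2] and mask.sum() == 1


class TestSpikeRemoval:
    def wl(self, n):
        return np.linspace(900, 1700, n)

    def test_single_huge_value_on_constant_spectrum_is_replaced(self):
        # one outlier among n bands deviates by at most (n-1)/sqrt(n) single-
        # pass SDs, so exceeding the 6-SD rule needs a reasonably long
        # spectrum (n >= 38); real cubes have 256 bands
        values = np.full((1, 1, 100), 0.3)
        values[0, 0, 7] = 5.0
        out = remove_spikes(Hypercube(values, self.wl(100)))
        np.testing.assert_allclose(out.values[0, 0], 0.3)

    def test_spike_at_spectrum_end_uses_same_side_neighbours(self):
        values = np.full((1, 1, 100), 0.3)
        values[0, 0, 0] = 5.0
        out = remove_spikes(Hypercube(values, self.wl(100)))
        assert out.values[0, 0, 0] == pytest.approx(0.3)

    def test_spectrum_within_six_sds_is_unchanged(self, rng):
        cube = small_cube(rng, 3, 3, 30)
        out = remove_spikes(cube)
        np.testing.assert_array_equal(out.values, cube.values)

    def test_all_injected_spikes_found_and_no_false_positives(self, calibrated_scene):
        _, cal, _, truth = calibrated_scene
        mask = find_spikes(cal)
        detected = set(map(tuple, np.argwhere(mask)))
        injected = set(map(tuple, truth.spikes))
        assert detected == injected

    def test_removal_is_idempotent(self, calibrated_scene):
        _, cal, _, truth = calibrated_scene
        once = remove_spikes(cal)
        twice = remove_spikes(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_non_spike_positions_are_bit_identical(self, calibrated_scene):
        _, cal, _, truth = calibrated_scene
        out = remove_spikes(cal)
        changed = np.argwhere(out.values != cal.values)
        assert set(map(tuple, changed)) <= set(map(tuple, truth.spikes))

    def test_needs_three_bands(self):
        cube = Hypercube(np.zeros((2, 2, 2)), np.array([900.0, 1700.0]))
        with pytest.raises(ValueError):
            remove_spikes(cube)
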