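import numpy as np
import pytest

from conftest import make_mask, make_projected
from macroquant.errors import ConfigurationError, InputError
from macroquant.particles import label_components
from macroquant.segmentation import (apply_mask, make_cell_mask,
                                     resolve_threshold,
                                     resolve_threshold_pooled, segment_nuclei,
                                     threshold_binary, watershed_split)
from oracles import flood_fill_components, otsu_exhaustive


def disk(shape, cy, cx, r):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def ellipse(shape, cy, cx, ry, rx):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


class TestThresholdBinary:
    def test_fixed_zero_marks_everything(self, rng):
        img = make_projected(rng.integers(0, 255, (8, 8), dtype=np.uint8))
        assert threshold_binary(img, {"method": "fixed", "value": 0}).pixels.all()

    def test_fixed_threshold_is_greater_or_equal(self):
        img = make_projected([[127, 128], [129, 0]])
        mask = threshold_binary(img, {"method": "fixed", "value": 128})
        np.testing.assert_array_equal(mask.pixels,
                                      [[False, True], [True, False]])
        assert mask.threshold_used == 128

    def test_otsu_separates_bimodal_exactly(self):
        values = np.concatenate([np.full(900, 10), np.full(100, 200)])
        img = make_projected(values.reshape(20, 50).astype(np.uint8))
        mask = threshold_binary(img, {"method": "otsu"})
        assert mask.pixels.sum() == 100
        assert (img.pixels[mask.pixels] == 200).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_otsu_matches_exhaustive_between_class_variance(self, seed):
        r = np.random.default_rng(seed)
        img = r.integers(0, 256, (32, 32)).astype(np.uint8)
        t = resolve_threshold(img, {"method": "otsu"})
        assert t == otsu_exhaustive(img) + 1

    def test_fixed_out_of_range_errors(self):
        img = make_projected(np.zeros((4, 4), np.uint8))
        with pytest.raises(ConfigurationError):
            threshold_binary(img, {"method": "fixed", "value": 300})

    @pytest.mark.parametrize("method", ["otsu", "li"])
    def test_constant_image_is_degenerate(self, method):
        img = make_projected(np.full((8, 8), 7, np.uint8))
        with pytest.raises(InputError, match="fixed"):
            threshold_binary(img, {"method": method})

    @pytest.mark.parametrize("seed", range(5))
    def test_foreground_count_monotone_in_threshold(self, seed):
        r = np.random.default_rng(seed)
        img = make_projected(r.integers(0, 256, (24, 24)).astype(np.uint8))
        counts = [threshold_binary(img, {"method": "fixed", "value": t}
                                   ).pixels.sum()
                  for t in range(0, 256, 17)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_pooled_resolution_matches_single_image_case(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        for method in ("otsu", "li"):
            assert (resolve_threshold_pooled([img], {"method": method})
                    == resolve_threshold(img, {"method": method}))

    def test_pooled_otsu_uses_the_whole_batch(self):
        dark = np.full((16, 16), 10, np.uint8)
        bright = np.full((16, 16), 200, np.uint8)
        t = resolve_threshold_pooled([dark, bright], {"method": "otsu"})
        assert 10 < t <= 200


class TestWatershedSplit:
    def test_isolated_disk_passes_through(self):
        mask = make_mask(disk((32, 32), 16, 16, 8))
        out = watershed_split(mask)
        np.testing.assert_array_equal(out.pixels, mask.pixels)
        assert out.watershed_applied

    def test_tangent_disks_are_split_into_two(self):
        fused = disk((40, 48), 20, 16, 8) | disk((40, 48), 20, 32, 8)
        _, n_before = flood_fill_components(fused)
        assert n_before == 1
        out = watershed_split(make_mask(fused))
        _, n_after = flood_fill_components(out.pixels)
        assert n_after == 2

    def test_empty_mask_passes_through(self):
        out = watershed_split(make_mask(np.zeros((16, 16), bool)))
        assert not out.pixels.any()

    @pytest.mark.parametrize("seed", range(8))
    def test_never_merges_and_never_adds_foreground(self, seed):
        r = np.random.default_rng(seed)
        blob = r.random((48, 48)) < 0.35
        from scipy import ndimage as ndi
        blob = ndi.binary_closing(blob, np.ones((3, 3)))
        mask = make_mask(blob)
        out = watershed_split(mask)
        assert not (out.pixels & ~mask.pixels).any()  # no pixel added
        _, n_in = label_components(mask.pixels)
        _, n_out = label_components(out.pixels)
        assert n_out >= n_in


class TestMakeCellMask:
    def test_uniformly_dark_image_gives_empty_mask(self):
        img = make_projected(np.zeros((32, 32), np.uint8))
        mask = make_cell_mask(img, {"method": "fixed", "value": 50})
        assert not mask.pixels.any()

    def test_nucleus_hole_is_filled(self):
        # a 30 um cell (50 px at 0.3 um/px) with a dark nucleus hole
        px = 0.3
        img = np.zeros((96, 96), np.uint8)
        cell = disk((96, 96), 48, 48, 50)
        hole = disk((96, 96), 48, 48, 10)
        img[cell] = 200
        img[hole] = 10
        mask = make_cell_mask(make_projected(img, pixel_size=px),
                              {"method": "fixed", "value": 100},
                              min_cell_area_um2=50.0)
        assert mask.pixels[48, 48]  # hole covered
        assert mask.pixels.sum() == pytest.approx(cell.sum(), rel=0.02)

    def test_components_below_min_cell_area_are_dropped(self):
        px = 1.0
        img = np.zeros((64, 64), np.uint8)
        img[disk((64, 64), 20, 20, 8)] = 200   # ~201 um2
        img[disk((64, 64), 50, 50, 1)] = 200   # ~5 um2, below 50
        mask = make_cell_mask(make_projected(img, pixel_size=px),
                              {"method": "fixed", "value": 100},
                              min_cell_area_um2=50.0)
        _, n = label_components(mask.pixels)
        assert n == 1
        assert not mask.pixels[50, 50]


class TestApplyMask:
    def test_full_cell_mask_is_identity(self, rng):
        structures = make_mask(rng.random((16, 16)) < 0.3)
        cells = make_mask(np.ones((16, 16), bool))
        out = apply_mask(structures, cells)
        np.testing.assert_array_equal(out.pixels, structures.pixels)

    def test_empty_cell_mask_annihilates(self, rng):
        structures = make_mask(rng.random((16, 16)) < 0.3)
        out = apply_mask(structures, make_mask(np.zeros((16, 16), bool)))
        assert not out.pixels.any()

    def test_whole_particle_keeps_majority_overlap_intact(self):
        structures = np.zeros((8, 8), bool)
        structures[2:5, 2:5] = True  # 9 px particle
        cells = np.zeros((8, 8), bool)
        cells[2:4, 2:5] = True  # covers 6 of 9 px
        out = apply_mask(make_mask(structures), make_mask(cells),
                         mode="whole_particle", overlap_fraction=0.5)
        assert out.pixels.sum() == 9  # kept with every pixel

    def test_pixel_and_clips_straddling_particles(self):
        structures = np.zeros((8, 8), bool)
        structures[2:5, 2:5] = True
        cells = np.zeros((8, 8), bool)
        cells[2:4, 2:5] = True
        out = apply_mask(make_mask(structures), make_mask(cells))
        assert out.pixels.sum() == 6

    @pytest.mark.parametrize("mode", ["pixel_and", "whole_particle"])
    def test_output_is_subset_of_structures(self, mode, rng):
        structures = make_mask(rng.random((24, 24)) < 0.3)
        cells = make_mask(rng.random((24, 24)) < 0.5)
        out = apply_mask(structures, cells, mode=mode)
        assert not (out.pixels & ~structures.pixels).any()
        if mode == "pixel_and":
            assert not (out.pixels & ~cells.pixels).any()

    def test_shape_mismatch_errors(self):
        with pytest.raises(InputError):
            apply_mask(make_mask(np.zeros((4, 4), bool)),
                       make_mask(np.zeros((5, 5), bool)))


class TestSegmentNuclei:
    def test_counts_well_separated_nuclei(self):
        img = np.zeros((96, 96), np.uint8)
        centers = [(15, 15), (15, 75), (48, 48), (80, 20), (80, 80)]
        for cy, cx in centers:
            img[ellipse((96, 96), cy, cx, 9, 7)] = 220
        mask = segment_nuclei(make_projected(img),
                              {"method": "fixed", "value": 100})
        _, n = flood_fill_components(mask.pixels)
        assert n == 5

    def test_tangent_nuclei_are_split(self):
        img = np.zeros((64, 96), np.uint8)
        img[ellipse((64, 96), 32, 30, 9, 12)] = 220
        img[ellipse((64, 96), 32, 54, 9, 12)] = 220
        _, n_raw = flood_fill_components(img > 100)
        assert n_raw == 1  # genuinely fused before splitting
        mask = segment_nuclei(make_projected(img),
                              {"method": "fixed", "value": 100})
        _, n = flood_fill_components(mask.pixels)
        assert n == 2

    def test_empty_field_gives_empty_mask(self):
        img = make_projected(np.zeros((32, 32), np.uint8))
        mask = segment_nuclei(img, {"method": "fixed", "value": 50})
        assert not mask.pixels.any()
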