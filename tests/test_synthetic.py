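import dataclasses
import json

import numpy as np
import pytest

from conftest import handcrafted_scene, small_scene_params
from macroquant.errors import GenerationError, InputError
from macroquant.synthetic import (SceneParams, Structure, _ellipse_mask,
                                  combine_scores, generate_scene,
                                  render_stack, score_detections)


class TestGenerateScene:
    def test_same_params_and_seed_give_identical_scenes(self):
        p = small_scene_params()
        a = generate_scene(p, 5, "f").truth_dict()
        b = generate_scene(p, 5, "f").truth_dict()
        assert a == b

    def test_different_seeds_differ(self):
        p = small_scene_params()
        a = generate_scene(p, 5, "f").truth_dict()
        b = generate_scene(p, 6, "f").truth_dict()
        assert a != b

    def test_exact_total_is_honoured_in_the_truth(self):
        p = small_scene_params(n_mp_total=20)
        scene = generate_scene(p, 3, "f")
        assert len(scene.macropinosomes) == 20

    def test_macropinosome_diameters_within_range(self):
        scene = generate_scene(small_scene_params(), 7, "f")
        for s in scene.macropinosomes:
            assert 0.5 <= s.diameter_um <= 5.0

    def test_every_structure_lies_inside_the_field(self):
        p = small_scene_params()
        scene = generate_scene(p, 11, "f")
        for s in scene.structures:
            h = s.diameter_um / 2
            assert h <= s.x_um <= p.field_size_um - h
            assert h <= s.y_um <= p.field_size_um - h

    def test_one_nucleus_per_cell_inside_the_field(self):
        p = small_scene_params()
        scene = generate_scene(p, 2, "f")
        truth = scene.truth_dict()
        n_nuc = sum(1 for s in truth["structures"] if s["class"] == "nucleus")
        n_cell = sum(1 for s in truth["structures"] if s["class"] == "cell")
        assert n_nuc == n_cell == len(scene.cells)

    def test_requested_confluency_is_reached(self):
        p = SceneParams(field_size_px=512, confluency=0.75)
        scene = generate_scene(p, 1, "f")
        shape = (p.field_size_px, p.field_size_px)
        px = p.pixel_size_um
        footprint = np.zeros(shape, bool)
        for c in scene.cells:
            footprint |= _ellipse_mask(
                shape, (c.center_um[0] / px, c.center_um[1] / px),
                (c.semi_axes_um[0] / px, c.semi_axes_um[1] / px), c.angle_rad)
        coverage = footprint.mean()
        assert 0.70 <= coverage <= 0.80

    def test_cells_do_not_overlap(self):
        p = small_scene_params(confluency=0.7)
        scene = generate_scene(p, 9, "f")
        shape = (p.field_size_px, p.field_size_px)
        px = p.pixel_size_um
        count = np.zeros(shape, np.int32)
        for c in scene.cells:
            count += _ellipse_mask(
                shape, (c.center_um[0] / px, c.center_um[1] / px),
                (c.semi_axes_um[0] / px, c.semi_axes_um[1] / px), c.angle_rad)
        assert count.max() <= 1

    def test_unreachable_confluency_errors(self):
        with pytest.raises(GenerationError, match="density"):
            generate_scene(small_scene_params(confluency=0.97), 0, "f")


class TestRenderStack:
    def test_empty_dark_scene_renders_all_zero_dextran(self):
        p = small_scene_params(mean_mp_per_cell=0.0, background_level=0.0,
                               background_gradient=0.0, read_noise_sigma=0.0,
                               noise=False, snr=1.0)
        scene = generate_scene(p, 4, "f")
        stack = render_stack(scene)
        assert stack.voxels[:, 0].max() == 0

    def test_structure_peaks_at_its_z_center_slice(self):
        scene = handcrafted_scene(n_cells_x=1, n_cells_y=1,
                                  mp_per_cell=[(0.0, 4.0, 2.0)])
        scene.params = dataclasses.replace(
            scene.params, noise=False, background_gradient=0.0)
        stack = render_stack(scene)
        s = scene.structures[0]
        x_px = int(round(s.x_um / scene.params.pixel_size_um))
        y_px = int(round(s.y_um / scene.params.pixel_size_um))
        profile = stack.voxels[:, 0, y_px, x_px].astype(int)
        assert np.argmax(profile) == 5  # z = 2.5 um at 0.5 um spacing

    def test_subresolution_vesicle_blurs_below_half_micron(self):
        # noiseless render of one 0.15 um vesicle: footprint at half peak
        # must stay under the 0.5 um minimum macropinosome diameter
        scene = handcrafted_scene(n_cells_x=1, n_cells_y=1, mp_per_cell=[])
        scene.params = dataclasses.replace(
            scene.params, noise=False, background_level=1.0,
            background_gradient=0.0, read_noise_sigma=0.0, snr=10.0)
        scene.structures = [Structure(cls="vesicle", x_um=38.4, y_um=38.4,
                                      z_um=2.5, diameter_um=0.15,
                                      cell_index=0)]
        stack = render_stack(scene)
        px = scene.params.pixel_size_um
        mip = stack.voxels[:, 0].max(axis=0).astype(float) - 1.0
        peak = mip.max()
        assert peak > 0
        area_px = (mip >= peak / 2).sum()
        equiv_diam_um = 2 * np.sqrt(area_px * px * px / np.pi)
        assert equiv_diam_um < 0.5

    def test_determinism_of_rendering(self):
        p = small_scene_params()
        scene = generate_scene(p, 8, "f")
        a = render_stack(scene).voxels
        b = render_stack(scene).voxels
        np.testing.assert_array_equal(a, b)

    def test_gfp_channel_marks_only_positive_cells(self):
        p = small_scene_params(gfp_fraction=0.0, noise=False,
                               background_level=0.0, background_gradient=0.0,
                               read_noise_sigma=0.0, snr=1.0)
        scene = generate_scene(p, 4, "f")
        stack = render_stack(scene)
        assert stack.voxels[:, 1].max() == 0  # no gfp-positive cells


class TestScoreDetections:
    def _truth(self, centers):
        return {"field_id": "f", "pixel_size_um": 0.3,
                "structures": [{"class": "macropinosome", "x_um": x,
                                "y_um": y, "z_um": 1.0, "diameter_um": 1.0}
                               for x, y in centers]}

    def test_perfect_detections_score_one(self):
        centers = [(5.0, 5.0), (10.0, 12.0), (20.0, 8.0)]
        score = score_detections(self._truth(centers), centers)
        assert score.precision == score.recall == score.f1 == 1.0
        assert score.count_error_fraction == 0.0

    def test_empty_detections(self):
        score = score_detections(self._truth([(i, i) for i in range(10)]), [])
        assert score.recall == 0.0 and score.false_negatives == 10

    def test_one_spurious_detection(self):
        centers = [(float(5 * i), 5.0) for i in range(10)]
        detections = centers[:9] + [(200.0, 200.0)]
        score = score_detections(self._truth(centers), detections)
        assert score.precision == pytest.approx(0.9)
        assert score.recall == pytest.approx(0.9)
        assert score.count_error_fraction == 0.0

    def test_matching_is_one_to_one(self):
        # two detections near one truth: only one may match
        score = score_detections(self._truth([(5.0, 5.0)]),
                                 [(5.1, 5.0), (4.9, 5.0)])
        assert score.true_positives == 1
        assert score.false_positives == 1

    def test_greedy_prefers_the_nearest_pair(self):
        truth = self._truth([(5.0, 5.0), (6.0, 5.0)])
        score = score_detections(truth, [(5.05, 5.0), (6.4, 5.0)])
        assert score.true_positives == 2

    def test_identity_bookkeeping(self):
        truth = self._truth([(1.0, 1.0), (3.0, 3.0)])
        score = score_detections(truth, [(1.0, 1.0)])
        assert score.true_positives + score.false_negatives == score.n_truth
        assert score.true_positives + score.false_positives == score.n_detected

    def test_mismatched_field_ids_error(self):
        import pandas as pd
        det = pd.DataFrame({"image_id": ["other"], "centroid_x_px": [1.0],
                            "centroid_y_px": [1.0]})
        with pytest.raises(InputError, match="other"):
            score_detections(self._truth([(1.0, 1.0)]), det)

    def test_truth_loaded_from_json_file(self, tmp_path):
        path = tmp_path / "truth.json"
        path.write_text(json.dumps(self._truth([(2.0, 2.0)])))
        score = score_detections(path, [(2.0, 2.0)])
        assert score.f1 == 1.0

    def test_combine_scores_pools_counts(self):
        a = score_detections(self._truth([(1, 1), (5, 5)]), [(1, 1)])
        b = score_detections(self._truth([(2, 2)]), [(2, 2), (9, 9)])
        pooled = combine_scores([a, b])
        assert pooled.n_truth == 3 and pooled.n_detected == 3
        assert pooled.true_positives == 2


class TestMonotoneDegradation:
    def test_median_f1_non_increasing_with_noise(self):
        from macroquant.pipeline import ExperimentConfig, run_field
        from macroquant.validation import SYNTHETIC_ANALYSIS_CONFIG
        config = ExperimentConfig.from_dict(SYNTHETIC_ANALYSIS_CONFIG)
        medians = []
        for snr in (20.0, 5.0, 2.0):
            f1s = []
            for seed in (21, 22, 23):
                p = small_scene_params(field_size_px=192, snr=snr)
                scene = generate_scene(p, seed, "f")
                stack = render_stack(scene)
                res = run_field(stack, config, image_id="f")
                sc = score_detections(scene.truth_dict(), res.particles,
                                      pixel_size_um=p.pixel_size_um)
                f1s.append(sc.f1)
            medians.append(float(np.median(f1s)))
        assert medians[0] >= medians[1] >= medians[2]
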