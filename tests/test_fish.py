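"""Segmentation, radius-based typing and distance statistics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from hepatlas import FishScene
from hepatlas.fish import (
    CellCall,
    Component,
    call_cells,
    distance_report,
    quantify_scene,
    segment_channel,
    tumor_calls_from,
)
from hepatlas.simulate import example_fish_config, simulate_fish


def match_calls_to_truth(calls, truth):
    cent = np.array([c.centroid_um for c in calls])
    planted = truth[["x_px", "y_px"]].to_numpy()
    idx = cdist(planted, cent).argmin(axis=1)
    return cent, planted, idx


class TestSegmentChannel:
    def test_block_centroid(self):
        img = np.zeros((20, 20))
        img[5:8, 10:13] = 255.0
        comps = segment_channel(img, threshold=128, min_component_px=5)
        assert len(comps) == 1
        assert comps[0].centroid_xy == pytest.approx((11.0, 6.0))

    def test_small_component_filtered(self):
        img = np.zeros((20, 20))
        img[3, 3] = img[3, 4] = 255.0
        assert segment_channel(img, threshold=128, min_component_px=5) == []

    def test_empty_mask_is_empty_result(self):
        assert segment_channel(np.zeros((10, 10)), threshold=0.5) == []

    def test_noise_free_centroids_within_one_pixel(self):
        scene, truth = simulate_fish(example_fish_config(seed=2))
        comps = segment_channel(scene.channels["DAPI"], threshold=0.5)
        got = np.array([c.centroid_xy for c in comps])
        planted = truth[["x_px", "y_px"]].to_numpy()
        idx = cdist(planted, got).argmin(axis=1)
        assert len(comps) == len(truth)
        assert np.abs(got[idx] - planted).max() <= 1.0


def scene_stub(channel_map, pixel_size_um=1.0):
    blank = np.zeros((10, 10))
    channels = {"DAPI": blank, **{ch: blank for ch in channel_map}}
    return FishScene(channels=channels, pixel_size_um=pixel_size_um,
                     channel_map=channel_map)


class TestCallCells:
    def test_macrophage_marker_within_radius_assigns(self):
        scene = scene_stub({"Clec4f": "Clec4f"})
        nuclei = [Component(1, (0.0, 0.0), 10)]
        spots = {"Clec4f": [Component(1, (9.0, 0.0), 4)]}
        calls = call_cells(scene, nuclei, spots)
        assert calls[0].resolved_type == "Mac"

    def test_tcell_marker_outside_radius_not_assigned(self):
        scene = scene_stub({"Cd3": "Cd3"})
        nuclei = [Component(1, (0.0, 0.0), 10)]
        spots = {"Cd3": [Component(1, (6.0, 0.0), 4)]}
        calls = call_cells(scene, nuclei, spots)
        assert calls[0].resolved_type == "unassigned"

    def test_boundary_is_inclusive(self):
        scene = scene_stub({"Cd3": "Cd3"})
        nuclei = [Component(1, (0.0, 0.0), 10)]
        spots = {"Cd3": [Component(1, (5.0, 0.0), 4)]}
        assert call_cells(scene, nuclei, spots)[0].resolved_type == "T"

    def test_unknown_channel_rejected(self):
        scene = scene_stub({})
        with pytest.raises(ValueError, match="channel_map"):
            call_cells(scene, [], {"mystery": []})

    def test_spots_at_fraction_of_radius_type_perfectly(self):
        # macrophage spots at 0.8x the 10 um radius assign; T spots at
        # 1.2x the 5 um radius do not
        scene = scene_stub({"Spp1": "Spp1", "Clec4f": "Clec4f", "Cd3": "Cd3"})
        nuclei = [Component(1, (20.0, 20.0), 10),
                  Component(2, (60.0, 60.0), 10)]
        spots = {
            "Spp1": [Component(1, (28.0, 20.0), 4)],    # 8 um = 0.8 * 10
            "Clec4f": [Component(1, (20.0, 28.0), 4)],
            "Cd3": [Component(1, (66.0, 60.0), 4)],     # 6 um = 1.2 * 5
        }
        calls = call_cells(scene, nuclei, spots)
        assert calls[0].resolved_type == "Spp1+ Mac"
        assert calls[0].double_positive
        assert calls[1].resolved_type == "unassigned"


class TestDistanceReport:
    def test_nearest_tumor_three_four_five(self):
        cell = CellCall(centroid_um=(0.0, 0.0), nucleus_component_id=1)
        tumors = [CellCall((30.0, 40.0), 2, resolved_type="tumor"),
                  CellCall((60.0, 80.0), 3, resolved_type="tumor")]
        rep = distance_report([cell], tumors)
        assert rep.nearest_tumor_um.iloc[0] == pytest.approx(50.0)

    def test_colocated_tumor_distance_zero(self):
        cell = CellCall((5.0, 5.0), 1)
        tumor = CellCall((5.0, 5.0), 2, resolved_type="tumor")
        rep = distance_report([cell], [tumor])
        assert rep.nearest_tumor_um.iloc[0] == 0.0

    def test_pairwise_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(6)
        calls = [CellCall(tuple(xy), i) for i, xy in
                 enumerate(rng.uniform(0, 100, (20, 2)))]
        rep = distance_report(calls, [CellCall((1.0, 1.0), 99,
                                               resolved_type="tumor")])
        pts = np.array([c.centroid_um for c in calls])
        oracle = np.array([[np.hypot(*(p - q)) for q in pts] for p in pts])
        assert np.abs(rep.pairwise_um - oracle).max() <= 1e-9

    def test_matrix_symmetric_zero_diagonal_triangle(self):
        rng = np.random.default_rng(7)
        calls = [CellCall(tuple(xy), i) for i, xy in
                 enumerate(rng.uniform(0, 50, (15, 2)))]
        d = distance_report(calls, [CellCall((0.0, 0.0), 99,
                                             resolved_type="tumor")]).pairwise_um
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        n = len(calls)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_no_tumor_calls_warns(self):
        with pytest.warns(UserWarning, match="tumor"):
            rep = distance_report([CellCall((0.0, 0.0), 1)], [])
        assert rep.nearest_tumor_um is None


class TestEndToEnd:
    def test_typing_accuracy_and_median_recovery(self):
        scene, truth = simulate_fish(example_fish_config(seed=4))
        calls, tumors, rep = quantify_scene(scene, threshold=0.5)
        cent, planted, idx = match_calls_to_truth(calls, truth)
        assert all(calls[j].resolved_type == t
                   for j, t in zip(idx, truth["true_type"]))
        truth_med = truth.groupby("true_type")["nearest_tumor_um"].median()
        for t, med in truth_med.items():
            assert rep.median_by_type[t] == pytest.approx(
                med, abs=scene.pixel_size_um)

    def test_double_positive_pairs_share_nucleus_at_zero(self):
        scene, _ = simulate_fish(example_fish_config(seed=4))
        _, _, rep = quantify_scene(scene, threshold=0.5)
        assert len(rep.double_positive_pairs) > 0
        assert (rep.double_positive_pairs["distance_um"] == 0.0).all()

    def test_translation_invariance(self):
        cfg = example_fish_config(seed=5, image_size=(300, 300))
        scene, _ = simulate_fish(cfg)
        shifted = FishScene(
            channels={k: np.roll(np.roll(v, 13, axis=0), 7, axis=1)
                      for k, v in scene.channels.items()},
            pixel_size_um=scene.pixel_size_um,
            channel_map=scene.channel_map,
        )
        _, _, rep_a = quantify_scene(scene, threshold=0.5)
        _, _, rep_b = quantify_scene(shifted, threshold=0.5)
        assert np.allclose(np.sort(rep_a.nearest_tumor_um),
                           np.sort(rep_b.nearest_tumor_um), atol=1e-6)
        assert np.allclose(rep_a.median_by_type.sort_index(),
                           rep_b.median_by_type.sort_index(), atol=1e-6)
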