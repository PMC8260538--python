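"""Centroid NMS, nearest-centroid grouping, and the per-frame pipeline."""

import numpy as np
import pytest

from surgseg.scene import PredictionBundle
from surgseg.targets import build_targets
from surgseg.inference import (InferenceConfig, extract_centroids,
                               assign_instances, predict_frame)
from surgseg.synthetic import SynthConfig, generate_scene
from surgseg.network import ModelConfig, build_model


class TestExtractCentroids:
    def test_single_isolated_peak(self):
        hm = np.zeros((10, 12), np.float32)
        hm[4, 7] = 0.9
        assert extract_centroids(hm) == [(4, 7, pytest.approx(0.9))]

    def test_cap_at_max_centroids(self):
        hm = np.zeros((20, 30), np.float32)
        for i, (r, c) in enumerate([(2, 2), (2, 12), (2, 22), (10, 2),
                                    (10, 12), (10, 22)]):
            hm[r, c] = 0.5 + 0.05 * i
        out = extract_centroids(hm)
        assert len(out) == 4
        scores = [s for _, _, s in out]
        assert scores == sorted(scores, reverse=True)

    def test_all_zero_map_gives_empty_list(self):
        assert extract_centroids(np.zeros((8, 8), np.float32)) == []

    def test_threshold_is_strict(self):
        hm = np.zeros((8, 8), np.float32)
        hm[2, 2] = 0.1
        assert extract_centroids(hm, InferenceConfig(peak_threshold=0.1)) == []

    def test_score_ties_break_lexicographically(self):
        hm = np.zeros((12, 12), np.float32)
        hm[8, 3] = 0.5
        hm[2, 9] = 0.5
        out = extract_centroids(hm, InferenceConfig(max_centroids=1))
        assert out == [(2, 9, pytest.approx(0.5))]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            extract_centroids(np.zeros((4, 4)), InferenceConfig(nms_window=4))


class TestAssignInstances:
    def test_background_stays_zero(self):
        fg = np.zeros((6, 6), bool)
        fg[2, 2] = True
        out = assign_instances(fg, np.zeros((6, 6, 2), np.float32),
                               [(2, 2, 1.0)])
        assert out[2, 2] == 1 and out.sum() == 1

    def test_equidistant_tie_goes_to_first_centroid(self):
        fg = np.zeros((5, 9), bool)
        fg[2, 4] = True  # exactly between (2,0) and (2,8)
        out = assign_instances(fg, np.zeros((5, 9, 2), np.float32),
                               [(2, 0, 0.9), (2, 8, 0.8)])
        assert out[2, 4] == 1

    def test_empty_centroid_list_yields_background(self):
        fg = np.ones((4, 4), bool)
        out = assign_instances(fg, np.zeros((4, 4, 2), np.float32), [])
        assert out.max() == 0

    def test_matches_exhaustive_search_on_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            fg = rng.random((16, 20)) < 0.4
            off = rng.normal(0, 3, (16, 20, 2)).astype(np.float32)
            k = int(rng.integers(1, 5))
            cents = [(int(rng.integers(16)), int(rng.integers(20)),
                      float(rng.random())) for _ in range(k)]
            got = assign_instances(fg, off, cents)
            for r in range(16):
                for c in range(20):
                    if not fg[r, c]:
                        assert got[r, c] == 0
                        continue
                    ar = r - off[r, c, 0]
                    ac = c - off[r, c, 1]
                    d = [np.hypot(ar - cr, ac - cc) for cr, cc, _ in cents]
                    assert got[r, c] == int(np.argmin(d)) + 1

    def test_ground_truth_round_trip(self):
        scene = generate_scene(SynthConfig(n_instruments=(2, 4)), 99)
        tb = build_targets(scene, sigma=3.0)
        ids = sorted(tb.centroid_list)
        cents = [(tb.centroid_list[i][0], tb.centroid_list[i][1], 1.0)
                 for i in ids]
        got = assign_instances(tb.foreground_mask, tb.offset_target, cents)
        for pos, i in enumerate(ids, start=1):
            m = scene.instance_map == i
            assert (got[m] == pos).all()


class TestPredictFrame:
    def test_structure_and_cap(self):
        model = build_model(ModelConfig(preset="tiny", init_seed=0))
        scene = generate_scene(SynthConfig(n_instruments=(1, 3)), 5)
        res = predict_frame(model, scene.image)
        ids = set(np.unique(res.instance_map)) - {0}
        assert ids == set(res.class_probs)
        assert len(res.centroids) <= 4
        for i in ids:
            assert res.class_probs[i].sum() == pytest.approx(1.0, abs=1e-5)
            assert res.class_label[i] == int(res.class_probs[i].argmax()) + 1

    def test_deterministic(self):
        model = build_model(ModelConfig(preset="tiny", init_seed=1))
        scene = generate_scene(SynthConfig(n_instruments=(1, 3)), 6)
        a = predict_frame(model, scene.image)
        b = predict_frame(model, scene.image)
        assert np.array_equal(a.instance_map, b.instance_map)
        assert a.centroids == b.centroids

    def test_oracle_predictions_reproduce_ground_truth(self, monkeypatch):
        """With heads stubbed to ground-truth targets and a perfect
        classifier, the pipeline returns the GT instances and types."""
        scene = generate_scene(SynthConfig(n_instruments=(2, 3)), 21)
        tb = build_targets(scene, sigma=3.0)
        onehot_parts = (tb.part_target[..., None] ==
                        np.arange(5)).astype(np.float32)
        pb = PredictionBundle(
            part_logits=np.log(onehot_parts + 1e-9),
            part_probs=onehot_parts,
            offsets=tb.offset_target,
            heatmap=tb.heatmap_target,
            f_seg=np.zeros(scene.shape + (32,), np.float32),
        )
        import surgseg.inference as inf
        monkeypatch.setattr(inf, "forward", lambda model, image: pb)

        def perfect_classifier(model, f_seg, mask, prior=None):
            overlaps = {i: (mask & (scene.instance_map == i)).sum()
                        for i in scene.instance_ids}
            gid = max(overlaps, key=overlaps.get)
            out = np.zeros(7, np.float32)
            out[scene.types[gid] - 1] = 1.0
            return out
        monkeypatch.setattr(inf, "classify_instance", perfect_classifier)

        model = build_model(ModelConfig(preset="tiny", init_seed=0))
        res = predict_frame(model, scene.image)
        assert set(np.unique(res.instance_map)) - {0} == \
            set(range(1, len(scene.instance_ids) + 1))
        # every GT instance maps to one predicted id with the right type
        for gid in scene.instance_ids:
            m = scene.instance_map == gid
            pred_ids = np.unique(res.instance_map[m])
            assert len(pred_ids) == 1
            assert res.class_label[int(pred_ids[0])] == scene.types[gid]

    def test_never_fails_on_empty_scene(self):
        model = build_model(ModelConfig(preset="tiny", init_seed=0))
        img = np.zeros((64, 80, 3), np.float32)
        res = predict_frame(model, img)  # untrained: any count, must not raise
        assert res.instance_map.shape == (64, 80)
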