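"""Network architecture algebra, loss, gradients, training contracts."""

import numpy as np
import pandas as pd
import pytest

from pupanet import (NetworkSpec, TrainConfig, classify_nearest_centroid,
                     contrastive_loss, embed_set, forward, init_weights, train)
from pupanet.network import (ModelError, TrainingDivergedError, _backward_full,
                             _contrastive_grad, _conv_forward, _forward_full)
from pupanet.synthetic import SpecimenImage


class TestArchitecture:
    def test_layer_shape_algebra_matches_published_table(self):
        spec = NetworkSpec()
        assert spec.layer_shapes() == [
            (1, 28, 28), (10, 25, 25), (10, 12, 12),
            (20, 9, 9), (20, 4, 4), (320,), (2,),
        ]
        assert spec.flatten_len() == 320

    def test_forward_trace_reports_intermediate_shapes(self, rng):
        spec = NetworkSpec()
        weights = init_weights(spec, seed=3)
        emb, shapes = forward(spec, weights, rng.uniform(size=(28, 28)), trace=True)
        assert emb.shape == (2,)
        assert shapes == [(10, 25, 25), (10, 12, 12), (20, 9, 9), (20, 4, 4), (320,)]

    def test_parameter_count_by_enumeration(self):
        spec = NetworkSpec()
        assert spec.n_parameters() == 4032
        weights = init_weights(spec, seed=0)
        assert sum(w.size for w in weights.values()) == 4032

    def test_zero_weights_give_zero_embedding(self, rng):
        spec = NetworkSpec()
        weights = {k: np.zeros_like(v) for k, v in init_weights(spec, 0).items()}
        emb = forward(spec, weights, rng.uniform(size=(28, 28)))
        assert np.allclose(emb, 0.0)

    def test_conv_matches_nested_loop_oracle(self, rng):
        x = rng.uniform(size=(1, 1, 6, 6))
        W = rng.uniform(size=(1, 1, 3, 3))
        b = rng.uniform(size=(1,))
        out, _ = _conv_forward(x, W, b)
        expected = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                expected[i, j] = (x[0, 0, i:i + 3, j:j + 3] * W[0, 0]).sum() + b[0]
        assert np.allclose(out[0, 0], expected, atol=1e-12)

    def test_wrong_weight_shapes_rejected(self, rng):
        spec = NetworkSpec()
        weights = init_weights(spec, 0)
        weights["W2"] = weights["W2"][:, :5]
        with pytest.raises(ModelError, match="W2"):
            forward(spec, weights, rng.uniform(size=(28, 28)))


class TestContrastiveLoss:
    def test_same_pair_identical_embeddings_zero(self):
        e = np.array([0.3, -0.7])
        assert contrastive_loss(e, e, True) == 0.0

    def test_different_pair_beyond_margin_zero(self):
        a, b = np.array([0.0, 0.0]), np.array([2.0, 0.0])
        assert contrastive_loss(a, b, False, margin=1.0) == 0.0

    def test_different_pair_inside_margin_hand_value(self):
        a, b = np.array([0.0, 0.0]), np.array([0.4, 0.0])
        assert contrastive_loss(a, b, False, margin=1.0) == pytest.approx(0.36)

    def test_gradients_match_central_differences(self, rng):
        """Analytic backprop through a toy spec agrees with numerical
        differentiation to 1e-4 relative error."""
        spec = NetworkSpec(in_size=14, kernel=3, conv1_filters=2,
                           conv2_filters=3, embed_dim=2)
        weights = init_weights(spec, seed=7)
        x = rng.uniform(size=(4, 1, 14, 14))  # 2 pairs
        same = np.array([True, False])

        def loss_of(w):
            cache = _forward_full(spec, w, x)
            ea, eb = cache["emb"][:2], cache["emb"][2:]
            return contrastive_loss(ea, eb, same, margin=1.0)

        cache = _forward_full(spec, weights, x)
        ea, eb = cache["emb"][:2], cache["emb"][2:]
        da, db = _contrastive_grad(ea, eb, same, 1.0)
        grads = _backward_full(spec, weights, cache, np.concatenate([da, db]))

        h = 1e-6
        for name in weights:
            flat = weights[name].ravel()
            idxs = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + h
                up = loss_of(weights)
                flat[i] = orig - h
                down = loss_of(weights)
                flat[i] = orig
                num = (up - down) / (2 * h)
                ana = grads[name].ravel()[i]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7), name


def _tiny_set():
    rng = np.random.default_rng(0)
    images, rows = [], []
    for g, offset in [("a", 0.2), ("b", 0.7)]:
        for i in range(3):
            px = np.clip(offset + 0.05 * rng.uniform(size=(28, 28)), 0, 1)
            sid = f"{g}{i}"
            images.append(SpecimenImage(sid, g, "hairy", px))
            rows.append({"specimen_id": sid, "group": g, "substrate": "hairy"})
    return images, pd.DataFrame(rows)


class TestTraining:
    def test_same_seeds_give_identical_weights_and_logs(self):
        images, manifest = _tiny_set()
        cfg = TrainConfig(n_rounds=2, pairs_per_round=32, batch_size=8,
                          init_seed=5, shuffle_seed=6)
        m1 = train(images, manifest, cfg)
        m2 = train(images, manifest, cfg)
        assert m1.weights_digest() == m2.weights_digest()
        pd.testing.assert_frame_equal(m1.log, m2.log)

    def test_round_mean_loss_non_increasing_on_separable_data(self, small_model):
        by_round = small_model.log.groupby("round")["loss"].mean()
        assert all(b <= a + 0.02 for a, b in zip(by_round, by_round[1:]))

    def test_single_group_rejected(self):
        images, manifest = _tiny_set()
        sub = manifest[manifest["group"] == "a"].reset_index(drop=True)
        with pytest.raises(ValueError, match="2 groups"):
            train([i for i in images if i.group == "a"], sub, TrainConfig())

    def test_divergent_learning_rate_raises(self):
        images, manifest = _tiny_set()
        cfg = TrainConfig(n_rounds=2, pairs_per_round=32, batch_size=8,
                          optimizer="sgd", lr=1e18)
        with pytest.raises(TrainingDivergedError, match="round"):
            train(images, manifest, cfg)

    def test_save_load_round_trip(self, small_model, tmp_path):
        path = tmp_path / "model.json"
        small_model.save(path)
        from pupanet import TrainedModel
        loaded = TrainedModel.load(path)
        for k in small_model.weights:
            assert np.allclose(loaded.weights[k], small_model.weights[k])


class TestEmbedAndClassify:
    def test_singleton_group_centroid_equals_score(self, small_model, small_set):
        prepped, _ = small_set
        one_each = [next(im for im in prepped if im.group == g)
                    for g in sorted({im.group for im in prepped})]
        space = embed_set(small_model, one_each)
        cols = [c for c in space.scores.columns if c.startswith("score_")]
        merged = space.scores.merge(space.centroids, on="group", suffixes=("", "_c"))
        for c in cols:
            assert np.allclose(merged[c], merged[f"{c}_c"])

    def test_identical_images_identical_scores(self, small_model, small_set):
        prepped, _ = small_set
        twin = SpecimenImage("twin", prepped[0].group, "hairy", prepped[0].pixels)
        space = embed_set(small_model, [prepped[0], twin])
        m = space.score_matrix()
        assert np.allclose(m[0], m[1])

    def test_centroids_equal_arithmetic_mean_oracle(self, small_model, small_set):
        prepped, manifest = small_set
        space = embed_set(small_model, prepped)
        m = space.score_matrix()
        g = space.scores["group"].to_numpy()
        for _, row in space.centroids.iterrows():
            cols = [c for c in space.centroids.columns if c.startswith("score_")]
            assert np.allclose(row[cols].to_numpy().astype(float),
                               m[g == row["group"]].mean(axis=0), atol=1e-6)

    def test_query_at_centroid_assigned_to_that_group(self, small_model, small_set):
        prepped, _ = small_set
        space = embed_set(small_model, prepped)
        cols = [c for c in space.centroids.columns if c.startswith("score_")]
        res = classify_nearest_centroid(space, space.centroids[cols].to_numpy())
        assert list(res["group"]) == list(space.centroids["group"])

    def test_equidistant_tie_goes_to_first_label_with_flag(self):
        from pupanet import FeatureSpace
        scores = pd.DataFrame({"specimen_id": ["x", "y"], "group": ["b", "a"],
                               "score_1": [1.0, -1.0], "score_2": [0.0, 0.0]})
        cents = pd.DataFrame({"group": ["a", "b"], "score_1": [-1.0, 1.0],
                              "score_2": [0.0, 0.0]})
        space = FeatureSpace(scores, cents)
        res = classify_nearest_centroid(space, np.array([[0.0, 0.0]]))
        assert res["group"].iloc[0] == "a"
        assert bool(res["tie"].iloc[0])

    def test_assignments_match_exhaustive_distance_oracle(self, rng):
        from pupanet import FeatureSpace
        cents = pd.DataFrame({"group": ["a", "b", "c"],
                              "score_1": [0.0, 3.0, -2.0],
                              "score_2": [0.0, 1.0, 2.0]})
        space = FeatureSpace(pd.DataFrame(columns=["specimen_id", "group",
                                                   "score_1", "score_2"]), cents)
        q = rng.normal(size=(50, 2), scale=3)
        res = classify_nearest_centroid(space, q)
        c = cents[["score_1", "score_2"]].to_numpy()
        for i in range(50):
            dists = [np.hypot(*(q[i] - c[j])) for j in range(3)]
            assert res["group"].iloc[i] == cents["group"].iloc[int(np.argmin(dists))]

    def test_empty_centroids_rejected(self):
        from pupanet import FeatureSpace
        space = FeatureSpace(pd.DataFrame(), pd.DataFrame(columns=["group"]))
        with pytest.raises(ValueError, match="centroid"):
            classify_nearest_centroid(space, np.zeros((1, 2)))
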