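"""Cascaded fern regression: augmentation, features, training, prediction."""

import numpy as np
import pytest

from irisloc import ferns, synth, training
from irisloc.ferns import Hyperparams, augment, select_features, train_fern
from irisloc.shapes import interocular_distance, shape_box


def _random_shapes(n, seed=0):
    rng = np.random.default_rng(seed)
    shapes = [rng.uniform(0, 100, size=(29, 2)) + rng.uniform(0, 50, 2) for _ in range(n)]
    boxes = [shape_box(s, margin=0.1) for s in shapes]
    return shapes, boxes


class TestAugment:
    def test_twenty_inits_per_sample(self):
        shapes, boxes = _random_shapes(100)
        idx, inits = augment(shapes, boxes, n_inits=20, seed=1)
        assert len(inits) == 2000
        assert np.bincount(idx).tolist() == [20] * 100

    def test_single_init_keeps_count(self):
        shapes, boxes = _random_shapes(30)
        idx, inits = augment(shapes, boxes, n_inits=1, seed=1)
        assert len(inits) == 30

    def test_deterministic(self):
        shapes, boxes = _random_shapes(25)
        _, a = augment(shapes, boxes, n_inits=10, seed=42)
        _, b = augment(shapes, boxes, n_inits=10, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_rejects_too_few_samples(self):
        shapes, boxes = _random_shapes(5)
        with pytest.raises(ValueError):
            augment(shapes, boxes, n_inits=20)


class TestIndexPixels:
    def _setup(self):
        rng = np.random.default_rng(0)
        mean = rng.uniform(100, 300, size=(29, 2))
        lm = rng.integers(0, 29, size=10).astype(np.intp)
        off = rng.normal(0, 10.0, size=(10, 2))
        return mean, lm, off

    def test_identity_transform(self):
        mean, lm, off = self._setup()
        pos = ferns.index_pixels(lm, off, mean, mean, (1000, 1000))
        assert np.allclose(pos, mean[lm] + off, atol=1e-9)

    def test_translation_equivariance(self):
        mean, lm, off = self._setup()
        pos0 = ferns.index_pixels(lm, off, mean, mean, (1000, 1000))
        pos1 = ferns.index_pixels(lm, off, mean + [10, 0], mean, (1000, 1000))
        assert np.allclose(pos1, pos0 + [10, 0], atol=1e-9)

    def test_scaling_doubles_offsets(self):
        mean, lm, off = self._setup()
        pos0 = ferns.index_pixels(lm, off, mean, mean, (1000, 1000))
        pos2 = ferns.index_pixels(lm, off, 2 * mean, mean, (1000, 1000))
        # offsets around each landmark double in length
        assert np.allclose(pos2 - 2 * mean[lm], 2 * (pos0 - mean[lm]), atol=1e-9)

    def test_degenerate_shape_raises(self):
        mean, lm, off = self._setup()
        with pytest.raises(ValueError):
            ferns.index_pixels(lm, off, np.ones((29, 2)), mean, (100, 100))


class TestSelectFeatures:
    def test_perfect_pair_found_by_brute_force_agreement(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(200, 12))
        target_pair = (4, 9)
        resid = (V[:, 4] - V[:, 9])[:, None] * np.ones((1, 6))
        ids, thresholds = select_features(V, resid, F=1, rng=np.random.default_rng(0))
        # brute-force max |corr| over all ordered pairs
        proj = resid @ np.ones(6)  # any direction: resid rank-1
        best, best_pair = -1.0, None
        for a in range(12):
            for b in range(12):
                if a == b:
                    continue
                f = V[:, a] - V[:, b]
                c = abs(np.corrcoef(f, proj)[0, 1])
                if c > best:
                    best, best_pair = c, (a, b)
        assert set(best_pair) == set(target_pair)
        assert set(ids[0]) == set(target_pair)
        feat = V[:, ids[0][0]] - V[:, ids[0][1]]
        assert feat.min() < thresholds[0] < feat.max()

    def test_zero_features_empty(self):
        V = np.random.default_rng(0).normal(size=(10, 5))
        ids, th = select_features(V, V[:, :2], F=0, rng=np.random.default_rng(0))
        assert ids.shape == (0, 2) and th.shape == (0,)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        V = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 4))
        a = select_features(V, Y, F=3, rng=np.random.default_rng(9))
        b = select_features(V, Y, F=3, rng=np.random.default_rng(9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_all_constant_features_raise(self):
        V = np.ones((20, 6))
        with pytest.raises(ferns.DegenerateDataError):
            select_features(V, np.random.default_rng(0).normal(size=(20, 4)), F=2,
                            rng=np.random.default_rng(0))


class TestTrainFern:
    def test_single_bin_beta_zero_gives_exact_mean(self):
        rng = np.random.default_rng(1)
        V = rng.normal(size=(40, 6))
        resid = rng.normal(size=(40, 8))
        fern = train_fern(V, resid, F=0, beta=0.0)
        assert np.allclose(fern.bin_outputs[0], resid.mean(axis=0), atol=1e-12)

    def test_singleton_bin_shrinks_to_residual_over_1001(self):
        # two samples with a hugely separated feature -> one per bin
        V = np.array([[0.0, 10.0], [10.0, 0.0]])
        resid = np.array([[2002.0, 0.0], [0.0, -3003.0]])
        rng = np.random.default_rng(0)
        fern = train_fern(V, resid, F=1, beta=1000.0, rng=rng)
        occupied = sorted(set(fern.bin_of(V)))
        assert len(occupied) == 2
        outs = fern.bin_outputs[occupied]
        mags = sorted(np.abs(outs).max(axis=1))
        assert mags[0] == pytest.approx(2002.0 / 1001.0, rel=1e-12)
        assert mags[1] == pytest.approx(3003.0 / 1001.0, rel=1e-12)

    def test_beta_infinity_limit_zeroes_outputs(self):
        rng = np.random.default_rng(2)
        V = rng.normal(size=(30, 5))
        resid = rng.normal(size=(30, 6))
        fern = train_fern(V, resid, F=2, beta=1e15, rng=np.random.default_rng(4))
        assert np.all(np.abs(fern.bin_outputs) < 1e-10)

    def test_shrinkage_monotone_in_beta(self):
        rng = np.random.default_rng(6)
        V = rng.normal(size=(60, 5))
        resid = rng.normal(size=(60, 6))
        norms = []
        for beta in (0.0, 10.0, 1000.0, 1e6):
            fern = train_fern(V, resid, F=2, beta=beta, rng=np.random.default_rng(8))
            norms.append(np.linalg.norm(fern.bin_outputs))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestCascade:
    def test_training_error_trace_non_increasing(self, face_model):
        trace = face_model.error_trace
        assert len(trace) == face_model.hyperparams.T
        assert np.all(np.diff(trace) <= 1e-9)

    def test_heldout_parameter_recovery(self, face_model, heldout_faces):
        images, shapes = heldout_faces
        errs = []
        for img, truth in zip(images, shapes):
            box = ferns.landmark_face_box(truth)
            pred = ferns.predict(img, box, face_model, n_init=5, seed=3)
            errs.append(
                np.mean(np.linalg.norm(pred - truth, axis=1)) / interocular_distance(truth)
            )
        assert np.median(errs) < 0.05

    def test_identical_seed_identical_model(self, tmp_path):
        specs = synth.sample_face_specs(12, seed=2)
        data = [synth.render_face(s) for s in specs]
        hp = Hyperparams(T=2, K=5, P=30, F=3, n_inits=5)
        kwargs = dict(hyperparams=hp, seed=123)
        m1 = training.train_model([d[0] for d in data], [d[1] for d in data], **kwargs)
        m2 = training.train_model([d[0] for d in data], [d[1] for d in data], **kwargs)
        ferns.save_model(tmp_path / "a.npz", m1)
        ferns.save_model(tmp_path / "b.npz", m2)
        with np.load(tmp_path / "a.npz") as a, np.load(tmp_path / "b.npz") as b:
            assert sorted(a.files) == sorted(b.files)
            for k in a.files:
                assert np.array_equal(a[k], b[k]), k

    def test_stage_composition_is_exact(self, face_model, heldout_faces):
        # running t stages then applying stage t+1 equals running t+1 stages
        import copy

        img, truth = heldout_faces[0][0], heldout_faces[1][0]
        box = ferns.landmark_face_box(truth)
        t = 3
        m_t = copy.copy(face_model)
        m_t = ferns.CascadeModel(
            stages=face_model.stages[:t], mean_shape=face_model.mean_shape,
            hyperparams=face_model.hyperparams, rng_seed=face_model.rng_seed)
        m_t1 = ferns.CascadeModel(
            stages=face_model.stages[: t + 1], mean_shape=face_model.mean_shape,
            hyperparams=face_model.hyperparams, rng_seed=face_model.rng_seed)
        s_t = ferns.predict(img, box, m_t, n_init=1, seed=0, perturbation=0.0)
        m_last = ferns.CascadeModel(
            stages=[face_model.stages[t]], mean_shape=face_model.mean_shape,
            hyperparams=face_model.hyperparams, rng_seed=face_model.rng_seed)
        composed = ferns._run_cascade(np.asarray(img, dtype=np.float64), s_t, m_last)
        direct = ferns.predict(img, box, m_t1, n_init=1, seed=0, perturbation=0.0)
        assert np.array_equal(composed, direct)

    def test_multi_init_zero_perturbation_matches_single(self, face_model, heldout_faces):
        img, truth = heldout_faces[0][0], heldout_faces[1][0]
        box = ferns.landmark_face_box(truth)
        one = ferns.predict(img, box, face_model, n_init=1, seed=0)
        five = ferns.predict(img, box, face_model, n_init=5, seed=0, perturbation=0.0)
        assert np.allclose(one, five, atol=1e-12)

    def test_translation_equivariance(self, face_model):
        spec = synth.FaceFixtureSpec(seed=5, jitter_sigma=0.5, brow_weight=2.0)
        img0, lm0 = synth.render_face(spec)
        from dataclasses import replace

        img1, lm1 = synth.render_face(replace(spec, translation=(5.0, 0.0)))
        assert np.allclose(lm1, lm0 + [5, 0])
        b0 = ferns.landmark_face_box(lm0)
        b1 = (b0[0] + 5, b0[1], b0[2], b0[3])
        p0 = ferns.predict(img0, b0, face_model, n_init=1, seed=0)
        p1 = ferns.predict(img1, b1, face_model, n_init=1, seed=0)
        assert np.max(np.abs(p1 - (p0 + [5, 0]))) <= 0.5

    def test_box_outside_image_raises(self, face_model):
        with pytest.raises(ValueError):
            ferns.predict(np.zeros((50, 50)), (200, 200, 40, 40), face_model)


class TestSerialization:
    def test_round_trip_preserves_model_and_predictions(self, face_model, heldout_faces,
                                                        tmp_path):
        path = tmp_path / "model.npz"
        ferns.save_model(path, face_model)
        loaded = ferns.load_model(path)
        assert loaded.hyperparams == face_model.hyperparams
        assert np.array_equal(loaded.mean_shape, face_model.mean_shape)
        assert np.array_equal(loaded.error_trace, face_model.error_trace)
        for s0, s1 in zip(face_model.stages, loaded.stages):
            assert np.array_equal(s0.anchor_offsets, s1.anchor_offsets)
            for f0, f1 in zip(s0.ferns, s1.ferns):
                assert np.array_equal(f0.bin_outputs, f1.bin_outputs)
        for side in ("left", "right"):
            assert np.array_equal(loaded.aisc[side]["omega"],
                                  face_model.aisc[side]["omega"])
        img, truth = heldout_faces[0][0], heldout_faces[1][0]
        box = ferns.landmark_face_box(truth)
        assert np.array_equal(
            ferns.predict(img, box, face_model, seed=1),
            ferns.predict(img, box, loaded, seed=1),
        )
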