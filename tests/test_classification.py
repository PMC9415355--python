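"""Augmentation geometry, scorer training contract, per-image decisions."""

import numpy as np
import pytest

from invertid import classification as cl
from invertid.synthetic import Frame

from conftest import block_frame


class TestResize:
    def test_downscale_to_224(self):
        out = cl.resize_image(Frame(np.full((496, 496), 0.5)), 224)
        assert out.pixels.shape == (224, 224)

    def test_identity_when_already_square(self):
        frame = block_frame(height=224, width=224)
        out = cl.resize_image(frame, 224)
        np.testing.assert_array_equal(out.pixels, frame.pixels)

    def test_uniform_stays_uniform(self):
        out = cl.resize_image(Frame(np.full((100, 60), 0.37)), 32)
        np.testing.assert_allclose(out.pixels, 0.37, atol=1e-9)

    def test_invalid_side(self):
        with pytest.raises(ValueError):
            cl.resize_image(block_frame(), 0)


class TestShear:
    def test_zero_shear_is_identity(self):
        p = cl.ShearParams(0.0, 0.0)
        assert cl.shear_coords(3.2, -1.5, p) == (3.2, -1.5)

    def test_explicit_mapping(self):
        p = cl.ShearParams(0.5, -0.25)
        x, y = cl.shear_coords(2.0, 4.0, p)
        assert x == pytest.approx(2.0 + 0.5 * 4.0)
        assert y == pytest.approx(-0.25 * 2.0 + 4.0)

    def test_collinearity_preserved(self):
        """Shear is affine: collinear points stay collinear."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = cl.ShearParams(*rng.uniform(-0.5, 0.5, 2))
            a = rng.uniform(-10, 10, 2)
            d = rng.uniform(-5, 5, 2)
            pts = [a, a + d, a + 2.7 * d]
            out = [np.array(cl.shear_coords(*q, p)) for q in pts]
            u, v = out[1] - out[0], out[2] - out[0]
            assert abs(u[0] * v[1] - u[1] * v[0]) < 1e-9

    def test_unit_square_area_is_determinant(self):
        """|1 - lx*ly| is the area scale factor of the mapping."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            lx, ly = rng.uniform(-0.5, 0.5, 2)
            p = cl.ShearParams(lx, ly)
            corners = [(0, 0), (1, 0), (1, 1), (0, 1)]
            mapped = [cl.shear_coords(x, y, p) for x, y in corners]
            area = 0.0  # shoelace
            for i in range(4):
                x0, y0 = mapped[i]
                x1, y1 = mapped[(i + 1) % 4]
                area += x0 * y1 - x1 * y0
            assert abs(abs(area) / 2 - abs(1 - lx * ly)) < 1e-9

    def test_degenerate_shear_rejected(self):
        with pytest.raises(ValueError):
            cl.ShearParams(2.0, 0.5)  # lx*ly == 1, not invertible


class TestAugment:
    def test_noop_config_returns_input(self):
        frame = block_frame()
        cfg = cl.AugmentConfig(
            rotation_range=0.0,
            allow_horizontal_flip=False,
            allow_vertical_flip=False,
            shear_range=(0.0, 0.0),
        )
        out = cl.augment_image(frame, cfg, draw_seed=3)
        np.testing.assert_array_equal(out.pixels, frame.pixels)

    def test_deterministic_under_draw_seed(self):
        frame = block_frame()
        cfg = cl.AugmentConfig()
        a = cl.augment_image(frame, cfg, draw_seed=11)
        b = cl.augment_image(frame, cfg, draw_seed=11)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_horizontal_flip_is_involution(self):
        frame = block_frame(block=(5, 20, 8, 40))
        once = cl.apply_augment(frame, flip_horizontal=True)
        twice = cl.apply_augment(once, flip_horizontal=True)
        np.testing.assert_array_equal(twice.pixels, frame.pixels)
        assert not np.array_equal(once.pixels, frame.pixels)

    def test_output_shape_preserved(self):
        frame = block_frame(height=60, width=80)
        out = cl.augment_image(frame, cl.AugmentConfig(), draw_seed=5)
        assert out.pixels.shape == (60, 80)


def separable_frames(n_per_class, rng, sides=(8, 22)):
    """Two classes of dark squares with disjoint size ranges."""
    frames, labels = [], []
    for label, side in enumerate(sides):
        for _ in range(n_per_class):
            r = int(rng.integers(5, 30))
            c = int(rng.integers(5, 30))
            s = side + int(rng.integers(-2, 3))
            frames.append(block_frame(64, 64, (r, r + s, c, c + s)))
            labels.append(label)
    return frames, labels


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    frames, labels = separable_frames(12, rng)
    val_frames, val_labels = separable_frames(4, rng)
    cfg = cl.TrainConfig(pixel_side=8, max_epochs=50)
    model = cl.ReferenceScorer(cfg).fit(frames, labels, val_frames, val_labels)
    return model, val_frames, val_labels


class TestReferenceScorer:
    def test_separable_classes_reach_perfect_validation(self, fitted):
        model, _, _ = fitted
        accs = [e["val_accuracy"] for e in model.training_log]
        assert max(accs) == 1.0

    def test_returned_weights_are_validation_loss_argmin(self, fitted):
        model, _, _ = fitted
        losses = [e["val_loss"] for e in model.training_log]
        assert model.best_epoch == int(np.argmin(losses))

    def test_score_vector_shape_and_purity(self, fitted):
        model, val_frames, _ = fitted
        s1 = model.score(val_frames[0])
        s2 = model.score(val_frames[0])
        assert s1.shape == (2,)
        np.testing.assert_array_equal(s1, s2)
        assert np.isfinite(s1).all()

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(3)
        frames, labels = separable_frames(6, rng)
        vf, vl = separable_frames(2, np.random.default_rng(4))
        cfg = cl.TrainConfig(pixel_side=8, max_epochs=30)
        m1 = cl.ReferenceScorer(cfg).fit(frames, labels, vf, vl)
        m2 = cl.ReferenceScorer(cfg).fit(frames, labels, vf, vl)
        np.testing.assert_array_equal(m1.W, m2.W)

    def test_single_class_rejected(self):
        frames = [block_frame() for _ in range(4)]
        with pytest.raises(ValueError):
            cl.ReferenceScorer(cl.TrainConfig(pixel_side=8)).fit(
                frames, [0, 0, 0, 0], frames[:1], [0]
            )

    def test_empty_validation_rejected(self):
        frames = [block_frame() for _ in range(4)]
        with pytest.raises(ValueError):
            cl.ReferenceScorer(cl.TrainConfig(pixel_side=8)).fit(
                frames, [0, 0, 1, 1], [], []
            )

    def test_unfitted_score_is_state_error(self):
        with pytest.raises(RuntimeError):
            cl.ReferenceScorer().score(block_frame())

    def test_scores_linear_in_features(self, fitted):
        """For the linear scorer a feature shift moves scores by W @ (d/sd)."""
        model, val_frames, _ = fitted
        x = model.extractor(val_frames[0])
        delta = np.zeros_like(x)
        delta[:16] = 0.1
        shifted = model.score_matrix((x + delta)[None, :])[0]
        base = model.score_matrix(x[None, :])[0]
        expected = model.W @ (delta / model._sd)
        np.testing.assert_allclose(shifted - base, expected, atol=1e-10)

    def test_save_load_roundtrip(self, fitted, tmp_path):
        model, val_frames, _ = fitted
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = cl.ReferenceScorer.load(path)
        np.testing.assert_array_equal(loaded.score(val_frames[0]),
                                      model.score(val_frames[0]))
        assert loaded.class_labels == model.class_labels

    def test_augmented_training_keeps_labels(self):
        """Augmentation multiplies images, never changes labels or classes."""
        rng = np.random.default_rng(5)
        frames, labels = separable_frames(4, rng)
        vf, vl = separable_frames(2, np.random.default_rng(6))
        cfg = cl.TrainConfig(pixel_side=8, max_epochs=10, n_augment=2, seed=1)
        model = cl.ReferenceScorer(cfg).fit(frames, labels, vf, vl)
        assert model.class_labels == [0, 1]


class TestPredictImage:
    def test_argmax(self):
        assert cl.predict_image([0.1, 3.2, -1.0]) == 1

    def test_tie_breaks_to_lowest_index(self):
        assert cl.predict_image([2.0, 2.0]) == 0

    def test_shift_invariance(self):
        s = np.array([0.3, -1.2, 0.9])
        assert cl.predict_image(s) == cl.predict_image(s + 17.5)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            cl.predict_image([0.1, np.nan])
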