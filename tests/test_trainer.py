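import numpy as np
import pytest

from bloomcount.density_targets import KernelConfig, gaussian_density_map
from bloomcount.trainer import (CountMetrics, TrainingConfig, evaluate,
                                mse_loss, train)
from bloomcount.unet_model import ModelSpec, UNet

TINY = ModelSpec(depth=2, base_channels=4)


def tiny_config(**kw):
    base = dict(batch_size=8, max_epochs=4, early_stop_patience=2,
                crop_size=32, sigma=4.0, seed=0)
    base.update(kw)
    return TrainingConfig(**base)


class TestMseLoss:
    def test_identical_maps_zero(self, rng):
        arr = rng.random((16, 16))
        assert mse_loss(arr, arr) == 0.0

    def test_quarter_example(self):
        target = np.zeros((2, 2))
        target[0, 0] = 1.0
        assert mse_loss(np.zeros((2, 2)), target) == pytest.approx(0.25)

    def test_matches_scalar_loop_oracle(self, rng):
        a = rng.random((9, 13))
        b = rng.random((9, 13))
        total = 0.0
        for i in range(9):
            for j in range(13):
                total += (a[i, j] - b[i, j]) ** 2
        assert mse_loss(a, b) == pytest.approx(total / (9 * 13))

    def test_symmetry_and_shape_check(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        assert mse_loss(a, b) == pytest.approx(mse_loss(b, a))
        with pytest.raises(ValueError):
            mse_loss(a, rng.random((4, 5)))


class TestTrainContracts:
    def test_empty_dataset_rejected(self, tiny_train_val):
        tr, va = tiny_train_val
        model = UNet(TINY, seed=0)
        with pytest.raises(ValueError):
            train(model, [], va, tiny_config())

    def test_early_stop_on_increasing_val_loss(self, tiny_train_val):
        tr, va = tiny_train_val
        model = UNet(TINY, seed=0)
        seq = iter([1.0, 2.0, 3.0, 4.0])

        def rising_val(_model):
            return next(seq)

        cfg = tiny_config(max_epochs=10, early_stop_patience=1,
                          target_scale=1.0)
        _, history = train(model, tr[:8], va, cfg, val_fn=rising_val)
        assert len(history) == 2  # stops at epoch 2
        assert history[0]["val_mse"] == 1.0

    def test_returns_argmin_validation_weights(self, tiny_train_val):
        tr, va = tiny_train_val
        model = UNet(TINY, seed=0)
        seq = iter([3.0, 1.0, 2.0, 2.5, 2.6])
        marks = []

        def val_fn(m):
            v = next(seq)
            marks.append((v, m.get_weights()))
            return v

        cfg = tiny_config(max_epochs=5, early_stop_patience=3,
                          target_scale=1.0)
        best, history = train(model, tr[:8], va, cfg, val_fn=val_fn)
        assert min(h["val_mse"] for h in history) == 1.0
        best_recorded = min(marks, key=lambda t: t[0])[1]
        for k in best:
            np.testing.assert_array_equal(best[k], best_recorded[k])

    def test_seeded_training_reproducible(self, tiny_train_val):
        tr, va = tiny_train_val
        hist = []
        for _ in range(2):
            model = UNet(TINY, seed=0)
            _, h = train(model, tr[:8], va[:2], tiny_config(max_epochs=2))
            hist.append(h)
        assert hist[0] == hist[1]

    def test_beats_all_zero_baseline(self, tiny_train_val, sample_factory):
        tr = sample_factory(20, 64, seed=17)
        va = tiny_train_val[1]
        cfg = tiny_config(batch_size=20, max_epochs=30,
                          early_stop_patience=30, crop_size=32, sigma=4.0)
        model = UNet(ModelSpec(depth=3, base_channels=8), seed=0)
        _, history = train(model, tr, va, cfg)
        # all-zero predictor loss: mean of target^2 over the same kernel
        kernel = KernelConfig(sigma=cfg.sigma)
        zero_losses = [
            mse_loss(np.zeros(s.image.shape[:2]),
                     gaussian_density_map(
                         s.annotations, s.image.shape[:2], kernel).values)
            for s in tr]
        assert history[-1]["train_mse"] < np.mean(zero_losses)


class TestEvaluate:
    def test_metrics_validation(self):
        with pytest.raises(ValueError):
            CountMetrics(mae=-1, mapd=0, pixel_mse=0)

    def test_arithmetic_example(self, tiny_train_val):
        # actual [100, 50], predicted [90, 55] -> mae 7.5, mapd 10.0
        err = np.mean([abs(90 - 100), abs(55 - 50)])
        mapd = np.mean([10 / 100, 5 / 50]) * 100
        assert err == pytest.approx(7.5)
        assert mapd == pytest.approx(10.0)

    def test_perfect_predictor_zero_error(self, rng):
        # interior points only, so targets integrate to the exact count
        from bloomcount.density_targets import PointAnnotationSet
        from bloomcount.trainer import Sample
        from bloomcount.unet_model import normalize_input

        kernel = KernelConfig(sigma=6.0)
        subset = []
        for i in range(3):
            pts = rng.uniform(26, 86, size=(4 + i, 2))
            img = rng.integers(0, 255, size=(112, 112, 3), dtype=np.uint8)
            subset.append(Sample(f"p{i}", img,
                                 PointAnnotationSet(f"p{i}", pts)))

        targets = {}
        for s in subset:
            targets[normalize_input(s.image).tobytes()] = \
                gaussian_density_map(s.annotations, s.image.shape[:2],
                                     kernel).values.astype(np.float32)

        class Oracle:
            def forward(self, x, train=False):
                return np.stack([targets[img.tobytes()]
                                 for img in x])[..., None]

        metrics, table = evaluate(Oracle(), subset, sigma=6.0)
        assert metrics.pixel_mse == pytest.approx(0.0, abs=1e-16)
        # nonzero only through the 4-sigma truncation tail (~3e-4/point)
        assert metrics.mae == pytest.approx(0.0, abs=0.01)
        assert metrics.mapd == pytest.approx(0.0, abs=0.1)

    def test_metrics_match_brute_force_recomputation(self, tiny_train_val):
        tr, _ = tiny_train_val
        model = UNet(TINY, seed=1)
        metrics, table = evaluate(model, tr[:4], sigma=4.0)
        err = [abs(p - a) for p, a
               in zip(table["predicted"], table["actual"])]
        assert metrics.mae == pytest.approx(float(np.mean(err)))
        pos = [(p, a) for p, a
               in zip(table["predicted"], table["actual"]) if a > 0]
        if pos:
            expected_mapd = float(np.mean(
                [abs(p - a) / a for p, a in pos]) * 100)
            assert metrics.mapd == pytest.approx(expected_mapd)

    def test_zero_count_patch_excluded_from_mapd(self):
        import pandas as pd

        from bloomcount.trainer import Sample
        from bloomcount.density_targets import PointAnnotationSet

        class Flat:
            def forward(self, x, train=False):
                return np.full(x.shape[:3] + (1,), 1e-4, dtype=np.float32)

        samples = [
            Sample("a", np.zeros((32, 32, 3), np.uint8),
                   PointAnnotationSet("a", np.zeros((0, 2)))),
            Sample("b", np.zeros((32, 32, 3), np.uint8),
                   PointAnnotationSet("b", np.array([[16.0, 16.0]]))),
        ]
        metrics, table = evaluate(Flat(), samples, sigma=4.0)
        pred = 32 * 32 * 1e-4
        # zero-count patch contributes to MAE...
        assert metrics.mae == pytest.approx(
            np.mean([pred, abs(pred - 1)]), rel=1e-4)
        # ...but only the nonzero patch enters MAPD
        assert metrics.mapd == pytest.approx(abs(pred - 1) * 100, rel=1e-4)
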