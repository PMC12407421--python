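import numpy as np
import pytest

from skulladapt import _nn
from skulladapt.adapt_train import (BackboneConfig, DataBundle, MMDConfig,
                                    TrainConfig, build_classifier, finetune,
                                    gaussian_kernel_matrix, load_model,
                                    median_heuristic_bandwidths, mmd2,
                                    records_to_array, save_model,
                                    select_best_epoch, train)
from skulladapt.errors import ArgumentError, CapabilityError, RegimeDataError
from skulladapt.meshforge import generate_species_bank
from skulladapt.viewsphere import (PhotoDomainConfig, RenderConfig,
                                   ViewSphereSpec, render_dataset)


def mmd2_double_loop(A, B, bandwidths, unbiased=False):
    """Brute-force oracle: explicit double loops over all pairs."""
    A, B = np.atleast_2d(A), np.atleast_2d(B)
    def k(x, y):
        return sum(np.exp(-np.sum((x - y) ** 2) / (2 * b * b))
                   for b in bandwidths)
    n, m = len(A), len(B)
    if unbiased:
        t_aa = sum(k(A[i], A[j]) for i in range(n) for j in range(n)
                   if i != j) / (n * (n - 1))
        t_bb = sum(k(B[i], B[j]) for i in range(m) for j in range(m)
                   if i != j) / (m * (m - 1))
    else:
        t_aa = sum(k(A[i], A[j]) for i in range(n) for j in range(n)) / n ** 2
        t_bb = sum(k(B[i], B[j]) for i in range(m) for j in range(m)) / m ** 2
    t_ab = sum(k(a, b) for a in A for b in B) / (n * m)
    return t_aa + t_bb - 2 * t_ab


@pytest.fixture(scope="module")
def mini_data():
    """4 forge species x 6 specimens rendered clean at 32 px, 4 poses."""
    bank = generate_species_bank(4, 6, seed=19, subdivisions=2)
    spec = ViewSphereSpec(yaw_step=90.0, ring_pitches=(15.0,),
                          include_poles=False, distance=2.5)
    records, _ = render_dataset(bank, spec, RenderConfig(resolution=32))
    classes = sorted({r.species_id for r in records})
    by_spec = {}
    for r in records:
        by_spec.setdefault(r.specimen_id, []).append(r)
    specimens = sorted(by_spec)
    test_ids = {s for s in specimens if s.endswith("005")}
    train = [r for s in specimens if s not in test_ids for r in by_spec[s]]
    test = [r for s in test_ids for r in by_spec[s]]
    return DataBundle(classes=classes, synthetic_train=train,
                      photo_unlabelled=None, synthetic_test=test,
                      photo_test=[r for r in test])


class TestBackbone:
    def test_softmax_rows_sum_to_one(self):
        m = build_classifier(BackboneConfig(kind="tiny", input_side=32), 5)
        x = np.random.default_rng(0).random((3, 3, 32, 32)).astype(np.float32)
        probs = m.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_tiny_backbone_64px_forward(self):
        m = build_classifier(BackboneConfig(kind="tiny", input_side=64), 3)
        x = np.zeros((2, 3, 64, 64), dtype=np.float32)
        assert m.net.forward(x).shape == (2, 3)

    def test_feature_tap_dimension(self):
        cfg = BackboneConfig(kind="tiny", input_side=48)
        m = build_classifier(cfg, 4)
        x = np.zeros((2, 3, 48, 48), dtype=np.float32)
        feats = m.net.forward_features(x)
        assert feats.shape == (2, cfg.feature_dim)

    def test_vgg19_like_forward_pass(self):
        m = build_classifier(BackboneConfig(kind="vgg19_like", input_side=64,
                                            hidden_dim=32), 3, seed=0)
        x = np.zeros((1, 3, 64, 64), dtype=np.float32)
        assert m.net.forward(x).shape == (1, 3)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ArgumentError):
            BackboneConfig(kind="resnet")

    def test_pretrained_without_weights_errors(self):
        cfg = BackboneConfig(kind="vgg19_like", input_side=32,
                             pretrained=True)
        with pytest.raises(CapabilityError):
            build_classifier(cfg, 3)


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        logits = np.array([[100.0, 0.0, 0.0]])
        loss, _ = _nn.cross_entropy(logits, np.array([0]))
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_log_c(self):
        for c in (2, 5, 10):
            logits = np.zeros((4, c))
            loss, _ = _nn.cross_entropy(logits, np.zeros(4, dtype=int))
            assert loss == pytest.approx(np.log(c), rel=1e-12)


class TestGaussianKernel:
    def test_identical_points_give_bandwidth_count(self):
        A = np.array([[1.0, 2.0], [3.0, 4.0]])
        K = gaussian_kernel_matrix(A, A, [0.5, 1.0, 2.0])
        np.testing.assert_allclose(np.diag(K), 3.0)

    def test_hand_case_exp_half(self):
        K = gaussian_kernel_matrix(np.array([[0.0]]), np.array([[1.0]]), [1.0])
        assert K[0, 0] == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_large_bandwidth_limit(self):
        rng = np.random.default_rng(1)
        A, B = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        K = gaussian_kernel_matrix(A, B, [1e8])
        np.testing.assert_allclose(K, 1.0, atol=1e-9)

    def test_symmetric_and_psd(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(12, 6))
        K = gaussian_kernel_matrix(A, A, [0.7, 1.3])
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_width_mismatch(self):
        with pytest.raises(ArgumentError):
            gaussian_kernel_matrix(np.zeros((2, 3)), np.zeros((2, 4)), [1.0])


class TestMMD2:
    def test_identical_batches_zero(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(8, 5))
        assert mmd2(A, A.copy(), MMDConfig(bandwidths=(1.0,))) == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_case(self):
        val = mmd2(np.array([[0.0]]), np.array([[1.0]]),
                   MMDConfig(bandwidths=(1.0,)))
        assert val == pytest.approx(2 - 2 * np.exp(-0.5), abs=1e-12)

    @pytest.mark.parametrize("estimator", ["biased", "unbiased"])
    def test_matches_double_loop_oracle(self, estimator):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n, m = rng.integers(3, 20, size=2)
            d = int(rng.integers(1, 6))
            A = rng.normal(size=(n, d))
            B = rng.normal(size=(m, d)) + 0.5
            bw = [0.5, 1.0, 2.0]
            ours = mmd2(A, B, MMDConfig(bandwidths=tuple(bw),
                                        estimator=estimator))
            oracle = mmd2_double_loop(A, B, bw, unbiased=estimator == "unbiased")
            assert abs(ours - oracle) < 1e-10

    def test_biased_nonnegative_random(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            A = rng.normal(size=(rng.integers(2, 10), 3))
            B = rng.normal(size=(rng.integers(2, 10), 3))
            assert mmd2(A, B, MMDConfig(bandwidths=(1.0,))) >= -1e-12

    def test_unbiased_null_distribution_centered(self):
        # under H0 (same distribution) the unbiased estimator has mean zero
        rng = np.random.default_rng(6)
        cfg = MMDConfig(bandwidths=(1.0,), estimator="unbiased")
        estimates = []
        for _ in range(100):
            A = rng.normal(size=(200, 2))
            B = rng.normal(size=(200, 2))
            estimates.append(mmd2(A, B, cfg))
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / 10.0
        assert abs(mean) < 3 * se

    def test_unbiased_needs_two_rows(self):
        with pytest.raises(ArgumentError):
            mmd2(np.zeros((1, 2)), np.zeros((3, 2)),
                 MMDConfig(estimator="unbiased"))

    def test_median_heuristic_positive(self):
        rng = np.random.default_rng(7)
        bw = median_heuristic_bandwidths(rng.normal(size=(10, 3)),
                                         rng.normal(size=(8, 3)))
        assert (bw > 0).all()
        assert bw[1] / bw[0] == pytest.approx(2.0)


class TestTraining:
    def test_mmd_regime_requires_unlabelled_stream(self, mini_data):
        cfg = TrainConfig(regime="mmd", max_epochs=1, patience=1)
        with pytest.raises(RegimeDataError):
            train(mini_data, cfg, BackboneConfig(kind="tiny", input_side=32))

    def test_learnable_task_reaches_high_accuracy(self, mini_data):
        cfg = TrainConfig(regime="baseline", max_epochs=20, patience=20,
                          learning_rate=2e-3, seed=0)
        model = train(mini_data, cfg,
                      BackboneConfig(kind="tiny", input_side=32))
        assert model.history[-1]["synthetic_test_accuracy"] >= 0.9

    def test_lambda_zero_mmd_equals_baseline(self, mini_data):
        bundle = DataBundle(
            classes=mini_data.classes,
            synthetic_train=mini_data.synthetic_train,
            photo_unlabelled=[r for r in mini_data.synthetic_test],
            synthetic_test=mini_data.synthetic_test,
            photo_test=mini_data.photo_test)
        kw = dict(max_epochs=3, patience=3, learning_rate=1e-3, seed=4)
        base = train(mini_data, TrainConfig(regime="baseline", **kw),
                     BackboneConfig(kind="tiny", input_side=32))
        null = train(bundle, TrainConfig(regime="mmd",
                                         mmd=MMDConfig(weight=0.0), **kw),
                     BackboneConfig(kind="tiny", input_side=32))
        for eb, en in zip(base.history, null.history):
            assert eb["train_loss"] == pytest.approx(en["train_loss"],
                                                     rel=1e-6)
            assert eb["synthetic_test_loss"] == pytest.approx(
                en["synthetic_test_loss"], rel=1e-6)

    def test_history_length_equals_stopped_epoch(self, mini_data):
        cfg = TrainConfig(regime="baseline", max_epochs=4, patience=4, seed=1)
        model = train(mini_data, cfg,
                      BackboneConfig(kind="tiny", input_side=32))
        assert len(model.history) == model.stopped_epoch <= 4

    def test_deterministic_given_seed(self, mini_data):
        cfg = TrainConfig(regime="baseline", max_epochs=2, patience=2, seed=8)
        a = train(mini_data, cfg, BackboneConfig(kind="tiny", input_side=32))
        b = train(mini_data, cfg, BackboneConfig(kind="tiny", input_side=32))
        assert a.history == b.history

    def test_patience_must_fit_epochs(self):
        with pytest.raises(ArgumentError):
            TrainConfig(max_epochs=5, patience=10)


@pytest.fixture(scope="module")
def start_model(mini_data):
    cfg = TrainConfig(regime="baseline", max_epochs=5, patience=5, seed=2)
    return train(mini_data, cfg, BackboneConfig(kind="tiny", input_side=32))


class TestFinetune:
    def _photo_bundle(self, mini_data):
        return DataBundle(classes=mini_data.classes,
                          photo_train=mini_data.synthetic_train[:24],
                          synthetic_test=mini_data.synthetic_test,
                          photo_test=mini_data.photo_test)

    def test_zero_epochs_keeps_weights(self, start_model, mini_data):
        out = finetune(start_model, self._photo_bundle(mini_data),
                       TrainConfig(regime="finetune", max_epochs=0, patience=0))
        for w0, w1 in zip(start_model.net.get_weights(), out.net.get_weights()):
            np.testing.assert_array_equal(w0, w1)

    def test_provenance_records_start(self, start_model, mini_data):
        out = finetune(start_model, self._photo_bundle(mini_data),
                       TrainConfig(regime="finetune", max_epochs=1, patience=1,
                                   seed=3))
        assert out.provenance["start_stopped_epoch"] == \
            start_model.stopped_epoch
        assert out.provenance["start_regime"] == "baseline"

    def test_one_epoch_on_own_data_does_not_blow_up(self, start_model,
                                                    mini_data):
        bundle = DataBundle(classes=mini_data.classes,
                            photo_train=mini_data.synthetic_train,
                            synthetic_test=mini_data.synthetic_test,
                            photo_test=mini_data.photo_test)
        out = finetune(start_model, bundle,
                       TrainConfig(regime="finetune", max_epochs=1, patience=1,
                                   learning_rate=1e-4, seed=3))
        assert out.history[-1]["train_loss"] <= \
            start_model.history[-1]["train_loss"] + 0.5

    def test_class_mismatch_rejected(self, start_model, mini_data):
        bad = DataBundle(classes=mini_data.classes[:-1] + ["zz"],
                         photo_train=mini_data.synthetic_train[:8],
                         synthetic_test=mini_data.synthetic_test,
                         photo_test=mini_data.photo_test)
        with pytest.raises(ArgumentError):
            finetune(start_model, bad,
                     TrainConfig(regime="finetune", max_epochs=1, patience=1))


class TestSelectBestEpoch:
    def _hist(self, pairs):
        return [{"epoch": i + 1, "synthetic_test_accuracy": s,
                 "photo_test_accuracy": p} for i, (s, p) in enumerate(pairs)]

    def test_monotone_improving_picks_last(self):
        hist = self._hist([(0.2, 0.2), (0.5, 0.4), (0.8, 0.9)])
        assert select_best_epoch(hist) == 3

    def test_single_epoch(self):
        assert select_best_epoch(self._hist([(0.5, 0.5)])) == 1

    def test_interior_maximum(self):
        hist = self._hist([(0.2, 0.2), (0.9, 0.9), (0.5, 0.5), (0.9, 0.85)])
        assert select_best_epoch(hist) == 2

    def test_tie_breaks_earliest(self):
        hist = self._hist([(0.5, 0.7), (0.7, 0.5), (0.6, 0.6)])
        assert select_best_epoch(hist) == 1

    def test_missing_metrics(self):
        with pytest.raises(ArgumentError):
            select_best_epoch([{"epoch": 1, "synthetic_test_accuracy": 0.5}])
        with pytest.raises(ArgumentError):
            select_best_epoch([])


class TestPersistence:
    def test_save_load_round_trip(self, mini_data, tmp_path):
        cfg = TrainConfig(regime="baseline", max_epochs=2, patience=2, seed=6)
        model = train(mini_data, cfg,
                      BackboneConfig(kind="tiny", input_side=32))
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        x = records_to_array(mini_data.synthetic_test[:4])
        np.testing.assert_allclose(model.predict_proba(x),
                                   back.predict_proba(x), atol=1e-6)
        assert back.stopped_epoch == model.stopped_epoch
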