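import numpy as np
import pytest

from skulladapt import evalsuite
from skulladapt.adapt_train import BackboneConfig, build_classifier
from skulladapt.errors import ArgumentError, UndefinedSilhouetteError
from skulladapt.evalsuite import (Embedding2D, confusion_matrix, embed_tsne,
                                  evaluate_accuracy, gradcam, gradcam_score,
                                  score_gradcam_sample, silhouette_scores)
from skulladapt.viewsphere import CameraPose, ImageRecord


class StubModel:
    """Duck-typed model with prescribed predictions."""

    def __init__(self, classes, predictions):
        self.classes = list(classes)
        self._pred = np.asarray(predictions)

    def predict(self, records):
        return self._pred[:len(records)]

    def labels_for(self, records):
        index = {c: i for i, c in enumerate(self.classes)}
        return np.array([index[r.species_id] for r in records])


def _records(species_sequence):
    out = []
    for i, sp in enumerate(species_sequence):
        px = np.zeros((8, 8, 3))
        mask = np.zeros((8, 8), dtype=bool)
        out.append(ImageRecord(px, mask, sp, f"{sp}_{i}", "synthetic",
                               CameraPose(0, 0, 3.0)))
    return out


def silhouette_double_loop(points, labels):
    """Brute-force silhouette oracle: explicit loops over every pair."""
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(points)
    svals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            svals.append(0.0)  # singleton convention
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
        b = np.inf
        for other in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            b = min(b, np.mean([np.linalg.norm(points[i] - points[j])
                                for j in members]))
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


class TestAccuracy:
    def test_perfect_predictor(self):
        recs = _records(["a", "b", "a", "b"])
        model = StubModel(["a", "b"], [0, 1, 0, 1])
        assert evaluate_accuracy(model, recs) == 1.0

    def test_constant_predictor_on_balanced_set(self):
        recs = _records(["a", "b", "c"] * 4)
        model = StubModel(["a", "b", "c"], [0] * 12)
        assert evaluate_accuracy(model, recs) == pytest.approx(1 / 3)

    def test_three_of_five_correct(self):
        recs = _records(["a", "a", "a", "b", "b"])
        model = StubModel(["a", "b"], [0, 0, 1, 1, 0])
        assert evaluate_accuracy(model, recs) == pytest.approx(0.6)

    def test_empty_set_rejected(self):
        with pytest.raises(ArgumentError):
            evaluate_accuracy(StubModel(["a"], []), [])


class TestConfusion:
    def test_perfect_predictor_identity(self):
        recs = _records(["a", "b", "c", "a", "b", "c"])
        model = StubModel(["a", "b", "c"], [0, 1, 2, 0, 1, 2])
        np.testing.assert_allclose(confusion_matrix(model, recs), np.eye(3))

    def test_constant_predictor_one_hot_rows(self):
        recs = _records(["a", "b", "b"])
        model = StubModel(["a", "b"], [0, 0, 0])
        mat = confusion_matrix(model, recs)
        np.testing.assert_allclose(mat, [[1, 0], [1, 0]])

    def test_row_normalization(self):
        recs = _records(["a", "a", "a", "a", "b"])
        model = StubModel(["a", "b"], [0, 0, 0, 1, 1])
        mat = confusion_matrix(model, recs)
        np.testing.assert_allclose(mat[0], [0.75, 0.25])

    def test_rows_sum_to_one_or_zero(self):
        recs = _records(["a", "b"] * 5)
        model = StubModel(["a", "b", "c"],
                          np.random.default_rng(0).integers(0, 3, 10))
        mat = confusion_matrix(model, recs)
        sums = mat.sum(axis=1)
        assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))
        assert sums[2] == 0  # class c never appears as a true label

    def test_accuracy_consistency(self):
        # accuracy equals the label-frequency-weighted diagonal of the
        # row-normalized confusion matrix
        rng = np.random.default_rng(1)
        recs = _records(rng.choice(["a", "b", "c"], 30))
        model = StubModel(["a", "b", "c"], rng.integers(0, 3, 30))
        y = model.labels_for(recs)
        mat = confusion_matrix(model, recs)
        weights = np.bincount(y, minlength=3) / len(y)
        assert evaluate_accuracy(model, recs) == pytest.approx(
            float(np.sum(weights * np.diag(mat))))


class TestTsne:
    def test_shape_and_metadata(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(30, 8))
        labels = ["a", "b"] * 15
        domains = ["synthetic"] * 15 + ["photo"] * 15
        emb = embed_tsne(feats, labels, domains, seed=1)
        assert emb.points.shape == (30, 2)
        assert list(emb.labels) == labels

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(25, 6))
        labels = np.arange(25) % 3
        domains = ["synthetic"] * 25
        a = embed_tsne(feats, labels, domains, seed=7)
        b = embed_tsne(feats, labels, domains, seed=7)
        np.testing.assert_array_equal(a.points, b.points)

    def test_separated_blobs_stay_separated(self):
        rng = np.random.default_rng(3)
        blob_a = rng.normal(size=(40, 10)) * 0.1
        blob_b = rng.normal(size=(40, 10)) * 0.1 + 8.0
        feats = np.concatenate([blob_a, blob_b])
        labels = np.array([0] * 40 + [1] * 40)
        emb = embed_tsne(feats, labels, ["synthetic"] * 80, seed=0)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(emb.points, labels) > 0.5

    def test_too_few_points(self):
        with pytest.raises(ArgumentError):
            embed_tsne(np.zeros((4, 3)), [0] * 4, ["synthetic"] * 4, seed=0)


class TestSilhouette:
    def test_well_separated_clusters_near_one(self):
        rng = np.random.default_rng(4)
        pts = np.concatenate([rng.normal(size=(30, 2)) * 0.05,
                              rng.normal(size=(30, 2)) * 0.05 + 20.0])
        labels = np.array([0] * 30 + [1] * 30)
        emb = Embedding2D(pts, labels, np.array(["synthetic"] * 60), seed=0)
        _, _, combined = silhouette_scores(emb)
        assert combined > 0.9

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(200, 2))
        labels = rng.integers(0, 2, 200)
        emb = Embedding2D(pts, labels, np.array(["photo"] * 200), seed=0)
        _, photo, combined = silhouette_scores(emb)
        assert abs(combined) < 0.1

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            n = int(rng.integers(10, 50))
            pts = rng.normal(size=(n, 2))
            labels = rng.integers(0, 3, n)
            if len(set(labels.tolist())) < 2:
                continue
            emb = Embedding2D(pts, labels, np.array(["photo"] * n), seed=0)
            _, photo, combined = silhouette_scores(emb)
            assert abs(combined - silhouette_double_loop(pts, labels)) < 1e-12

    def test_identical_points_cluster_scores_one(self):
        # a(i) = 0 within the degenerate cluster, so s(i) = 1 for its points
        pts = np.array([[0.0, 0.0]] * 5 + [[10.0, 0.0], [10.0, 1.0],
                                           [11.0, 0.0]])
        labels = np.array([0] * 5 + [1] * 3)
        oracle = silhouette_double_loop(pts, labels)
        emb = Embedding2D(pts, labels, np.array(["photo"] * 8), seed=0)
        _, _, combined = silhouette_scores(emb)
        assert combined == pytest.approx(oracle, abs=1e-12)
        per_point_first_cluster = 1.0  # by the formula, since a(i)=0, b>0
        assert combined > 0.9  # dominated by the five perfect points

    def test_per_domain_and_combined_components(self):
        rng = np.random.default_rng(7)
        pts = np.concatenate([rng.normal(size=(20, 2)),
                              rng.normal(size=(20, 2)) + 5.0])
        labels = np.array([0] * 20 + [1] * 20)
        domains = np.array((["synthetic"] * 10 + ["photo"] * 10) * 2)
        syn, photo, combined = silhouette_scores(
            Embedding2D(pts, labels, domains, seed=0))
        for val in (syn, photo, combined):
            assert -1.0 <= val <= 1.0

    def test_single_label_subset_undefined(self):
        pts = np.random.default_rng(8).normal(size=(10, 2))
        emb = Embedding2D(pts, np.zeros(10, dtype=int),
                          np.array(["photo"] * 10), seed=0)
        with pytest.raises(UndefinedSilhouetteError):
            silhouette_scores(emb)

    def test_domain_offset_lowers_combined_score(self):
        # coincident domains: species clusters overlap across domains ->
        # combined close to per-domain; offset domains: each species splits
        # into two blobs -> combined drops (the domain-confusion signature)
        rng = np.random.default_rng(9)
        means = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float)
        def build(offset):
            pts, labels, domains = [], [], []
            for k, mu in enumerate(means):
                for dom, shift in (("synthetic", 0.0), ("photo", offset)):
                    p = rng.normal(size=(15, 2)) * 0.5 + mu + shift
                    pts.append(p)
                    labels += [k] * 15
                    domains += [dom] * 15
            return Embedding2D(np.concatenate(pts), np.array(labels),
                               np.array(domains), seed=0)
        syn_c, photo_c, combined_c = silhouette_scores(build(0.0))
        syn_o, photo_o, combined_o = silhouette_scores(build(4.0))
        assert combined_o < combined_c
        assert combined_c == pytest.approx(min(syn_c, photo_c), abs=0.05)
        assert combined_o < min(syn_o, photo_o)


@pytest.fixture(scope="module")
def tiny_model(rendered_specimen):
    model = build_classifier(BackboneConfig(kind="tiny", input_side=64), 3,
                             seed=0)
    model.classes = ["a", "b", "c"]
    return model


class TestGradcam:
    def test_shape_and_range(self, tiny_model, rendered_specimen):
        cam = gradcam(tiny_model, rendered_specimen)
        assert cam.shape == rendered_specimen.foreground_mask.shape
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_max_normalized(self, tiny_model, rendered_specimen):
        cam = gradcam(tiny_model, rendered_specimen)
        assert cam.max() == pytest.approx(1.0) or cam.max() == 0.0

    def test_positive_logit_scaling_invariance(self, tiny_model,
                                               rendered_specimen):
        cam_a = gradcam(tiny_model, rendered_specimen, target_class=1)
        final = tiny_model.net.classifier[-1]
        final.W *= 3.0
        final.b *= 3.0
        try:
            cam_b = gradcam(tiny_model, rendered_specimen, target_class=1)
        finally:
            final.W /= 3.0
            final.b /= 3.0
        np.testing.assert_allclose(cam_a, cam_b, atol=1e-5)


class TestGradcamScore:
    def _mask(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        return mask

    def test_all_hot_inside_scores_three(self):
        mask = self._mask()
        heat = np.where(mask, 1.0, 0.0)
        assert gradcam_score(heat, mask) == 3

    def test_all_hot_outside_scores_zero(self):
        mask = self._mask()
        heat = np.where(mask, 0.0, 1.0)
        assert gradcam_score(heat, mask) == 0

    def test_half_mass_inside_scores_one(self):
        mask = self._mask()
        heat = np.zeros((20, 20))
        heat[5:15, 5:10] = 1.0     # 50 hot pixels inside
        heat[5:15, 15:20] = 1.0    # 50 hot pixels outside
        assert gradcam_score(heat, mask) == 1

    def test_threshold_bins(self):
        mask = self._mask()
        heat = np.zeros((20, 20))
        heat[5:15, 5:12] = 1.0     # 70 inside
        heat[0:3, 0:10] = 1.0      # 30 outside -> f = 0.7 -> score 2
        assert gradcam_score(heat, mask) == 2

    def test_shape_mismatch(self):
        with pytest.raises(ArgumentError):
            gradcam_score(np.zeros((4, 4)), np.zeros((5, 5), dtype=bool))

    def test_all_zero_map_scores_zero(self):
        assert gradcam_score(np.zeros((20, 20)), self._mask()) == 0


class TestScoreSample:
    def test_crafted_scores_mean(self, monkeypatch, rendered_specimen):
        # 96 images focused in-mask, 4 at f = 0.7: mean (96*3 + 4*2)/100
        records = []
        for i in range(100):
            rec = ImageRecord(rendered_specimen.pixels.copy(),
                              rendered_specimen.foreground_mask.copy(),
                              "a", f"s{i}", "photo", CameraPose(0, 0, 3.0))
            records.append(rec)
        crafted = {}
        for i, rec in enumerate(records):
            heat = np.zeros_like(rec.foreground_mask, dtype=float)
            if i < 96:
                heat[rec.foreground_mask] = 1.0
            else:
                inside = np.argwhere(rec.foreground_mask)
                heat[tuple(inside[:70].T)] = 1.0
                heat[0:1, 0:30] = 1.0
            crafted[rec.specimen_id] = heat
        monkeypatch.setattr(evalsuite, "gradcam",
                            lambda model, rec, target_class=None:
                            crafted[rec.specimen_id])
        hist, mean = score_gradcam_sample(None, records, n=100, seed=0,
                                          mask_dilation_px=0)
        assert hist == {0: 0, 1: 0, 2: 4, 3: 96}
        assert mean == pytest.approx(2.96)

    def test_sample_too_large(self, tiny_model, rendered_specimen):
        with pytest.raises(ArgumentError):
            score_gradcam_sample(tiny_model, [rendered_specimen], n=5, seed=0)

    def test_full_sample_scores_each_once(self, monkeypatch,
                                          rendered_specimen):
        seen = []
        monkeypatch.setattr(
            evalsuite, "gradcam",
            lambda model, rec, target_class=None:
            seen.append(rec.specimen_id) or
            np.ones_like(rec.foreground_mask, dtype=float))
        records = [ImageRecord(rendered_specimen.pixels,
                               rendered_specimen.foreground_mask, "a",
                               f"s{i}", "photo", CameraPose(0, 0, 3.0))
                   for i in range(7)]
        score_gradcam_sample(None, records, n=7, seed=1, mask_dilation_px=0)
        assert sorted(seen) == sorted(r.specimen_id for r in records)
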