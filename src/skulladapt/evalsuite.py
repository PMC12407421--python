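"""Evaluation: accuracy, confusion matrices, domain-confusion analysis, Grad-CAM.

Domain confusion is read off a joint 2-D t-SNE embedding of the flattened
post-convolution features of both test sets: silhouette scores of the
ground-truth species clusters are reported for the synthetic-only subset, the
photo-only subset and the pooled embedding.  A feature extractor that maps
the two domains' class clusters on top of each other keeps the combined
silhouette close to the per-domain ones; domain-specific features drive the
combined score down.

Grad-CAM heatmaps localize the evidence behind a prediction.  Because the
renderer emits exact foreground masks, the manual focus-scoring rubric is
automated as mask overlap: the fraction of hot heatmap mass (above 50% of the
map maximum) inside the specimen silhouette is binned into a 0-3 score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from . import _nn
from .adapt_train import TrainedModel, records_to_array
from .errors import ArgumentError, CapabilityError, UndefinedSilhouetteError
from .viewsphere import PHOTO, SYNTHETIC, ImageRecord

__all__ = [
    "EvalReport",
    "Embedding2D",
    "evaluate_accuracy",
    "confusion_matrix",
    "embed_tsne",
    "silhouette_scores",
    "gradcam",
    "gradcam_score",
    "score_gradcam_sample",
    "evaluate_model",
]

DEFAULT_SCORE_THRESHOLDS = (0.3, 0.6, 0.9)   # bin edges for scores 1, 2, 3


@dataclass
class Embedding2D:
    """2-D embedding of image features with labels and domain tags."""

    points: np.ndarray
    labels: np.ndarray
    domains: np.ndarray
    seed: int

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.domains = np.asarray(self.domains)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ArgumentError("points must be (N, 2)")
        if not (len(self.points) == len(self.labels) == len(self.domains)):
            raise ArgumentError("points, labels, domains must align")
        if not np.all(np.isfinite(self.points)):
            raise ArgumentError("embedding coordinates must be finite")


@dataclass
class EvalReport:
    """Per-domain accuracy, confusion, silhouettes and Grad-CAM scores."""

    accuracy_synthetic: float
    accuracy_photo: float
    confusion_synthetic: np.ndarray
    confusion_photo: np.ndarray
    silhouette_synthetic: float | None = None
    silhouette_photo: float | None = None
    silhouette_combined: float | None = None
    gradcam_histogram: dict = field(default_factory=dict)
    gradcam_mean: float | None = None
    classes: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "accuracy_synthetic": self.accuracy_synthetic,
            "accuracy_photo": self.accuracy_photo,
            "confusion_synthetic": self.confusion_synthetic.tolist(),
            "confusion_photo": self.confusion_photo.tolist(),
            "silhouette_synthetic": self.silhouette_synthetic,
            "silhouette_photo": self.silhouette_photo,
            "silhouette_combined": self.silhouette_combined,
            "gradcam_histogram": {str(k): v for k, v in
                                  self.gradcam_histogram.items()},
            "gradcam_mean": self.gradcam_mean,
            "classes": list(self.classes),
        }


def evaluate_accuracy(model: TrainedModel, records) -> float:
    """Fraction of records whose argmax prediction matches the label."""
    if not len(records):
        raise ArgumentError("record set is empty")
    pred = model.predict(records)
    y = model.labels_for(records)
    return float((pred == y).mean())


def confusion_matrix(model: TrainedModel, records,
                     normalize: bool = True) -> np.ndarray:
    """Row-normalized confusion matrix (rows = true class, cols = predicted).

    Rows with at least one record sum to one; empty rows stay all-zero.
    """
    if not len(records):
        raise ArgumentError("record set is empty")
    c = len(model.classes)
    pred = model.predict(records)
    y = model.labels_for(records)
    mat = np.zeros((c, c))
    np.add.at(mat, (y, pred), 1.0)
    if normalize:
        sums = mat.sum(axis=1, keepdims=True)
        mat = np.divide(mat, sums, out=np.zeros_like(mat), where=sums > 0)
    return mat


def embed_tsne(features: np.ndarray, labels, domains, seed: int = 0,
               perplexity: float = 30.0) -> Embedding2D:
    """Joint 2-D t-SNE of a feature batch; deterministic given the seed.

    Perplexity is clamped below (N - 1) / 3 so small batches stay valid.
    """
    features = np.asarray(features, dtype=np.float64)
    n = len(features)
    if n < 5:
        raise ArgumentError("need at least 5 points to embed")
    perplexity = float(min(perplexity, max((n - 1) / 3.0, 2.0)))
    ts = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
              init="pca", max_iter=500)
    pts = ts.fit_transform(features)
    return Embedding2D(pts, np.asarray(labels), np.asarray(domains), seed)


def _silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    if len(np.unique(labels)) < 2:
        raise UndefinedSilhouetteError(
            "silhouette undefined for fewer than two labels")
    return float(silhouette_score(points, labels, metric="euclidean"))


def silhouette_scores(emb: Embedding2D) -> tuple[float, float, float]:
    """(synthetic, photo, combined) silhouettes of the species clusters.

    Each is the mean over points of ``(b - a) / max(a, b)`` with Euclidean
    distances on the 2-D embedding; clusters are the ground-truth species
    labels.  The per-domain scores use only that domain's points; the
    combined score pools both.
    """
    per_domain = {}
    for dom in (SYNTHETIC, PHOTO):
        sel = emb.domains == dom
        if not sel.any():
            per_domain[dom] = None
            continue
        per_domain[dom] = _silhouette(emb.points[sel], emb.labels[sel])
    combined = _silhouette(emb.points, emb.labels)
    return per_domain[SYNTHETIC], per_domain[PHOTO], combined


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

def gradcam(model: TrainedModel, img: ImageRecord,
            target_class: int | None = None) -> np.ndarray:
    """Gradient-weighted class activation map for one image, in [0, 1].

    Channel weights are the spatial means of the gradient of the target-class
    logit with respect to the final convolutional activations; the map is the
    rectified weighted channel sum, bilinearly upsampled to image size and
    max-normalized (an all-zero map stays all-zero).  The target defaults to
    the predicted class.
    """
    net = model.net
    if not net.trunk:
        raise CapabilityError("model exposes no convolutional tap")
    x = records_to_array([img])
    logits = net.forward(x)
    if target_class is None:
        target_class = int(logits.argmax(axis=1)[0])
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    dconv = net.backward_head(dlogits)        # (1, C, h, w)
    acts = net.conv_act                        # (1, C, h, w)
    weights = dconv.mean(axis=(2, 3))          # (1, C)
    cam = np.maximum((weights[:, :, None, None] * acts).sum(axis=1), 0.0)[0]
    h, w = img.foreground_mask.shape
    cam = _sk_resize(cam.astype(np.float64), (h, w), order=1,
                     anti_aliasing=False, preserve_range=True)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam


def gradcam_score(heatmap: np.ndarray, foreground_mask: np.ndarray,
                  thresholds=DEFAULT_SCORE_THRESHOLDS,
                  mask_dilation_px: int = 0) -> int:
    """Bin the in-mask fraction of hot heatmap mass into a 0-3 focus score.

    Hot pixels are those at or above 50% of the map maximum; ``f`` is the
    fraction of their total heat inside the foreground mask.  Default bins:
    score 3 for f >= 0.9, 2 for f >= 0.6, 1 for f >= 0.3, else 0.

    ``mask_dilation_px`` dilates the mask before the overlap is measured;
    evaluation pipelines set it to the heatmap's upsampling factor so that
    heat on the specimen outline, blurred by the coarse activation grid,
    still counts as specimen focus.
    """
    heatmap = np.asarray(heatmap, dtype=np.float64)
    if heatmap.shape != foreground_mask.shape:
        raise ArgumentError("heatmap and mask shapes differ")
    if mask_dilation_px > 0:
        from scipy import ndimage

        foreground_mask = ndimage.binary_dilation(
            foreground_mask, iterations=mask_dilation_px)
    t1, t2, t3 = thresholds
    peak = heatmap.max()
    if peak <= 0:
        return 0
    hot = heatmap >= 0.5 * peak
    total = heatmap[hot].sum()
    inside = heatmap[hot & foreground_mask].sum()
    f = inside / total if total > 0 else 0.0
    if f >= t3:
        return 3
    if f >= t2:
        return 2
    if f >= t1:
        return 1
    return 0


def score_gradcam_sample(model: TrainedModel, records, n: int = 100,
                         seed: int = 0,
                         thresholds=DEFAULT_SCORE_THRESHOLDS,
                         mask_dilation_px: int | None = None):
    """Score Grad-CAMs of a seeded sample (without replacement) of records.

    Returns ``(histogram over {0,1,2,3}, mean score)``.  By default the mask
    is dilated by the CAM upsampling factor (image side / activation-grid
    side); pass ``mask_dilation_px=0`` for the raw rubric.
    """
    if n > len(records):
        raise ArgumentError(f"sample size {n} exceeds {len(records)} records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(records), size=n, replace=False)
    scores = []
    for i in idx:
        rec = records[int(i)]
        cam = gradcam(model, rec)
        if mask_dilation_px is None:
            side = rec.foreground_mask.shape[0]
            cam_side = model.net.conv_act.shape[-1]
            mask_dilation_px = max(side // max(cam_side, 1), 0)
        scores.append(gradcam_score(cam, rec.foreground_mask, thresholds,
                                    mask_dilation_px=mask_dilation_px))
    hist = {s: int(np.sum(np.array(scores) == s)) for s in (0, 1, 2, 3)}
    return hist, float(np.mean(scores))


def evaluate_model(model: TrainedModel, synthetic_test, photo_test,
                   tsne_seed: int = 0, gradcam_n: int = 100,
                   gradcam_seed: int = 0,
                   thresholds=DEFAULT_SCORE_THRESHOLDS) -> EvalReport:
    """Full evaluation of one trained model on both test domains."""
    acc_s = evaluate_accuracy(model, synthetic_test)
    acc_p = evaluate_accuracy(model, photo_test)
    conf_s = confusion_matrix(model, synthetic_test)
    conf_p = confusion_matrix(model, photo_test)

    feats = np.concatenate([model.features(synthetic_test),
                            model.features(photo_test)], axis=0)
    labels = np.array([r.species_id for r in synthetic_test]
                      + [r.species_id for r in photo_test])
    domains = np.array([SYNTHETIC] * len(synthetic_test)
                       + [PHOTO] * len(photo_test))
    emb = embed_tsne(feats, labels, domains, seed=tsne_seed)
    sil_s, sil_p, sil_c = silhouette_scores(emb)

    n = min(gradcam_n, len(photo_test))
    hist, mean = score_gradcam_sample(model, photo_test, n=n,
                                      seed=gradcam_seed,
                                      thresholds=thresholds)
    return EvalReport(
        accuracy_synthetic=acc_s, accuracy_photo=acc_p,
        confusion_synthetic=conf_s, confusion_photo=conf_p,
        silhouette_synthetic=sil_s, silhouette_photo=sil_p,
        silhouette_combined=sil_c,
        gradcam_histogram=hist, gradcam_mean=mean,
        classes=list(model.classes))
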