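"""Classifier construction and domain-adaptive training regimes.

Six regimes cover the source-only / target-only / adaptation comparison:

``baseline``
    labelled synthetic renders only (source domain).
``photo_baseline`` / ``photo_subset``
    labelled photographs only (full training set, or the retained subset).
``mmd``
    labelled synthetic renders plus *unlabelled* photographs; each batch
    minimizes cross-entropy plus ``lambda * MMD^2`` between the two domains'
    flattened post-convolution features, pulling the feature distributions
    together without target labels.
``supplemented``
    labelled synthetic renders mixed with the labelled photograph subset.
``finetune``
    continues from the final MMD weights with cross-entropy on the labelled
    photograph subset.

Training uses Adam with early stopping: the monitored quantity is the
training-domain test loss (patience in consecutive non-improving epochs),
except for the supplemented and fine-tuned models whose final epoch is chosen
to maximize the mean of the two domains' test accuracies.  The weights of the
best monitored epoch are restored at the end of training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .datapipe import AugmentConfig, augment
from .errors import (ArgumentError, CapabilityError, RegimeDataError,
                     TrainingDivergedError)

__all__ = [
    "REGIMES",
    "BackboneConfig",
    "MMDConfig",
    "TrainConfig",
    "DataBundle",
    "TrainedModel",
    "build_classifier",
    "gaussian_kernel_matrix",
    "median_heuristic_bandwidths",
    "mmd2",
    "train",
    "finetune",
    "select_best_epoch",
    "save_model",
    "load_model",
]

REGIMES = ("baseline", "photo_baseline", "photo_subset", "mmd", "finetune",
           "supplemented")


@dataclass(frozen=True)
class BackboneConfig:
    """Feature-extractor choice plus the fixed dense head.

    The head is always max-pool -> flatten -> dense (ReLU) -> dense ->
    softmax.  ``tiny`` is a three-conv-block backbone sized for small renders;
    ``vgg19_like`` mirrors the 16-convolution VGG19 layout.  ``pretrained``
    loads weights from a local ``.npz`` (no download is ever attempted).
    """

    kind: str = "tiny"
    input_side: int = 64
    hidden_dim: int = 64
    pretrained: bool = False
    pretrained_weights: str | None = None

    def __post_init__(self):
        if self.kind not in ("tiny", "vgg19_like"):
            raise ArgumentError(f"unknown backbone kind '{self.kind}'")
        if self.kind == "tiny" and self.input_side % 8 != 0:
            raise ArgumentError("tiny backbone needs input_side divisible by 8")
        if self.kind == "vgg19_like" and self.input_side % 32 != 0:
            raise ArgumentError(
                "vgg19_like backbone needs input_side divisible by 32")
        if self.pretrained and self.kind != "vgg19_like":
            raise ArgumentError("pretrained weights only apply to vgg19_like")

    @property
    def feature_dim(self) -> int:
        if self.kind == "tiny":
            return (self.input_side // 8) ** 2 * 32
        # 4 trunk pool stages + the head pool: side / 32 (224 -> 7x7x512)
        return (self.input_side // 32) ** 2 * 512


@dataclass(frozen=True)
class MMDConfig:
    """Gaussian-kernel MMD settings for the adaptation loss."""

    bandwidths: tuple[float, ...] | None = None   # None -> median heuristic
    bandwidth_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0)
    estimator: str = "biased"
    weight: float = 1.0

    def __post_init__(self):
        if self.estimator not in ("biased", "unbiased"):
            raise ArgumentError("estimator must be 'biased' or 'unbiased'")
        if self.weight < 0:
            raise ArgumentError("MMD weight must be nonnegative")
        if self.bandwidths is not None and any(b <= 0 for b in self.bandwidths):
            raise ArgumentError("bandwidths must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one training run."""

    regime: str = "baseline"
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 15
    batch_size: int = 32
    seed: int = 0
    monitor: str | None = None    # None -> regime default
    augment_config: AugmentConfig | None = None
    mmd: MMDConfig = field(default_factory=MMDConfig)

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ArgumentError(f"unknown regime '{self.regime}'")
        if self.patience > self.max_epochs:
            raise ArgumentError("patience must be <= max_epochs")
        if self.monitor not in (None, "train_domain_loss", "mean_test_accuracy"):
            raise ArgumentError(f"unknown monitor '{self.monitor}'")


@dataclass
class DataBundle:
    """Image streams a regime may draw on; regimes validate what they need."""

    classes: list
    synthetic_train: list = field(default_factory=list)
    photo_train: list = field(default_factory=list)
    photo_unlabelled: list = field(default_factory=list)
    synthetic_test: list = field(default_factory=list)
    photo_test: list = field(default_factory=list)


@dataclass
class TrainedModel:
    """A (possibly untrained) classifier with its config and history."""

    net: _nn.SequentialNet
    classes: list
    backbone: BackboneConfig
    train_config: TrainConfig | None = None
    history: list = field(default_factory=list)
    stopped_epoch: int = 0
    provenance: dict = field(default_factory=dict)

    # -- inference ---------------------------------------------------------
    def _to_array(self, records) -> np.ndarray:
        if isinstance(records, np.ndarray):
            return records
        return records_to_array(records)

    def predict_proba(self, records, batch_size: int = 256) -> np.ndarray:
        X = self._to_array(records)
        out = [
            _nn.softmax(self.net.forward(X[i:i + batch_size]))
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, records) -> np.ndarray:
        # argmax with ties toward the lowest class index
        return self.predict_proba(records).argmax(axis=1)

    def features(self, records, batch_size: int = 256) -> np.ndarray:
        """Flattened post-convolution features (the t-SNE / MMD tap)."""
        X = self._to_array(records)
        out = [
            np.array(self.net.forward_features(X[i:i + batch_size]))
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def labels_for(self, records) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.classes)}
        return np.array([index[r.species_id] for r in records])


def records_to_array(records) -> np.ndarray:
    """Stack ImageRecords into an (N, 3, H, W) float32 batch."""
    return np.stack([r.pixels.transpose(2, 0, 1) for r in records]).astype(
        _nn.DTYPE)


def build_classifier(cfg: BackboneConfig, n_classes: int,
                     seed: int = 0) -> TrainedModel:
    """Construct an untrained classifier with the fixed dense head.

    Exposes two taps: the flattened post-convolution features and the final
    convolutional activations (for Grad-CAM).
    """
    if n_classes < 2:
        raise ArgumentError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    if cfg.kind == "tiny":
        trunk = [
            _nn.Conv2d(3, 8, rng), _nn.ReLU(), _nn.MaxPool2(),
            _nn.Conv2d(8, 16, rng), _nn.ReLU(), _nn.MaxPool2(),
            _nn.Conv2d(16, 32, rng), _nn.ReLU(),
        ]
    else:
        blocks = [(64, 2), (128, 2), (256, 4), (512, 4), (512, 4)]
        trunk = []
        c_in = 3
        for c_out, reps in blocks:
            for _ in range(reps):
                trunk += [_nn.Conv2d(c_in, c_out, rng), _nn.ReLU()]
                c_in = c_out
            trunk.append(_nn.MaxPool2())
        trunk = trunk[:-1]  # final pool belongs to the head
    neck = [_nn.MaxPool2(), _nn.Flatten()]
    classifier = [
        _nn.Dense(cfg.feature_dim, cfg.hidden_dim, rng), _nn.ReLU(),
        _nn.Dense(cfg.hidden_dim, n_classes, rng),
    ]
    net = _nn.SequentialNet(trunk, neck, classifier)
    if cfg.pretrained:
        if not cfg.pretrained_weights:
            raise CapabilityError(
                "pretrained=True requires a local pretrained_weights .npz; "
                "no weights are downloaded")
        data = np.load(cfg.pretrained_weights)
        net.set_weights([data[k] for k in sorted(data.files,
                                                 key=lambda s: int(s))])
    return TrainedModel(net=net, classes=[], backbone=cfg)


# ---------------------------------------------------------------------------
# Maximum mean discrepancy
# ---------------------------------------------------------------------------

def gaussian_kernel_matrix(A: np.ndarray, B: np.ndarray,
                           bandwidths) -> np.ndarray:
    """Multi-bandwidth Gaussian kernel: K[i,j] = sum_b exp(-|a_i-b_j|^2 / 2b^2)."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ArgumentError(
            f"feature widths differ: {A.shape[1]} vs {B.shape[1]}")
    bandwidths = np.atleast_1d(np.asarray(bandwidths, dtype=np.float64))
    if np.any(bandwidths <= 0):
        raise ArgumentError("bandwidths must be positive")
    sq = (np.sum(A * A, axis=1)[:, None] + np.sum(B * B, axis=1)[None, :]
          - 2.0 * A @ B.T)
    sq = np.maximum(sq, 0.0)
    K = np.zeros_like(sq)
    for b in bandwidths:
        K += np.exp(-sq / (2.0 * b * b))
    return K


def median_heuristic_bandwidths(A, B, multipliers=(0.5, 1.0, 2.0)) -> np.ndarray:
    """Median pairwise distance of the pooled batch, times the multipliers."""
    X = np.concatenate([np.atleast_2d(A), np.atleast_2d(B)], axis=0).astype(
        np.float64)
    sq = (np.sum(X * X, axis=1)[:, None] + np.sum(X * X, axis=1)[None, :]
          - 2.0 * X @ X.T)
    d = np.sqrt(np.maximum(sq[np.triu_indices(len(X), k=1)], 0.0))
    med = float(np.median(d)) if len(d) else 1.0
    if med <= 0:
        med = 1.0
    return med * np.asarray(multipliers, dtype=np.float64)


def mmd2(A: np.ndarray, B: np.ndarray, cfg: MMDConfig | None = None) -> float:
    """Squared maximum mean discrepancy between two feature batches.

    Biased estimator: ``mean(K_AA) + mean(K_BB) - 2 mean(K_AB)`` — always
    nonnegative, zero iff the batches are identical as multisets.  The
    unbiased estimator excludes the diagonals of the within-batch kernel
    matrices and needs at least two rows per batch.
    """
    cfg = cfg or MMDConfig()
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    n, m = len(A), len(B)
    if cfg.estimator == "unbiased" and (n < 2 or m < 2):
        raise ArgumentError("unbiased estimator needs >= 2 rows per batch")
    if n < 1 or m < 1:
        raise ArgumentError("batches must be nonempty")
    bw = (np.asarray(cfg.bandwidths) if cfg.bandwidths is not None
          else median_heuristic_bandwidths(A, B, cfg.bandwidth_multipliers))
    K_aa = gaussian_kernel_matrix(A, A, bw)
    K_bb = gaussian_kernel_matrix(B, B, bw)
    K_ab = gaussian_kernel_matrix(A, B, bw)
    if cfg.estimator == "biased":
        return float(K_aa.mean() + K_bb.mean() - 2.0 * K_ab.mean())
    t_aa = (K_aa.sum() - np.trace(K_aa)) / (n * (n - 1))
    t_bb = (K_bb.sum() - np.trace(K_bb)) / (m * (m - 1))
    return float(t_aa + t_bb - 2.0 * K_ab.mean())


def _mmd2_biased_with_grads(A, B, bandwidths):
    """Biased MMD^2 plus gradients w.r.t. both batches (for training)."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    n, m = len(A), len(B)
    bw = np.atleast_1d(bandwidths)
    sq_aa = (np.sum(A * A, 1)[:, None] + np.sum(A * A, 1)[None, :] - 2 * A @ A.T)
    sq_bb = (np.sum(B * B, 1)[:, None] + np.sum(B * B, 1)[None, :] - 2 * B @ B.T)
    sq_ab = (np.sum(A * A, 1)[:, None] + np.sum(B * B, 1)[None, :] - 2 * A @ B.T)
    value = 0.0
    dA = np.zeros_like(A)
    dB = np.zeros_like(B)
    for b in bw:
        g = 1.0 / (b * b)
        W_aa = np.exp(-np.maximum(sq_aa, 0) * g / 2.0)
        W_bb = np.exp(-np.maximum(sq_bb, 0) * g / 2.0)
        W_ab = np.exp(-np.maximum(sq_ab, 0) * g / 2.0)
        value += W_aa.mean() + W_bb.mean() - 2.0 * W_ab.mean()
        # d mean(K_AA) / dA_i = (2 g / n^2) * (W@A - rowsum(W)*A_i) etc.
        dA += (2.0 * g / (n * n)) * (W_aa @ A - W_aa.sum(1)[:, None] * A)
        dA -= (2.0 * g / (n * m)) * (W_ab @ B - W_ab.sum(1)[:, None] * A)
        dB += (2.0 * g / (m * m)) * (W_bb @ B - W_bb.sum(1)[:, None] * B)
        dB -= (2.0 * g / (n * m)) * (W_ab.T @ A - W_ab.sum(0)[:, None] * B)
    return float(value), dA, dB


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _eval_split(net, X, y, batch_size=256):
    losses, correct = [], 0
    for i in range(0, len(X), batch_size):
        logits = net.forward(X[i:i + batch_size])
        loss, _ = _nn.cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def _regime_streams(bundle: DataBundle, regime: str):
    """Select (labelled records, unlabelled records, monitored test domain)."""
    if regime == "baseline":
        labelled, unlab, dom = bundle.synthetic_train, None, "synthetic"
    elif regime in ("photo_baseline", "photo_subset"):
        labelled, unlab, dom = bundle.photo_train, None, "photo"
    elif regime == "mmd":
        if not bundle.photo_unlabelled:
            raise RegimeDataError("regime 'mmd' needs an unlabelled photo stream")
        labelled, unlab, dom = (bundle.synthetic_train, bundle.photo_unlabelled,
                                "synthetic")
    elif regime == "supplemented":
        if not bundle.photo_train:
            raise RegimeDataError(
                "regime 'supplemented' needs a labelled photo stream")
        labelled = list(bundle.synthetic_train) + list(bundle.photo_train)
        unlab, dom = None, "synthetic"
        if not bundle.synthetic_train:
            raise RegimeDataError(
                "regime 'supplemented' needs a labelled synthetic stream")
    elif regime == "finetune":
        labelled, unlab, dom = bundle.photo_train, None, "photo"
        if not labelled:
            raise RegimeDataError("regime 'finetune' needs a labelled photo stream")
    else:  # pragma: no cover
        raise ArgumentError(regime)
    if not labelled:
        raise RegimeDataError(f"regime '{regime}' is missing its labelled stream")
    if not bundle.synthetic_test or not bundle.photo_test:
        raise RegimeDataError("both test domains are required to record history")
    return list(labelled), list(unlab) if unlab else None, dom


def _default_monitor(regime: str) -> str:
    return ("mean_test_accuracy" if regime in ("supplemented", "finetune")
            else "train_domain_loss")


def _train_loop(model: TrainedModel, bundle: DataBundle, cfg: TrainConfig):
    labelled, unlabelled, train_domain = _regime_streams(bundle, cfg.regime)
    net = model.net
    classes = bundle.classes
    index = {c: i for i, c in enumerate(classes)}
    y = np.array([index[r.species_id] for r in labelled])

    Xs_test = records_to_array(bundle.synthetic_test)
    ys_test = np.array([index[r.species_id] for r in bundle.synthetic_test])
    Xp_test = records_to_array(bundle.photo_test)
    yp_test = np.array([index[r.species_id] for r in bundle.photo_test])

    X_clean = records_to_array(labelled)
    # lambda = 0 switches adaptation off entirely, so the run is identical
    # to the baseline regime at the same seed (no joint batches).
    use_mmd = unlabelled is not None and cfg.mmd.weight > 0
    X_unlab = records_to_array(unlabelled) if use_mmd else None

    monitor = cfg.monitor or _default_monitor(cfg.regime)
    rng = np.random.default_rng(cfg.seed)
    # Separate stream for the unlabelled batches so that the labelled-side
    # draws (shuffles, augmentations) are identical with and without an
    # unlabelled stream; lambda = 0 then reproduces the baseline exactly.
    rng_u = np.random.default_rng(np.random.SeedSequence(
        entropy=cfg.seed, spawn_key=(1,)))
    opt = _nn.Adam(net, lr=cfg.learning_rate)

    best_value = None
    best_weights = net.get_weights()
    best_epoch = 0
    stall = 0
    history = []
    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.augment_config is not None and not cfg.augment_config.is_identity:
            X = records_to_array([
                augment(r, cfg.augment_config,
                        seed=int(rng.integers(2 ** 31)))
                for r in labelled])
        else:
            X = X_clean
        order = rng.permutation(len(X))
        if X_unlab is not None:
            u_order = rng.permutation(len(X_unlab))
            u_pos = 0
        epoch_loss, epoch_mmd, n_batches = 0.0, 0.0, 0
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            if X_unlab is None:
                logits = net.forward(xb)
                loss, dlogits = _nn.cross_entropy(logits, yb)
                net.backward(dlogits)
            else:
                k = min(len(idx), len(X_unlab))
                if u_pos + k > len(X_unlab):
                    u_order = rng.permutation(len(X_unlab))
                    u_pos = 0
                ub = X_unlab[u_order[u_pos:u_pos + k]]
                u_pos += k
                joint = np.concatenate([xb, ub], axis=0)
                feats = net.forward_features(joint)
                h = feats
                for layer in net.classifier:
                    h = layer.forward(h)
                logits_all = h
                # classifier saw the joint batch; only labelled rows carry CE
                loss, dlog_lab = _nn.cross_entropy(logits_all[:len(idx)], yb)
                dlogits = np.zeros_like(logits_all)
                dlogits[:len(idx)] = dlog_lab
                lam = cfg.mmd.weight
                fa, fb = feats[:len(idx)], feats[len(idx):]
                bw = (np.asarray(cfg.mmd.bandwidths)
                      if cfg.mmd.bandwidths is not None
                      else median_heuristic_bandwidths(
                          fa, fb, cfg.mmd.bandwidth_multipliers))
                mmd_val, dA, dB = _mmd2_biased_with_grads(fa, fb, bw)
                dfeat = np.concatenate([lam * dA, lam * dB], axis=0)
                net.backward(dlogits, dfeatures_extra=dfeat)
                loss = loss + lam * mmd_val
                epoch_mmd += mmd_val
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}")
            opt.step()
            epoch_loss += loss
            n_batches += 1

        s_loss, s_acc = _eval_split(net, Xs_test, ys_test)
        p_loss, p_acc = _eval_split(net, Xp_test, yp_test)
        entry = {
            "epoch": epoch,
            "train_loss": epoch_loss / max(n_batches, 1),
            "synthetic_test_loss": s_loss,
            "synthetic_test_accuracy": s_acc,
            "photo_test_loss": p_loss,
            "photo_test_accuracy": p_acc,
        }
        if X_unlab is not None:
            entry["mean_batch_mmd2"] = epoch_mmd / max(n_batches, 1)
        history.append(entry)

        if monitor == "train_domain_loss":
            value = s_loss if train_domain == "synthetic" else p_loss
            improved = best_value is None or value < best_value
        else:
            value = 0.5 * (s_acc + p_acc)
            improved = best_value is None or value > best_value
        if improved:
            best_value, best_epoch, stall = value, epoch, 0
            best_weights = net.get_weights()
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    net.set_weights(best_weights)
    model.history = history
    model.stopped_epoch = len(history)
    model.provenance.update({"monitor": monitor, "best_epoch": best_epoch,
                             "regime": cfg.regime})
    model.train_config = cfg
    return model


def train(bundle: DataBundle, cfg: TrainConfig,
          backbone: BackboneConfig | None = None) -> TrainedModel:
    """Train a classifier under one regime (see module docstring).

    Deterministic given ``cfg.seed`` at a fixed thread count.  Raises
    :class:`RegimeDataError` when a required stream is missing and
    :class:`TrainingDivergedError` on non-finite loss.
    """
    if cfg.regime == "finetune":
        raise ArgumentError("use finetune(start, bundle, cfg) for the "
                            "fine-tuning regime")
    backbone = backbone or BackboneConfig()
    model = build_classifier(backbone, len(bundle.classes), seed=cfg.seed)
    model.classes = list(bundle.classes)
    return _train_loop(model, bundle, cfg)


def finetune(start: TrainedModel, bundle: DataBundle,
             cfg: TrainConfig) -> TrainedModel:
    """Continue training from ``start``'s final weights on the photo subset.

    The new model records a provenance link to the starting run (its regime
    and stopped epoch), so a 50-epoch adaptation run followed by 2 epochs of
    fine-tuning reports as "50 + 2".
    """
    if cfg.regime != "finetune":
        cfg = TrainConfig(**{**asdict_shallow(cfg), "regime": "finetune"})
    if start.classes != bundle.classes:
        raise ArgumentError("class list mismatch between start model and bundle")
    model = build_classifier(start.backbone, len(bundle.classes), seed=cfg.seed)
    model.classes = list(bundle.classes)
    try:
        model.net.set_weights(start.net.get_weights())
    except ValueError as e:
        raise ArgumentError(f"architecture mismatch: {e}") from e
    model.provenance = {
        "start_regime": (start.train_config.regime if start.train_config
                         else None),
        "start_stopped_epoch": start.stopped_epoch,
    }
    if cfg.max_epochs == 0:
        model.train_config = cfg
        return model
    return _train_loop(model, bundle, cfg)


def asdict_shallow(cfg: TrainConfig) -> dict:
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def select_best_epoch(history, criterion: str = "mean_test_accuracy") -> int:
    """Epoch (1-based) maximizing the mean of both domains' test accuracies.

    Ties break toward the earliest epoch.  Replaces a manual best-epoch
    choice with an explicit, reproducible criterion.
    """
    if not history:
        raise ArgumentError("history is empty")
    values = []
    for entry in history:
        try:
            values.append(0.5 * (entry["synthetic_test_accuracy"]
                                 + entry["photo_test_accuracy"]))
        except KeyError as e:
            raise ArgumentError(f"history entry missing {e}") from None
    best = int(np.argmax(values))  # argmax returns the first maximum
    return history[best].get("epoch", best + 1)


# ---------------------------------------------------------------------------
# Persistence: npz weights + JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    path = Path(path)
    weights = model.net.get_weights()
    np.savez(path.with_suffix(".npz"), **{str(i): w for i, w in
                                          enumerate(weights)})
    sidecar = {
        "classes": list(model.classes),
        "backbone": asdict(model.backbone),
        "train_config": (asdict_shallow(model.train_config)
                         if model.train_config else None),
        "history": model.history,
        "stopped_epoch": model.stopped_epoch,
        "provenance": model.provenance,
    }
    if sidecar["train_config"]:
        ac = sidecar["train_config"].get("augment_config")
        sidecar["train_config"]["augment_config"] = asdict(ac) if ac else None
        sidecar["train_config"]["mmd"] = asdict(sidecar["train_config"]["mmd"])
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    backbone = BackboneConfig(**sidecar["backbone"])
    model = build_classifier(backbone, max(len(sidecar["classes"]), 2))
    model.classes = sidecar["classes"]
    data = np.load(path.with_suffix(".npz"))
    model.net.set_weights([data[str(i)] for i in range(len(data.files))])
    model.history = sidecar["history"]
    model.stopped_epoch = sidecar["stopped_epoch"]
    model.provenance = sidecar["provenance"]
    return model
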