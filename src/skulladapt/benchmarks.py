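"""Reproduction benchmarks: dataset geometry and mechanism-recovery runs.

Two kinds of checks live here.  The *geometry* checks recompute the exact
dataset arithmetic of a full-scale study — the 92-pose view sphere, a
16-species x 30-specimen bank with one dropped scan (479 assets), the
479 x 92 = 44,068 render tasks and the specimen-level 80:20 split giving
35,328 train / 8,740 test source-domain images.  The *mechanism* checks run
the desk-scale profile end to end and measure the qualitative structure the
pipeline is built to reproduce: no accuracy gap without a domain shift, the
baseline < MMD <= supplemented cross-domain ordering with the shift on, the
collapse of photo-trained models on the synthetic domain, and the Grad-CAM
focus contrast between photo-only and supplemented training under a session
confound.

All randomness is derived from one master seed.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np

from . import meshforge, orchestrate
from .adapt_train import MMDConfig, TrainConfig, finetune, mmd2, train
from .datapipe import split_by_specimen
from .evalsuite import evaluate_accuracy, score_gradcam_sample
from .orchestrate import prepare_data, regime_bundle, _derive_seed
from .viewsphere import PhotoDomainConfig, ViewSphereSpec, view_sphere_poses

__all__ = [
    "desk_config",
    "geometry_counts",
    "mmd_oracle_check",
    "silhouette_oracle_check",
    "null_shift_gap",
    "regime_battery",
    "gradcam_confound_comparison",
]

REPLICATION_SCALE = dict(n_species=16, specimens_per_species=30,
                         drop=[(15, 1)], test_fraction=0.2)


def desk_config():
    """The shipped desk-scale experiment profile."""
    path = resources.files("skulladapt") / "configs" / "desk_test.yaml"
    return orchestrate.load_config(path)


def geometry_counts(seed: int = 0) -> dict:
    """Recompute the full-scale dataset arithmetic from scratch.

    Builds the complete specimen bank (cheap low-subdivision meshes — only
    the bookkeeping matters here), enumerates the 92-pose lattice and splits
    at the specimen level, then counts render tasks and split images.
    """
    spec = ViewSphereSpec(yaw_step=20.0,
                          ring_pitches=(0.0, 30.0, -30.0, 60.0, -60.0),
                          include_poles=True)
    poses = view_sphere_poses(spec)
    bank = meshforge.generate_species_bank(
        REPLICATION_SCALE["n_species"],
        REPLICATION_SCALE["specimens_per_species"],
        seed=seed, drop=REPLICATION_SCALE["drop"], subdivisions=1)
    plan = split_by_specimen(bank, REPLICATION_SCALE["test_fraction"],
                             seed=seed)
    return {
        "view_sphere_poses": len(poses),
        "specimen_bank_size": len(bank),
        "render_tasks": len(bank) * len(poses),
        "synthetic_train_images": len(plan.train_specimens) * len(poses),
        "synthetic_test_images": len(plan.test_specimens) * len(poses),
    }


def mmd_oracle_check(seed: int = 0, n_batches: int = 5) -> dict:
    """Vectorized MMD^2 vs an explicit double-loop oracle on small batches."""

    def double_loop(A, B, bw, unbiased):
        def k(x, y):
            return sum(np.exp(-np.sum((x - y) ** 2) / (2 * b * b)) for b in bw)
        n, m = len(A), len(B)
        if unbiased:
            t_aa = sum(k(A[i], A[j]) for i in range(n) for j in range(n)
                       if i != j) / (n * (n - 1))
            t_bb = sum(k(B[i], B[j]) for i in range(m) for j in range(m)
                       if i != j) / (m * (m - 1))
        else:
            t_aa = sum(k(a, b) for a in A for b in A) / n ** 2
            t_bb = sum(k(a, b) for a in B for b in B) / m ** 2
        t_ab = sum(k(a, b) for a in A for b in B) / (n * m)
        return t_aa + t_bb - 2 * t_ab

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_batches):
        n, m = rng.integers(3, 20, size=2)
        d = int(rng.integers(1, 5))
        A = rng.normal(size=(int(n), d))
        B = rng.normal(size=(int(m), d)) + 0.3
        bw = (0.5, 1.0, 2.0)
        for estimator in ("biased", "unbiased"):
            ours = mmd2(A, B, MMDConfig(bandwidths=bw, estimator=estimator))
            ref = double_loop(A, B, bw, estimator == "unbiased")
            worst = max(worst, abs(ours - ref))
    hand = mmd2(np.array([[0.0]]), np.array([[1.0]]),
                MMDConfig(bandwidths=(1.0,)))
    return {"mmd2_two_point_biased": hand,
            "mmd_oracle_max_abs_diff": worst}


def silhouette_oracle_check(seed: int = 0, n_sets: int = 5) -> dict:
    """Implementation vs a double-loop silhouette oracle on <= 50 points."""
    from .evalsuite import Embedding2D, silhouette_scores

    def oracle(points, labels):
        n = len(points)
        vals = []
        for i in range(n):
            same = [j for j in range(n) if labels[j] == labels[i] and j != i]
            if not same:
                vals.append(0.0)
                continue
            a = np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
            b = min(np.mean([np.linalg.norm(points[i] - points[j])
                             for j in range(n) if labels[j] == other])
                    for other in set(labels.tolist()) - {labels[i]})
            vals.append((b - a) / max(a, b))
        return float(np.mean(vals))

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_sets):
        n = int(rng.integers(10, 50))
        pts = rng.normal(size=(n, 2))
        labels = rng.integers(0, 3, n)
        if len(set(labels.tolist())) < 2:
            continue
        emb = Embedding2D(pts, labels, np.array(["photo"] * n), seed=0)
        _, _, combined = silhouette_scores(emb)
        worst = max(worst, abs(combined - oracle(pts, labels)))
    return {"silhouette_oracle_max_abs_diff": worst}


def _train_one(cfg, data, regime: str, seed: int, mmd_model=None):
    tc = cfg.training
    run_cfg = TrainConfig(
        regime=regime, learning_rate=tc.learning_rate,
        max_epochs=tc.max_epochs, patience=tc.patience,
        batch_size=tc.batch_size,
        seed=_derive_seed(seed, 100 + orchestrate.REGIME_INDEX[regime]),
        augment_config=cfg.datapipe.augment, mmd=tc.mmd)
    bundle = regime_bundle(data, regime)
    if regime == "finetune":
        return finetune(mmd_model, bundle, run_cfg)
    return train(bundle, run_cfg, tc.backbone)


def null_shift_gap(seed: int, cfg=None) -> dict:
    """Baseline same-domain vs cross-domain accuracy with the shift OFF.

    With every photo-domain nuisance at zero, the target domain differs from
    the source only in which individuals were imaged, so a source-trained
    model should generalize with essentially no gap.
    """
    cfg = cfg or desk_config()
    cfg = dataclasses.replace(cfg, photo_domain=PhotoDomainConfig())
    data = prepare_data(cfg, seed)
    model = _train_one(cfg, data, "baseline", seed)
    same = evaluate_accuracy(model, data.synth_test)
    cross = evaluate_accuracy(model, data.photo_test)
    return {"baseline_same_domain_accuracy_no_shift": same,
            "baseline_cross_domain_accuracy_no_shift": cross,
            "null_shift_gap_pp": abs(same - cross) * 100.0,
            "_sizes": {"synthetic_test": len(data.synth_test),
                       "photo_test": len(data.photo_test)}}


def regime_battery(seed: int, cfg=None,
                   regimes=("baseline", "mmd", "supplemented",
                            "photo_baseline", "photo_subset")) -> dict:
    """Train the comparison regimes once and measure both test accuracies."""
    cfg = cfg or desk_config()
    data = prepare_data(cfg, seed)
    out = {"_sizes": {"synthetic_test": len(data.synth_test),
                      "photo_test": len(data.photo_test)}}
    for regime in regimes:
        model = _train_one(cfg, data, regime, seed)
        out[regime] = {
            "synthetic_accuracy": evaluate_accuracy(model, data.synth_test),
            "photo_accuracy": evaluate_accuracy(model, data.photo_test),
        }
    return out


def gradcam_confound_comparison(seed: int, cfg=None, sample: int = 96) -> dict:
    """Mean Grad-CAM focus score, photo-only vs supplemented, confound ON.

    The probe runs at the renderer's native 64 px (a finer attribution grid
    than the 48 px training profile) with a dense, salient marking pattern,
    so that background reliance is clearly visible in the activation maps.
    """
    from .adapt_train import BackboneConfig

    cfg = cfg or desk_config()
    cfg = dataclasses.replace(
        cfg,
        photo_domain=dataclasses.replace(cfg.photo_domain,
                                         session_confound=True,
                                         background_marking_density=2.5),
        datapipe=dataclasses.replace(cfg.datapipe, resize_side=64),
        training=dataclasses.replace(
            cfg.training,
            backbone=BackboneConfig(kind="tiny", input_side=64,
                                    hidden_dim=cfg.training.backbone.hidden_dim)))
    data = prepare_data(cfg, seed)
    out = {}
    for regime in ("photo_baseline", "supplemented"):
        model = _train_one(cfg, data, regime, seed)
        n = min(sample, len(data.photo_test))
        _, mean = score_gradcam_sample(model, data.photo_test, n=n,
                                       seed=_derive_seed(seed, 8))
        out[regime] = mean
    return out
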