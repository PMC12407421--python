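"""Experiment driver: YAML config, staged pipeline, six-regime comparison.

``run_experiment`` executes forge -> render (clean + photo domains) ->
specimen-level split -> training regimes -> evaluation, and emits one
evaluation report per regime plus a comparison table (per-domain accuracies,
silhouette triple, Grad-CAM mean, epochs).  Every random procedure draws its
seed from the experiment master seed through named spawn keys, so re-running
the same config reproduces results seed-for-seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import yaml

from . import datapipe, evalsuite, meshforge, viewsphere
from .adapt_train import (BackboneConfig, DataBundle, MMDConfig, TrainConfig,
                          finetune, train)
from .datapipe import AugmentConfig
from .errors import ArgumentError, StageError
from .viewsphere import PhotoDomainConfig, RenderConfig, ViewSphereSpec

__all__ = [
    "ExperimentConfig",
    "load_config",
    "config_hash",
    "prepare_data",
    "run_experiment",
]

log = logging.getLogger("skulladapt")


@dataclass(frozen=True)
class ForgeSection:
    n_species: int = 4
    specimens_per_species: int = 6
    photo_specimens_per_species: int = 4
    drop: tuple = ()
    standard_length: float = 1.0
    target_faces: int = 600
    subdivisions: int = 3


@dataclass(frozen=True)
class DatapipeSection:
    test_fraction: float = 0.2
    subset_fraction: float = 0.25
    resize_side: int = 48
    augment: AugmentConfig = field(default_factory=AugmentConfig)


@dataclass(frozen=True)
class TrainingSection:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    learning_rate: float = 1e-3
    max_epochs: int = 30
    patience: int = 8
    batch_size: int = 32
    mmd: MMDConfig = field(default_factory=MMDConfig)
    regimes: tuple = ("baseline", "photo_baseline", "photo_subset", "mmd",
                      "finetune", "supplemented")


@dataclass(frozen=True)
class EvaluationSection:
    gradcam_sample: int = 100
    gradcam_thresholds: tuple = evalsuite.DEFAULT_SCORE_THRESHOLDS


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    output_dir: str | None = None
    forge: ForgeSection = field(default_factory=ForgeSection)
    viewsphere: ViewSphereSpec = field(default_factory=ViewSphereSpec)
    render: RenderConfig = field(default_factory=RenderConfig)
    photo_domain: PhotoDomainConfig = field(default_factory=PhotoDomainConfig)
    datapipe: DatapipeSection = field(default_factory=DatapipeSection)
    training: TrainingSection = field(default_factory=TrainingSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)


def _build(cls, data, path):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ArgumentError(f"config section '{path}' must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ArgumentError(f"unknown config keys in '{path}': {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        nested = _NESTED.get((cls, name))
        if nested is not None:
            kwargs[name] = _build(nested, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(tuple(v) if isinstance(v, list) else v
                                 for v in value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    (ExperimentConfig, "forge"): ForgeSection,
    (ExperimentConfig, "viewsphere"): ViewSphereSpec,
    (ExperimentConfig, "render"): RenderConfig,
    (ExperimentConfig, "photo_domain"): PhotoDomainConfig,
    (ExperimentConfig, "datapipe"): DatapipeSection,
    (ExperimentConfig, "training"): TrainingSection,
    (ExperimentConfig, "evaluation"): EvaluationSection,
    (DatapipeSection, "augment"): AugmentConfig,
    (TrainingSection, "backbone"): BackboneConfig,
    (TrainingSection, "mmd"): MMDConfig,
}


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    return _build(ExperimentConfig, data, "experiment")


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _derive_seed(master: int, key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _standardize_bank(bank, forge_cfg: ForgeSection):
    for rec in bank:
        mesh = meshforge.standardize_length(rec.mesh, forge_cfg.standard_length)
        rec.mesh = meshforge.decimate(mesh, forge_cfg.target_faces)
    return bank


def prepare_data(cfg: ExperimentConfig, seed: int | None = None):
    """Forge both specimen banks, render both domains and build the splits.

    Returns a namespace with banks, records per partition, split plans and
    the sorted class list — everything a training regime draws on.
    """
    master = cfg.seed if seed is None else seed
    fc = cfg.forge
    t0 = time.time()
    specs = meshforge.default_species_specs(fc.n_species, _derive_seed(master, 0))
    synth_bank = meshforge.generate_species_bank(
        fc.n_species, fc.specimens_per_species, seed=_derive_seed(master, 0),
        drop=list(fc.drop), species_specs=specs, subdivisions=fc.subdivisions)
    photo_bank = meshforge.generate_species_bank(
        fc.n_species, fc.photo_specimens_per_species,
        seed=_derive_seed(master, 1), species_specs=specs,
        subdivisions=fc.subdivisions)
    for rec in photo_bank:
        rec.specimen_id = "ph_" + rec.specimen_id
    _standardize_bank(synth_bank, fc)
    _standardize_bank(photo_bank, fc)
    log.info("forge: %d + %d specimens in %.1fs", len(synth_bank),
             len(photo_bank), time.time() - t0)

    t0 = time.time()
    synth_records, synth_manifest = viewsphere.render_dataset(
        synth_bank, cfg.viewsphere, cfg.render, None)
    photo_records, photo_manifest = viewsphere.render_dataset(
        photo_bank, cfg.viewsphere, cfg.render, cfg.photo_domain,
        seed=_derive_seed(master, 2))
    side = cfg.datapipe.resize_side
    synth_records = [datapipe.resize(r, side) for r in synth_records]
    photo_records = [datapipe.resize(r, side) for r in photo_records]
    log.info("render: %d + %d images in %.1fs", len(synth_records),
             len(photo_records), time.time() - t0)

    synth_plan = datapipe.split_by_specimen(
        synth_bank, cfg.datapipe.test_fraction, _derive_seed(master, 3))
    photo_plan = datapipe.split_by_specimen(
        photo_bank, cfg.datapipe.test_fraction, _derive_seed(master, 4))
    photo_subset_plan = datapipe.subset_training_specimens(
        photo_plan, cfg.datapipe.subset_fraction, _derive_seed(master, 5))

    def part(records, plan, partition):
        return [r for r in records
                if plan.partition_of(r.specimen_id) == partition]

    classes = sorted({r.species_id for r in synth_bank})
    return SimpleNamespace(
        classes=classes,
        species_specs=specs,
        synth_bank=synth_bank, photo_bank=photo_bank,
        synth_manifest=synth_manifest, photo_manifest=photo_manifest,
        synth_plan=synth_plan, photo_plan=photo_plan,
        photo_subset_plan=photo_subset_plan,
        synth_train=part(synth_records, synth_plan, "train"),
        synth_test=part(synth_records, synth_plan, "test"),
        photo_train=part(photo_records, photo_plan, "train"),
        photo_test=part(photo_records, photo_plan, "test"),
        photo_subset_train=part(photo_records, photo_subset_plan, "train"),
        master_seed=master,
    )


def regime_bundle(data, regime: str) -> DataBundle:
    """Assemble the DataBundle a regime requires from prepared data."""
    common = dict(classes=data.classes, synthetic_test=data.synth_test,
                  photo_test=data.photo_test)
    if regime == "baseline":
        return DataBundle(synthetic_train=data.synth_train, **common)
    if regime == "photo_baseline":
        return DataBundle(photo_train=data.photo_train, **common)
    if regime in ("photo_subset", "finetune"):
        return DataBundle(photo_train=data.photo_subset_train, **common)
    if regime == "mmd":
        return DataBundle(synthetic_train=data.synth_train,
                          photo_unlabelled=data.photo_train, **common)
    if regime == "supplemented":
        return DataBundle(synthetic_train=data.synth_train,
                          photo_train=data.photo_subset_train, **common)
    raise ArgumentError(f"unknown regime '{regime}'")


def _train_regimes(cfg: ExperimentConfig, data, regimes):
    tc = cfg.training
    models = {}
    # fine-tuning continues from the MMD model, so order mmd first
    ordered = sorted(regimes, key=lambda r: 0 if r == "mmd" else 1)
    if "finetune" in ordered and "mmd" not in ordered:
        ordered.insert(0, "mmd")
    for regime in ordered:
        run_cfg = TrainConfig(
            regime=regime, learning_rate=tc.learning_rate,
            max_epochs=tc.max_epochs, patience=tc.patience,
            batch_size=tc.batch_size,
            seed=_derive_seed(data.master_seed, 100 + REGIME_INDEX[regime]),
            augment_config=cfg.datapipe.augment, mmd=tc.mmd)
        bundle = regime_bundle(data, regime)
        t0 = time.time()
        if regime == "finetune":
            models[regime] = finetune(models["mmd"], bundle, run_cfg)
        else:
            models[regime] = train(bundle, run_cfg, tc.backbone)
        log.info("train[%s]: %d epochs in %.1fs", regime,
                 models[regime].stopped_epoch, time.time() - t0)
    return {r: models[r] for r in regimes if r in models}


REGIME_INDEX = {r: i for i, r in enumerate(
    ("baseline", "photo_baseline", "photo_subset", "mmd", "finetune",
     "supplemented"))}


def _tsne_figure(models, data, out) -> None:
    """One joint t-SNE scatter per regime: species by colour, domain by marker."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as _np

    from . import evalsuite as _ev

    for regime, model in models.items():
        feats = _np.concatenate([model.features(data.synth_test),
                                 model.features(data.photo_test)], axis=0)
        labels = _np.array([r.species_id for r in data.synth_test]
                           + [r.species_id for r in data.photo_test])
        domains = _np.array(["synthetic"] * len(data.synth_test)
                            + ["photo"] * len(data.photo_test))
        emb = _ev.embed_tsne(feats, labels, domains,
                             seed=_derive_seed(data.master_seed, 7))
        fig, ax = plt.subplots(figsize=(5, 5))
        classes = sorted(set(labels.tolist()))
        cmap = plt.get_cmap("tab10")
        for ci, cls in enumerate(classes):
            for dom, marker in (("synthetic", "x"), ("photo", "o")):
                sel = (emb.labels == cls) & (emb.domains == dom)
                ax.scatter(emb.points[sel, 0], emb.points[sel, 1], s=12,
                           marker=marker, color=cmap(ci % 10),
                           label=f"{cls} ({dom})" if ci < 2 else None)
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(f"t-SNE of test features: {regime}")
        ax.legend(fontsize=6, loc="best")
        fig.savefig(out / f"tsne_{regime}.png", dpi=120)
        plt.close(fig)


def run_experiment(cfg: ExperimentConfig, seed: int | None = None,
                   out_dir=None):
    """Run the full comparison; returns ``(reports, models, table)``.

    ``reports`` maps regime name to :class:`~skulladapt.evalsuite.EvalReport`;
    ``table`` is the comparison DataFrame (one row per regime).  When an
    output directory is configured, reports, the table and a config-hash
    sidecar are written there.
    """
    import pandas as pd

    out = Path(out_dir) if out_dir else (
        Path(cfg.output_dir) if cfg.output_dir else None)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:  # noqa: BLE001 - report the failing stage
            raise StageError(name, cfg.output_dir, e) from e

    data = stage("prepare_data", prepare_data, cfg, seed)
    models = stage("train", _train_regimes, cfg, data,
                   list(cfg.training.regimes))

    reports = {}
    master = data.master_seed
    for regime, model in models.items():
        reports[regime] = stage(
            f"evaluate[{regime}]", evalsuite.evaluate_model, model,
            data.synth_test, data.photo_test,
            tsne_seed=_derive_seed(master, 7),
            gradcam_n=min(cfg.evaluation.gradcam_sample, len(data.photo_test)),
            gradcam_seed=_derive_seed(master, 8),
            thresholds=cfg.evaluation.gradcam_thresholds)

    rows = []
    for regime, rep in reports.items():
        model = models[regime]
        epochs = str(model.stopped_epoch)
        if regime == "finetune":
            epochs = (f"{model.provenance.get('start_stopped_epoch', '?')}"
                      f" + {model.stopped_epoch}")
        rows.append({
            "model": regime,
            "synthetic_accuracy": rep.accuracy_synthetic,
            "photo_accuracy": rep.accuracy_photo,
            "silhouette_synthetic": rep.silhouette_synthetic,
            "silhouette_photo": rep.silhouette_photo,
            "silhouette_combined": rep.silhouette_combined,
            "gradcam_mean": rep.gradcam_mean,
            "epochs": epochs,
        })
    table = pd.DataFrame(rows).set_index("model")

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        chash = config_hash(cfg)
        for regime, rep in reports.items():
            payload = rep.to_json_dict()
            payload["config_hash"] = chash
            (out / f"report_{regime}.json").write_text(
                json.dumps(payload, indent=2))
            pd.DataFrame(rep.confusion_photo, index=rep.classes,
                         columns=rep.classes).to_csv(
                out / f"confusion_photo_{regime}.csv")
            if models[regime].history:
                pd.DataFrame(models[regime].history).to_csv(
                    out / f"training_curves_{regime}.csv", index=False)
        table.to_csv(out / "comparison.csv")
        _tsne_figure(models, data, out)
        (out / "run_info.json").write_text(json.dumps({
            "config_hash": chash, "seed": data.master_seed,
            "regimes": list(models),
        }, indent=2))
    return reports, models, table
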