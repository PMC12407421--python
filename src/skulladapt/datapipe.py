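"""Specimen-level splitting, subsetting, augmentation and resizing.

Splits are made at the specimen level so that every image of an individual
lands on exactly one side — the guard against identity leakage that a random
per-image split would violate.  The test count per species is
``floor(n * test_fraction)`` clamped so both sides are nonempty; a 30-specimen
species at 0.2 therefore splits 24:6 and a 29-specimen species 24:5.
Subsetting keeps ``floor(keep_fraction * n_train)`` (minimum 1) training
specimens per species and marks the rest unused, so a 25% subset of an 8:2
split gives 2:2:6 train:test:unused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import ArgumentError, SplitInfeasibleError
from .viewsphere import ImageRecord

__all__ = [
    "SplitPlan",
    "AugmentConfig",
    "split_by_specimen",
    "subset_training_specimens",
    "augment",
    "resize",
]


@dataclass
class SplitPlan:
    """Specimen-level partition: disjoint train/test sets plus unused pool."""

    train_specimens: frozenset
    test_specimens: frozenset
    unused_specimens: frozenset = frozenset()
    species_of: dict = field(default_factory=dict)

    def __post_init__(self):
        pools = [self.train_specimens, self.test_specimens, self.unused_specimens]
        for i in range(3):
            for j in range(i + 1, 3):
                if pools[i] & pools[j]:
                    raise ArgumentError("split partitions overlap")

    def partition_of(self, specimen_id) -> str:
        if specimen_id in self.train_specimens:
            return "train"
        if specimen_id in self.test_specimens:
            return "test"
        if specimen_id in self.unused_specimens:
            return "unused"
        raise KeyError(specimen_id)

    def counts_by_species(self):
        """Per-species (train, test, unused) specimen counts as a DataFrame."""
        import pandas as pd

        rows = {}
        for part, pool in (("train", self.train_specimens),
                           ("test", self.test_specimens),
                           ("unused", self.unused_specimens)):
            for sp in pool:
                species = self.species_of.get(sp, "?")
                rows.setdefault(species, {"train": 0, "test": 0, "unused": 0})
                rows[species][part] += 1
        return pd.DataFrame.from_dict(rows, orient="index").sort_index()

    def to_json_dict(self) -> dict:
        return {sp: self.partition_of(sp)
                for sp in sorted(self.train_specimens | self.test_specimens
                                 | self.unused_specimens)}


def _specimen_table(records):
    """(specimen_id -> species_id) from anything with those attributes."""
    table: dict = {}
    for r in records:
        sp, species = r.specimen_id, r.species_id
        if table.setdefault(sp, species) != species:
            raise ArgumentError(f"specimen {sp} has inconsistent species labels")
    return table


def split_by_specimen(records, test_fraction: float, seed: int) -> SplitPlan:
    """Partition specimens into train/test within each species.

    ``records`` is any iterable with ``specimen_id`` and ``species_id``
    attributes (rendered images or bank records).  Per species,
    ``floor(n * test_fraction)`` specimens go to test, clamped to [1, n-1];
    membership is drawn with a seeded generator, counts are seed-independent.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ArgumentError("test_fraction must be in (0, 1)")
    table = _specimen_table(records)
    if not table:
        raise ArgumentError("no records to split")
    by_species: dict = {}
    for sp, species in table.items():
        by_species.setdefault(species, []).append(sp)
    rng = np.random.default_rng(seed)
    train, test = set(), set()
    for species in sorted(by_species):
        specs = sorted(by_species[species])
        n = len(specs)
        if n < 2:
            raise SplitInfeasibleError(
                f"species {species} has {n} specimen(s); need >= 2 to split")
        n_test = min(max(int(np.floor(n * test_fraction)), 1), n - 1)
        order = rng.permutation(n)
        test.update(specs[i] for i in order[:n_test])
        train.update(specs[i] for i in order[n_test:])
    return SplitPlan(frozenset(train), frozenset(test), frozenset(),
                     dict(table))


def subset_training_specimens(plan: SplitPlan, keep_fraction: float,
                              seed: int) -> SplitPlan:
    """Keep a per-species fraction of training specimens; rest become unused.

    Retains ``floor(keep_fraction * n_train)`` (minimum 1) per species; the
    test set is untouched.  ``keep_fraction`` of 1 returns the plan unchanged.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ArgumentError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return plan
    by_species: dict = {}
    for sp in plan.train_specimens:
        by_species.setdefault(plan.species_of.get(sp, "?"), []).append(sp)
    rng = np.random.default_rng(seed)
    keep, unused = set(), set(plan.unused_specimens)
    for species in sorted(by_species):
        specs = sorted(by_species[species])
        n_keep = max(int(np.floor(keep_fraction * len(specs))), 1)
        order = rng.permutation(len(specs))
        keep.update(specs[i] for i in order[:n_keep])
        unused.update(specs[i] for i in order[n_keep:])
    return SplitPlan(frozenset(keep), plan.test_specimens, frozenset(unused),
                     dict(plan.species_of))


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic training-time augmentation magnitudes.

    Translation is drawn uniformly in ``[-translate_frac, translate_frac]``
    of the side length per axis; colour jitter factors are drawn uniformly in
    ``1 +/- range`` (hue in ``+/- hue_range``, as a fraction of the hue
    circle).  All-zero magnitudes make augmentation the identity.
    """

    translate_frac: float = 0.1
    hflip_prob: float = 0.5
    brightness_range: float = 0.2
    contrast_range: float = 0.2
    saturation_range: float = 0.2
    hue_range: float = 0.05

    def __post_init__(self):
        if not (0.0 <= self.translate_frac <= 0.5):
            raise ArgumentError("translate_frac must be in [0, 0.5]")
        if not (0.0 <= self.hflip_prob <= 1.0):
            raise ArgumentError("hflip_prob must be in [0, 1]")
        for name in ("brightness_range", "contrast_range", "saturation_range",
                     "hue_range"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be nonnegative")

    @property
    def is_identity(self) -> bool:
        return (self.translate_frac == 0 and self.hflip_prob == 0
                and self.brightness_range == 0 and self.contrast_range == 0
                and self.saturation_range == 0 and self.hue_range == 0)


def _rgb_to_hsv(img):
    import matplotlib.colors as mcolors
    return mcolors.rgb_to_hsv(img)


def _hsv_to_rgb(img):
    import matplotlib.colors as mcolors
    return mcolors.hsv_to_rgb(img)


def augment(img: ImageRecord, cfg: AugmentConfig, seed: int) -> ImageRecord:
    """Apply seeded translation, horizontal flip and colour jitter.

    Labels, domain tag and shape are preserved; pixel values stay in [0, 1];
    deterministic given the seed; the all-zero config is the identity.
    """
    if cfg.is_identity:
        return img
    rng = np.random.default_rng(seed)
    px = img.pixels
    mask = img.foreground_mask
    h, w = mask.shape

    if cfg.hflip_prob > 0 and rng.random() < cfg.hflip_prob:
        px = px[:, ::-1]
        mask = mask[:, ::-1]
    if cfg.translate_frac > 0:
        dy = int(round(rng.uniform(-cfg.translate_frac, cfg.translate_frac) * h))
        dx = int(round(rng.uniform(-cfg.translate_frac, cfg.translate_frac) * w))
        if dy or dx:
            # Shift with edge replication, which extends the background.
            pad = np.pad(px, ((abs(dy),) * 2, (abs(dx),) * 2, (0, 0)), mode="edge")
            px = pad[abs(dy) - dy:abs(dy) - dy + h, abs(dx) - dx:abs(dx) - dx + w]
            mpad = np.pad(mask, ((abs(dy),) * 2, (abs(dx),) * 2),
                          mode="constant", constant_values=False)
            mask = mpad[abs(dy) - dy:abs(dy) - dy + h, abs(dx) - dx:abs(dx) - dx + w]

    px = np.asarray(px, dtype=np.float64).copy()
    if cfg.brightness_range > 0:
        px *= rng.uniform(1 - cfg.brightness_range, 1 + cfg.brightness_range)
    if cfg.contrast_range > 0:
        factor = rng.uniform(1 - cfg.contrast_range, 1 + cfg.contrast_range)
        mean = px.mean()
        px = mean + (px - mean) * factor
    px = np.clip(px, 0.0, 1.0)
    if cfg.saturation_range > 0 or cfg.hue_range > 0:
        hsv = _rgb_to_hsv(px)
        if cfg.hue_range > 0:
            hsv[..., 0] = (hsv[..., 0]
                           + rng.uniform(-cfg.hue_range, cfg.hue_range)) % 1.0
        if cfg.saturation_range > 0:
            hsv[..., 1] = np.clip(hsv[..., 1] * rng.uniform(
                1 - cfg.saturation_range, 1 + cfg.saturation_range), 0.0, 1.0)
        px = _hsv_to_rgb(hsv)
    return ImageRecord(np.clip(px, 0.0, 1.0), np.ascontiguousarray(mask),
                       img.species_id, img.specimen_id, img.domain, img.pose)


def resize(img: ImageRecord, side: int) -> ImageRecord:
    """Bilinear resample to ``side x side``; masks use nearest-neighbour.

    Resizing to the current size is the exact identity.
    """
    if side < 8:
        raise ArgumentError("side must be >= 8")
    h, w = img.foreground_mask.shape
    if (h, w) == (side, side):
        return img
    px = _sk_resize(img.pixels, (side, side), order=1, anti_aliasing=False,
                    preserve_range=True)
    mask = _sk_resize(img.foreground_mask.astype(float), (side, side), order=0,
                      anti_aliasing=False, preserve_range=True) > 0.5
    return ImageRecord(np.clip(px, 0.0, 1.0), mask, img.species_id,
                       img.specimen_id, img.domain, img.pose)
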