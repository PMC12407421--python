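"""Multiview rendering: camera lattice, software rasterizer, photo-domain simulator.

The camera lattice mirrors a standard multiview digitization protocol: yaw
rings at a handful of pitches plus single poses at the two poles (a yaw_step
of 20 degrees with rings at 0, +/-30, +/-60 degrees and both poles gives 92
views).  Meshes are rendered with a depth-buffered perspective rasterizer and
flat Lambertian shading — the clean "synthetic" domain.  The "photo" domain
re-renders the same geometry and then injects nuisance factors a real
photography session would add: a marked turntable-like background, brightness
jitter, colour cast, blur, sensor noise and camera-distance jitter.  With all
nuisance magnitudes at zero, the photo domain is pixel-identical to the clean
render.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ArgumentError, DegenerateViewError
from .meshforge import SpecimenRecord, TriMesh

__all__ = [
    "CameraPose",
    "ViewSphereSpec",
    "RenderConfig",
    "PhotoDomainConfig",
    "ImageRecord",
    "view_sphere_poses",
    "render",
    "render_photo_domain",
    "render_dataset",
    "save_dataset",
]

SYNTHETIC = "synthetic"
PHOTO = "photo"

# Bone-like base tint of the rendered surface (RGB multipliers).
_SURFACE_TINT = np.array([0.93, 0.89, 0.80])


@dataclass(frozen=True)
class CameraPose:
    """Camera position on the view sphere, looking at the mesh centroid.

    yaw 0 puts the camera on the +x axis; positive pitch raises it above the
    equator (pitch +90 is the dorsal, top-down view).  ``distance`` is a
    multiple of the mesh bounding radius.
    """

    yaw: float
    pitch: float
    distance: float = 3.0

    def __post_init__(self):
        if not (-90.0 <= self.pitch <= 90.0):
            raise ArgumentError("pitch must be in [-90, 90]")
        if not self.distance > 0:
            raise ArgumentError("distance must be positive")
        # A pole admits exactly one pose; pin yaw there.
        if abs(self.pitch) == 90.0 and self.yaw != 0.0:
            object.__setattr__(self, "yaw", 0.0)
        else:
            object.__setattr__(self, "yaw", float(self.yaw) % 360.0)


@dataclass(frozen=True)
class ViewSphereSpec:
    """Lattice of camera poses: yaw rings at given pitches, optional poles."""

    yaw_step: float = 20.0
    ring_pitches: tuple[float, ...] = (0.0, 30.0, -30.0, 60.0, -60.0)
    include_poles: bool = True
    distance: float = 3.0

    def __post_init__(self):
        if self.yaw_step <= 0 or (360.0 / self.yaw_step) % 1.0 != 0.0:
            raise ArgumentError("yaw_step must divide 360")
        for p in self.ring_pitches:
            if not (-90.0 < p < 90.0):
                raise ArgumentError("ring pitches must lie strictly in (-90, 90)")
        if len(set(self.ring_pitches)) != len(self.ring_pitches):
            raise ArgumentError("ring pitches must be distinct")


@dataclass(frozen=True)
class RenderConfig:
    """Rasterizer settings shared by every render of an experiment."""

    resolution: int = 64
    light_direction: tuple[float, float, float] = (0.4, 0.3, 0.85)
    ambient: float = 0.25
    diffuse: float = 0.7
    background_level: float = 0.12
    fov_degrees: float = 35.0

    def __post_init__(self):
        if self.resolution < 16:
            raise ArgumentError("resolution must be >= 16")
        if not (0.0 <= self.ambient <= 1.0):
            raise ArgumentError("ambient must be in [0, 1]")
        if not (0.0 < self.fov_degrees < 180.0):
            raise ArgumentError("fov_degrees must be in (0, 180)")


@dataclass(frozen=True)
class PhotoDomainConfig:
    """Nuisance factors of the simulated photography session.

    All magnitudes are nonnegative and every effect vanishes at zero, so the
    all-zero config reproduces the clean render exactly.  ``session_confound``
    ties the background marking pattern to the photography session (one
    session per species), emulating a stable contextual cue (turntable
    markings) a model can exploit instead of morphology.
    """

    background_marking_density: float = 0.0
    brightness_jitter_sd: float = 0.0
    color_cast_strength: float = 0.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    distance_jitter_sd: float = 0.0
    session_confound: bool = False

    def __post_init__(self):
        for name in ("background_marking_density", "brightness_jitter_sd",
                     "color_cast_strength", "blur_sigma", "noise_sd",
                     "distance_jitter_sd"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be nonnegative")


@dataclass
class ImageRecord:
    """A rendered image plus its labels, domain tag and camera pose."""

    pixels: np.ndarray           # H x W x 3 floats in [0, 1]
    foreground_mask: np.ndarray  # H x W bool, True where the mesh rasterized
    species_id: str
    specimen_id: str
    domain: str
    pose: CameraPose

    def __post_init__(self):
        if self.domain not in (SYNTHETIC, PHOTO):
            raise ArgumentError(f"unknown domain '{self.domain}'")


def view_sphere_poses(spec: ViewSphereSpec) -> list[CameraPose]:
    """Enumerate the lattice: pitch descending, yaw ascending, poles included
    as single poses.  Pose count = (360/yaw_step) * n_rings + 2*include_poles."""
    n_yaw = int(round(360.0 / spec.yaw_step))
    poses: list[CameraPose] = []
    if spec.include_poles:
        poses.append(CameraPose(0.0, 90.0, spec.distance))
    for pitch in sorted(spec.ring_pitches, reverse=True):
        for k in range(n_yaw):
            poses.append(CameraPose(k * spec.yaw_step, pitch, spec.distance))
    if spec.include_poles:
        poses.append(CameraPose(0.0, -90.0, spec.distance))
    return poses


def _camera_basis(pose: CameraPose, center: np.ndarray, radius: float):
    yaw = np.deg2rad(pose.yaw)
    pitch = np.deg2rad(pose.pitch)
    d = pose.distance * radius
    eye = center + d * np.array([
        np.cos(pitch) * np.cos(yaw),
        np.cos(pitch) * np.sin(yaw),
        np.sin(pitch),
    ])
    forward = center - eye
    forward /= np.linalg.norm(forward)
    # Up = world z, except at the poles where z is degenerate; use world x.
    up = np.array([1.0, 0.0, 0.0]) if abs(pose.pitch) == 90.0 else \
        np.array([0.0, 0.0, 1.0])
    right = np.cross(forward, up)
    right /= np.linalg.norm(right)
    true_up = np.cross(right, forward)
    return eye, right, true_up, forward


def render(mesh: TriMesh, pose: CameraPose, cfg: RenderConfig,
           species_id: str = "", specimen_id: str = "",
           domain: str = SYNTHETIC) -> ImageRecord:
    """Depth-buffered perspective render with flat Lambertian shading.

    Shading per triangle: ``ambient + diffuse * |n . light|`` (two-sided, no
    back-face culling so thin features stay visible), tinted by a fixed
    bone-like surface colour; uniform background at ``background_level``.
    Deterministic.
    """
    res = cfg.resolution
    center = mesh.centroid()
    radius = mesh.bounding_radius()
    eye, right, up, forward = _camera_basis(pose, center, radius)

    # Camera-space coordinates: u (right), v (up), w (depth along forward).
    rel = mesh.vertices - eye
    u = rel @ right
    v = rel @ up
    w = rel @ forward
    if np.all(w <= 1e-9):
        raise DegenerateViewError("mesh entirely behind the camera")

    focal = 1.0 / np.tan(np.deg2rad(cfg.fov_degrees) / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndc_x = focal * u / w
        ndc_y = focal * v / w
    px = (ndc_x + 1.0) * 0.5 * (res - 1)
    py = (1.0 - (ndc_y + 1.0) * 0.5) * (res - 1)

    light = np.asarray(cfg.light_direction, dtype=float)
    light = light / np.linalg.norm(light)

    tri = mesh.faces
    p0, p1, p2 = mesh.vertices[tri[:, 0]], mesh.vertices[tri[:, 1]], mesh.vertices[tri[:, 2]]
    normals = np.cross(p1 - p0, p2 - p0)
    nlen = np.linalg.norm(normals, axis=1)
    good_n = nlen > 1e-15
    shade = cfg.ambient + cfg.diffuse * np.abs(normals @ light) / np.where(
        good_n, nlen, 1.0)
    shade = np.clip(np.where(good_n, shade, cfg.ambient), 0.0, 1.0)

    depth = np.full((res, res), np.inf)
    shade_buf = np.full((res, res), -1.0)

    xs = px[tri]      # (M, 3) pixel coordinates per triangle corner
    ys = py[tri]
    ws = w[tri]
    front = np.all(ws > 1e-9, axis=1)   # clip triangles crossing the camera plane
    order = np.nonzero(front & good_n)[0]

    for fi in order:
        x0, x1, x2 = xs[fi]
        y0, y1, y2 = ys[fi]
        minx = max(int(np.floor(min(x0, x1, x2))), 0)
        maxx = min(int(np.ceil(max(x0, x1, x2))), res - 1)
        miny = max(int(np.floor(min(y0, y1, y2))), 0)
        maxy = min(int(np.ceil(max(y0, y1, y2))), res - 1)
        if minx > maxx or miny > maxy:
            continue
        det = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if abs(det) < 1e-12:
            continue
        gx, gy = np.meshgrid(np.arange(minx, maxx + 1),
                             np.arange(miny, maxy + 1))
        b1 = ((gx - x0) * (y2 - y0) - (x2 - x0) * (gy - y0)) / det
        b2 = ((x1 - x0) * (gy - y0) - (gx - x0) * (y1 - y0)) / det
        b0 = 1.0 - b1 - b2
        inside = (b0 >= 0) & (b1 >= 0) & (b2 >= 0)
        if not inside.any():
            continue
        # Perspective-correct depth via interpolated 1/w.
        inv_w = b0 / ws[fi, 0] + b1 / ws[fi, 1] + b2 / ws[fi, 2]
        z = 1.0 / inv_w
        yy, xx = gy[inside], gx[inside]
        zz = z[inside]
        closer = zz < depth[yy, xx]
        yy, xx, zz = yy[closer], xx[closer], zz[closer]
        depth[yy, xx] = zz
        shade_buf[yy, xx] = shade[fi]

    mask = shade_buf >= 0.0
    if not mask.any():
        raise DegenerateViewError("mesh projects to no pixels at this pose")
    img = np.empty((res, res, 3))
    img[:] = cfg.background_level
    img[mask] = shade_buf[mask, None] * _SURFACE_TINT
    return ImageRecord(np.clip(img, 0.0, 1.0), mask, species_id, specimen_id,
                       domain, pose)


def _marked_background(res: int, density: float, rng: np.random.Generator,
                       base_level: float) -> np.ndarray:
    """Turntable-like background: dark field with radial tick marks and a rim."""
    img = np.full((res, res, 3), base_level)
    if density <= 0:
        return img
    yy, xx = np.mgrid[0:res, 0:res]
    cx = cy = (res - 1) / 2.0
    r = np.hypot(xx - cx, yy - cy) / (res / 2.0)
    theta = np.arctan2(yy - cy, xx - cx)
    n_marks = max(1, int(round(12 * density)))
    phase = rng.uniform(0, 2 * np.pi)
    width = 0.06 + 0.1 * rng.random()
    marks = (np.cos(n_marks * theta + phase) > 1.0 - width) & (r > 0.55) & (r < 0.97)
    rim_r = 0.75 + 0.15 * rng.random()
    rim = np.abs(r - rim_r) < 0.012
    level = base_level + 0.5 * min(density, 1.5)
    img[marks | rim] = np.clip(level, 0.0, 1.0)
    return img


def render_photo_domain(mesh: TriMesh, pose: CameraPose, cfg: RenderConfig,
                        pd: PhotoDomainConfig, rng_seed: int,
                        species_id: str = "", specimen_id: str = "",
                        background_key: int | None = None) -> ImageRecord:
    """Render into the simulated photograph domain.

    The clean render is composited over a procedurally marked background, then
    brightness jitter, colour cast, Gaussian blur and sensor noise are applied
    in that order.  ``background_key`` seeds the background pattern; when
    ``pd.session_confound`` is set, callers pass a per-specimen key so the
    pattern becomes a specimen-identity cue.  Deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    if pd.distance_jitter_sd > 0:
        factor = float(np.exp(pd.distance_jitter_sd * rng.standard_normal()))
        pose = replace(pose, distance=pose.distance * factor)
    clean = render(mesh, pose, cfg, species_id, specimen_id, domain=PHOTO)
    img = clean.pixels.copy()
    mask = clean.foreground_mask

    if pd.background_marking_density > 0:
        bg_rng = np.random.default_rng(
            rng_seed if background_key is None else background_key)
        bg = _marked_background(cfg.resolution, pd.background_marking_density,
                                bg_rng, cfg.background_level)
        img = np.where(mask[:, :, None], img, bg)
    if pd.brightness_jitter_sd > 0:
        img = img * float(np.exp(pd.brightness_jitter_sd * rng.standard_normal()))
    if pd.color_cast_strength > 0:
        cast = 1.0 + pd.color_cast_strength * rng.standard_normal(3)
        img = img * np.clip(cast, 0.2, 2.0)
    if pd.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(pd.blur_sigma, pd.blur_sigma, 0))
    if pd.noise_sd > 0:
        img = img + pd.noise_sd * rng.standard_normal(img.shape)
    return ImageRecord(np.clip(img, 0.0, 1.0), mask, species_id, specimen_id,
                       PHOTO, pose)


def render_dataset(bank: list[SpecimenRecord], spec: ViewSphereSpec,
                   cfg: RenderConfig, pd: PhotoDomainConfig | None = None,
                   seed: int = 0) -> tuple[list[ImageRecord], "object"]:
    """Render every specimen from every pose.

    Returns ``len(bank) * n_poses`` records plus a manifest DataFrame with
    columns specimen_id, species_id, yaw, pitch, domain, index.  Passing a
    ``PhotoDomainConfig`` renders the photo domain, otherwise the clean
    synthetic domain.
    """
    import pandas as pd_mod

    if not bank:
        raise ArgumentError("bank must be nonempty")
    poses = view_sphere_poses(spec)
    records: list[ImageRecord] = []
    rows = []
    for si, rec in enumerate(bank):
        for pi, pose in enumerate(poses):
            try:
                if pd is None:
                    img = render(rec.mesh, pose, cfg, rec.species_id,
                                 rec.specimen_id)
                else:
                    img_seed = int(np.random.SeedSequence(
                        entropy=seed, spawn_key=(si, pi)).generate_state(1)[0]
                        % (2 ** 31))
                    bg_key = None
                    if pd.session_confound:
                        # One photography session per species: the background
                        # pattern is a stable contextual cue shared by every
                        # specimen of the species, train and test alike.
                        bg_key = int(np.random.SeedSequence(
                            entropy=zlib.crc32(rec.species_id.encode()),
                            spawn_key=(997,)).generate_state(1)[0] % (2 ** 31))
                    img = render_photo_domain(rec.mesh, pose, cfg, pd, img_seed,
                                              rec.species_id, rec.specimen_id,
                                              background_key=bg_key)
            except DegenerateViewError as e:
                raise DegenerateViewError(
                    f"specimen {rec.specimen_id}: {e}") from e
            records.append(img)
            rows.append((rec.specimen_id, rec.species_id, pose.yaw, pose.pitch,
                         img.domain, len(records) - 1))
    manifest = pd_mod.DataFrame(
        rows, columns=["specimen_id", "species_id", "yaw", "pitch", "domain",
                       "index"])
    return records, manifest


def save_dataset(records: list[ImageRecord], manifest, out_dir) -> None:
    """Write 8-bit RGB PNGs, boolean mask PNGs and the CSV manifest."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rec in enumerate(records):
        name = f"{rec.specimen_id}_y{rec.pose.yaw:05.1f}_p{rec.pose.pitch:+05.1f}_{rec.domain}.png"
        iio.imwrite(out / "images" / name,
                    (rec.pixels * 255).round().astype(np.uint8))
        iio.imwrite(out / "masks" / name,
                    (rec.foreground_mask * 255).astype(np.uint8))
        paths.append(f"images/{name}")
    manifest = manifest.copy()
    manifest["path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
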