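"""Procedural specimen forge: seedable 3D specimen meshes plus asset standardization.

The forge emulates a digitization workflow for skull-like specimens: each
*species* is a point in a small morphology parameter space (relative width and
height, cross-section squareness, rostrum taper, sagittal-crest amplitude and
lateral bump arcs standing in for tooth rows), and each *specimen* is a seeded
Gaussian perturbation of its species' parameters applied to a deformed
superellipsoid.  Species placed far apart in parameter space relative to the
within-species spread are visually distinguishable from most view angles,
which makes the downstream classification task learnable by construction.

Also provided are the two asset-standardization operations applied before
rendering — uniform rescaling to a standard anterior-posterior length and
decimation to a polygon budget — and Wavefront OBJ I/O restricted to v/f
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

from .errors import ArgumentError, DegenerateMeshError, ObjParseError

__all__ = [
    "TriMesh",
    "SpeciesSpec",
    "SpecimenRecord",
    "PARAM_NAMES",
    "PARAM_RANGES",
    "default_species_specs",
    "generate_specimen",
    "generate_species_bank",
    "standardize_length",
    "decimate",
    "read_obj",
    "write_obj",
    "bank_manifest",
]

# Anterior-posterior axis convention: local +x points anterior (rostrum).
ANTERIOR_AXIS = 0


@dataclass
class TriMesh:
    """A triangle mesh: (N, 3) float vertices and (M, 3) integer faces."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DegenerateMeshError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DegenerateMeshError("faces must be an (M, 3) array")
        if len(self.vertices) < 4 or len(self.faces) < 4:
            raise DegenerateMeshError(
                f"mesh needs >= 4 vertices and >= 4 faces, got "
                f"{len(self.vertices)} / {len(self.faces)}"
            )
        if not np.all(np.isfinite(self.vertices)):
            raise DegenerateMeshError("vertex coordinates must be finite")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise DegenerateMeshError("face indices out of vertex range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def extent(self, axis: int = ANTERIOR_AXIS) -> float:
        v = self.vertices[:, axis]
        return float(v.max() - v.min())

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def bounding_radius(self) -> float:
        return float(np.linalg.norm(self.vertices - self.centroid(), axis=1).max())

    def copy(self, name: str | None = None) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(),
                       self.name if name is None else name)


# Morphology parameters, their meaning and plausible ranges (unitless except
# where noted; lengths are fractions of the anterior-posterior length).
PARAM_NAMES = (
    "width_ratio",      # mediolateral extent / length
    "height_ratio",     # dorsoventral extent / length
    "squareness",       # superellipsoid cross-section exponent
    "rostrum_taper",    # residual width/height factor at the anterior tip
    "crest_amplitude",  # dorsal midline ridge height
    "bump_amplitude",   # ventral lateral bump-arc height (tooth-row analogue)
    "bump_count",       # bumps per lateral arc
)
PARAM_RANGES = np.array([
    (0.35, 0.80),
    (0.30, 0.70),
    (1.60, 4.00),
    (0.20, 0.80),
    (0.00, 0.22),
    (0.00, 0.10),
    (3.00, 9.00),
])
# Hard floors so a perturbed specimen can never degenerate.
_PARAM_FLOOR = np.array([0.10, 0.10, 1.05, 0.05, 0.0, 0.0, 1.0])
_PARAM_CEIL = np.array([1.50, 1.50, 8.00, 1.00, 0.5, 0.3, 16.0])


@dataclass
class SpeciesSpec:
    """Morphology of one species: mean shape parameters and within-species spread."""

    species_id: str
    base_shape_params: np.ndarray
    within_species_sd: np.ndarray
    base_length: float = 1.0

    def __post_init__(self):
        self.base_shape_params = np.asarray(self.base_shape_params, dtype=np.float64)
        self.within_species_sd = np.asarray(self.within_species_sd, dtype=np.float64)
        if self.base_shape_params.shape != (len(PARAM_NAMES),):
            raise ArgumentError(
                f"base_shape_params must have {len(PARAM_NAMES)} entries"
            )
        if self.within_species_sd.shape != self.base_shape_params.shape:
            raise ArgumentError("within_species_sd shape mismatch")
        if np.any(self.within_species_sd < 0):
            raise ArgumentError("within_species_sd must be nonnegative")
        if not self.base_length > 0:
            raise ArgumentError("base_length must be positive")


@dataclass
class SpecimenRecord:
    """One generated specimen: mesh plus its identity and reproduction seed."""

    specimen_id: str
    species_id: str
    mesh: TriMesh
    seed: int
    shape_params: np.ndarray | None = field(default=None, repr=False)


def _base_sphere(subdivisions: int = 3) -> tuple[np.ndarray, np.ndarray]:
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=0.5)
    return np.asarray(ico.vertices, dtype=np.float64), np.asarray(ico.faces, dtype=np.int64)


def _deform(vertices: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Deform a radius-0.5 sphere into the parameterized specimen shape."""
    width, height, square, taper, crest, bump_amp, bump_n = p
    x, y, z = vertices.T.copy()

    # Superellipsoid cross-section: remap the circular section |y|^2+|z|^2
    # to exponent `square` at constant polar angle, preserving the radius
    # profile along x.
    r = np.hypot(y, z)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arctan2(z, y)
        c, s = np.cos(theta), np.sin(theta)
        denom = (np.abs(c) ** square + np.abs(s) ** square) ** (1.0 / square)
        denom = np.where(denom > 0, denom, 1.0)
    scale_cs = 1.0 / denom
    y = r * c * scale_cs
    z = r * s * scale_cs

    # Anteroposterior taper: shrink the cross-section toward the rostrum (+x).
    t = np.clip(x + 0.5, 0.0, 1.0)            # 0 posterior .. 1 anterior
    f = 1.0 - (1.0 - taper) * t ** 2
    y *= f
    z *= f

    # Aspect ratios (length fixed at 1 before base_length scaling).
    y *= width
    z *= height

    # Dorsal sagittal crest: a midline ridge, strongest mid-skull.
    dorsal = np.clip(z, 0.0, None) / max(height * 0.5, 1e-9)
    ridge = np.exp(-((y / (0.18 * width + 1e-9)) ** 2)) * np.cos(np.pi * x) ** 2
    z += crest * ridge * dorsal

    # Ventral lateral bump arcs (tooth-row analogue): two arcs mirrored in y,
    # bumps repeating along x on the ventral surface.
    ventral = np.clip(-z, 0.0, None) / max(height * 0.5, 1e-9)
    arc = np.exp(-(((np.abs(y) - 0.45 * width * f) / (0.12 * width + 1e-9)) ** 2))
    waves = np.clip(np.sin(np.round(bump_n) * np.pi * (x + 0.5)), 0.0, None)
    z -= bump_amp * arc * waves * ventral

    return np.column_stack([x, y, z])


def generate_specimen(spec: SpeciesSpec, specimen_seed: int,
                      subdivisions: int = 3) -> TriMesh:
    """Generate one specimen mesh from a species spec and a seed.

    The specimen's shape parameters are ``base_shape_params`` plus a seeded
    Gaussian perturbation scaled elementwise by ``within_species_sd``; the
    same ``(spec, specimen_seed)`` pair always yields an identical mesh.
    """
    rng = np.random.default_rng(specimen_seed)
    p = spec.base_shape_params + spec.within_species_sd * rng.standard_normal(
        len(PARAM_NAMES))
    p = np.clip(p, _PARAM_FLOOR, _PARAM_CEIL)
    verts, faces = _base_sphere(subdivisions)
    verts = _deform(verts, p)
    # Standardize anterior-posterior extent to base_length.
    ext = verts[:, ANTERIOR_AXIS].max() - verts[:, ANTERIOR_AXIS].min()
    verts *= spec.base_length / ext
    mesh = TriMesh(verts, faces, name=f"{spec.species_id}:{specimen_seed}")
    return mesh


def default_species_specs(n_species: int, seed: int,
                          sd_fraction: float = 0.03,
                          separation: float = 6.0,
                          base_length: float = 1.0,
                          max_tries: int = 5000) -> list[SpeciesSpec]:
    """Draw well-separated species parameter vectors.

    Candidates are sampled uniformly in the per-parameter ranges and accepted
    only if, in range-normalized coordinates, they keep a minimum distance of
    ``separation * sd_fraction * sqrt(n_params)`` from every accepted species.
    ``sd_fraction`` sets the within-species standard deviation as a fraction
    of each parameter's range.
    """
    rng = np.random.default_rng(seed)
    lo, hi = PARAM_RANGES[:, 0], PARAM_RANGES[:, 1]
    span = hi - lo
    sd = sd_fraction * span
    min_dist = separation * sd_fraction * np.sqrt(len(PARAM_NAMES))
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < n_species:
        tries += 1
        if tries > max_tries:
            raise ArgumentError(
                f"could not place {n_species} species with separation "
                f"{separation}; lower separation or n_species")
        cand = rng.uniform(lo, hi)
        cand_n = (cand - lo) / span
        if all(np.linalg.norm(cand_n - (a - lo) / span) >= min_dist
               for a in accepted):
            accepted.append(cand)
    return [
        SpeciesSpec(species_id=f"species_{i:02d}", base_shape_params=a,
                    within_species_sd=sd, base_length=base_length)
        for i, a in enumerate(accepted)
    ]


def generate_species_bank(n_species: int, specimens_per_species: int, seed: int,
                          drop: list[tuple[int, int]] | None = None,
                          species_specs: list[SpeciesSpec] | None = None,
                          subdivisions: int = 3) -> list[SpecimenRecord]:
    """Generate a bank of specimen meshes for ``n_species`` species.

    ``drop`` emulates loss of scans: each ``(species_index, count)`` entry
    removes the last ``count`` specimens of that species (e.g. a corrupted
    scan).  Deterministic given ``seed``.
    """
    if n_species < 2:
        raise ArgumentError("n_species must be >= 2")
    if specimens_per_species < 2:
        raise ArgumentError("specimens_per_species must be >= 2")
    drop = list(drop or [])
    dropped = dict()
    for s_idx, count in drop:
        if not (0 <= s_idx < n_species):
            raise ArgumentError(f"drop species index {s_idx} out of range")
        if count >= specimens_per_species:
            raise ArgumentError("cannot drop all specimens of a species")
        dropped[s_idx] = dropped.get(s_idx, 0) + count

    if species_specs is None:
        species_specs = default_species_specs(n_species, seed)
    elif len(species_specs) != n_species:
        raise ArgumentError("species_specs length must equal n_species")

    records: list[SpecimenRecord] = []
    for s_idx, spec in enumerate(species_specs):
        keep = specimens_per_species - dropped.get(s_idx, 0)
        for i in range(keep):
            # Stable per-specimen seed stream, independent of drop pattern.
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(s_idx, i))
            sp_seed = int(ss.generate_state(1)[0] % (2 ** 31))
            mesh = generate_specimen(spec, sp_seed, subdivisions=subdivisions)
            rng = np.random.default_rng(sp_seed)
            p = spec.base_shape_params + spec.within_species_sd * \
                rng.standard_normal(len(PARAM_NAMES))
            records.append(SpecimenRecord(
                specimen_id=f"{spec.species_id}_sp{i:03d}",
                species_id=spec.species_id,
                mesh=mesh, seed=sp_seed,
                shape_params=np.clip(p, _PARAM_FLOOR, _PARAM_CEIL)))
    return records


def bank_manifest(bank: list[SpecimenRecord]):
    """Forge manifest as a pandas DataFrame (specimen_id, species_id, seed)."""
    import pandas as pd

    return pd.DataFrame(
        [(r.specimen_id, r.species_id, r.seed) for r in bank],
        columns=["specimen_id", "species_id", "seed"])


def standardize_length(mesh: TriMesh, target_length: float,
                       axis: int = ANTERIOR_AXIS) -> TriMesh:
    """Uniformly scale so the bounding-box extent along ``axis`` equals
    ``target_length``, and translate the vertex centroid to the origin.

    Idempotent, and invariant to any uniform pre-scaling of the input.
    """
    if not target_length > 0:
        raise ArgumentError("target_length must be positive")
    ext = mesh.extent(axis)
    if ext <= 0:
        raise DegenerateMeshError(f"mesh has zero extent along axis {axis}")
    scale = target_length / ext
    verts = mesh.vertices * scale
    verts = verts - verts.mean(axis=0)
    return TriMesh(verts, mesh.faces.copy(), mesh.name)


def _cluster_decimate(mesh: TriMesh, n_cells: int) -> tuple[np.ndarray, np.ndarray]:
    """Vertex clustering on a uniform n_cells^3 grid over the bounding box."""
    v = mesh.vertices
    lo = v.min(axis=0)
    span = v.max(axis=0) - lo
    span[span == 0] = 1.0
    cell = np.minimum((((v - lo) / span) * n_cells).astype(np.int64), n_cells - 1)
    key = (cell[:, 0] * n_cells + cell[:, 1]) * n_cells + cell[:, 2]
    uniq, inverse = np.unique(key, return_inverse=True)
    new_verts = np.zeros((len(uniq), 3))
    counts = np.bincount(inverse, minlength=len(uniq)).astype(float)
    for d in range(3):
        new_verts[:, d] = np.bincount(inverse, weights=v[:, d],
                                      minlength=len(uniq)) / counts
    f = inverse[mesh.faces]
    # Drop collapsed faces (repeated vertices) and duplicates.
    ok = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    f = f[ok]
    if len(f):
        canon = np.sort(f, axis=1)
        _, first = np.unique(canon, axis=0, return_index=True)
        f = f[np.sort(first)]
    return new_verts, f


def decimate(mesh: TriMesh, target_faces: int) -> TriMesh:
    """Reduce the face count to at most ``target_faces`` by vertex clustering.

    Uses the finest uniform grid whose clustered mesh meets the face budget;
    meshes already within budget are returned unchanged.
    """
    if target_faces < 4:
        raise ArgumentError("target_faces must be >= 4")
    if mesh.n_faces <= target_faces:
        return mesh

    best: tuple[np.ndarray, np.ndarray] | None = None
    lo_n, hi_n = 1, 128
    # Binary search the largest grid resolution meeting the budget; face
    # count grows (approximately monotonically) with resolution.
    while lo_n <= hi_n:
        mid = (lo_n + hi_n) // 2
        verts, faces = _cluster_decimate(mesh, mid)
        if len(faces) <= target_faces:
            if len(faces) >= 4 and len(verts) >= 4:
                best = (verts, faces)
            lo_n = mid + 1
        else:
            hi_n = mid - 1
    if best is None:
        raise DegenerateMeshError(
            f"decimation to {target_faces} faces degenerates the mesh")
    verts, faces = best
    # Compact unused vertices.
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(verts[used], remap[faces], mesh.name)


def write_obj(mesh: TriMesh, path) -> None:
    """Write v/f records with 17-significant-digit coordinates (lossless)."""
    mesh.validate()
    with open(path, "w") as fh:
        fh.write(f"# skulladapt OBJ: {mesh.name}\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.17g} {y:.17g} {z:.17g}\n")
        for a, b, c in mesh.faces + 1:
            fh.write(f"f {a} {b} {c}\n")


def read_obj(path, name: str | None = None) -> TriMesh:
    """Read a Wavefront OBJ, honouring only v and f records.

    Face indices are 1-based; negative indices are resolved relative to the
    vertices defined so far, per the OBJ standard.  Polygonal faces are
    fan-triangulated.  Normals, texture coordinates and materials are ignored.
    """
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            rec = tokens[0]
            if rec == "v":
                if len(tokens) < 4:
                    raise ObjParseError("vertex record needs 3 coordinates", lineno)
                try:
                    vertices.append([float(t) for t in tokens[1:4]])
                except ValueError:
                    raise ObjParseError(f"bad vertex coordinates {tokens[1:4]}",
                                        lineno) from None
            elif rec == "f":
                if len(tokens) < 4:
                    raise ObjParseError("face record needs >= 3 vertices", lineno)
                idx = []
                for tok in tokens[1:]:
                    head = tok.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError:
                        raise ObjParseError(f"bad face index '{tok}'", lineno) from None
                    if i == 0:
                        raise ObjParseError("face index 0 is invalid", lineno)
                    resolved = len(vertices) + i if i < 0 else i - 1
                    if not (0 <= resolved < len(vertices)):
                        raise ObjParseError(
                            f"face index {i} out of range (have "
                            f"{len(vertices)} vertices)", lineno)
                    idx.append(resolved)
                for k in range(1, len(idx) - 1):
                    faces.append([idx[0], idx[k], idx[k + 1]])
            # every other record type is ignored
    if name is None:
        name = str(path)
    try:
        return TriMesh(np.array(vertices, dtype=np.float64),
                       np.array(faces, dtype=np.int64), name)
    except DegenerateMeshError as e:
        raise ObjParseError(str(e), lineno if vertices or faces else 0) from e
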