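"""Parametric molar-like surfaces, opposing surfaces, and training triplets.

Real crown scans cannot be redistributed, so every geometric and learning
stage in this package is exercised on synthetic occlusal surfaces built from
a closed-form height field over a square crown footprint:

    z(x, y) = dome(x, y) + sum_k cusp_k(x, y) - trench(x, y)

The dome is a broad Gaussian base; each cusp is a Gaussian bump (3-5 cusps
placed around a circle, like the buccal/lingual cusps of a molar); the
trench carves a connected valley (fissure) network of a given depth and
width along a star-shaped skeleton polyline through the inter-cusp saddles.
The skeleton runs through the crown center, so the fissure network is always
connected, emulating the central groove pattern of posterior teeth.

An opposing (antagonist) surface is the z-mirrored complement offset so that
the minimum vertical gap equals a prescribed occlusal clearance.

Training triplets mirror the network dataset layout: a mask image x (depth
image with a disk of the occlusal region blanked to 0, the "missing" area),
the opposing-tooth image op, and the target image y holding the depth values
inside the fissure band and 0 elsewhere.

What this generator does NOT emulate: scan noise, anatomical variability of
real dentitions, wear facets, or neighbouring-tooth context.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .depth_projection import DepthImage, ProjectionConfig, distance_grid, project_mesh

__all__ = [
    "ToothSpec",
    "SampleTriplet",
    "height_field",
    "load_manifest",
    "generate_tooth_mesh",
    "generate_opposing_mesh",
    "build_triplet",
    "generate_dataset",
    "random_tooth_spec",
    "random_patch_mesh",
]

#: half-side of the square crown footprint, mm (a molar crown is ~8-10 mm wide)
FOOTPRINT_HALF = 4.0


@dataclass(frozen=True)
class ToothSpec:
    """Closed-form description of one synthetic occlusal surface.

    Heights and widths in mm.  ``cusp_centers`` are XY positions inside the
    footprint; ``skeleton`` is an ordered polyline (list of XY points) along
    which the fissure trench is carved.
    """

    cusp_centers: tuple[tuple[float, float], ...]
    cusp_heights: tuple[float, ...]
    cusp_widths: tuple[float, ...]
    skeleton: tuple[tuple[float, float], ...]
    groove_depth: float = 0.8
    groove_width: float = 0.9
    dome_height: float = 2.0
    dome_width: float = 3.2
    grid_resolution: int = 129
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.cusp_centers)
        if not (len(self.cusp_heights) == len(self.cusp_widths) == k):
            raise ValueError("cusp centers/heights/widths lengths differ")
        if self.groove_depth < 0:
            raise ValueError("groove depth must be >= 0")
        if k and min(self.cusp_heights) <= self.groove_depth - self.dome_height:
            raise ValueError("cusps must rise above the groove floor")
        if self.grid_resolution < 65:
            raise ValueError("grid resolution too coarse for a crown surface")
        for p in self.skeleton:
            if max(abs(p[0]), abs(p[1])) > FOOTPRINT_HALF:
                raise ValueError("skeleton leaves the crown footprint")


@dataclass
class SampleTriplet:
    """(mask x, opposing op, target y) training example sharing one grid."""

    x: DepthImage
    op: DepthImage
    y: DepthImage

    def __post_init__(self) -> None:
        if not (self.x.pixels.shape == self.op.pixels.shape == self.y.pixels.shape):
            raise ValueError("triplet images must share one resolution")


def _segment_distance(px: np.ndarray, py: np.ndarray, skeleton) -> np.ndarray:
    """Distance from each (px, py) to the nearest skeleton segment."""
    pts = np.asarray(skeleton, dtype=float)
    if len(pts) == 1:
        return np.hypot(px - pts[0, 0], py - pts[0, 1])
    best = np.full(px.shape, np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            t = np.zeros_like(px)
        else:
            t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom
            t = np.clip(t, 0.0, 1.0)
        dx = px - (a[0] + t * ab[0])
        dy = py - (a[1] + t * ab[1])
        best = np.minimum(best, np.hypot(dx, dy))
    return best


def height_field(spec: ToothSpec, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Evaluate the closed-form occlusal height field z(x, y) (mm)."""
    z = spec.dome_height * np.exp(-(px**2 + py**2) / (2.0 * spec.dome_width**2))
    for (cx, cy), h, w in zip(spec.cusp_centers, spec.cusp_heights, spec.cusp_widths):
        z = z + h * np.exp(-((px - cx) ** 2 + (py - cy) ** 2) / (2.0 * w**2))
    if spec.skeleton and spec.groove_depth > 0:
        dist = _segment_distance(px, py, spec.skeleton)
        sigma = spec.groove_width / 2.0
        z = z - spec.groove_depth * np.exp(-(dist / sigma) ** 2)
    return z


def generate_tooth_mesh(spec: ToothSpec) -> trimesh.Trimesh:
    """Triangulate the height field on a regular grid over the footprint.

    Deterministic: the surface is a pure function of the spec.  The occlusal
    surface faces +Z.
    """
    r = spec.grid_resolution
    xs = np.linspace(-FOOTPRINT_HALF, FOOTPRINT_HALF, r)
    px, py = np.meshgrid(xs, xs, indexing="xy")
    z = height_field(spec, px, py)
    vertices = np.column_stack([px.ravel(), py.ravel(), z.ravel()])

    idx = np.arange(r * r).reshape(r, r)
    a = idx[:-1, :-1].ravel()
    b = idx[:-1, 1:].ravel()
    c = idx[1:, :-1].ravel()
    d = idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([a, b, d]), np.column_stack([a, d, c])], axis=0
    )
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def generate_opposing_mesh(mesh: trimesh.Trimesh, clearance: float = 0.5) -> trimesh.Trimesh:
    """Z-mirrored complement of a crown surface with a given occlusal gap (mm).

    The opposing surface is z' = C - z with C chosen so the minimum vertical
    gap equals ``clearance``; its contacting side therefore faces -Z and sits
    above the crown, like an antagonist at maximum intercuspation.
    """
    if clearance < 0:
        raise ValueError("clearance must be >= 0")
    v = np.asarray(mesh.vertices, dtype=float).copy()
    zmax = v[:, 2].max()
    v[:, 2] = 2.0 * zmax + clearance - v[:, 2]
    faces = np.asarray(mesh.faces)[:, ::-1]  # keep outward orientation
    return trimesh.Trimesh(vertices=v, faces=faces, process=False)


def _flip_for_projection(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Rotate pi about the X axis so a -Z-facing occlusal surface faces +Z."""
    v = np.asarray(mesh.vertices, dtype=float).copy()
    v[:, 1] *= -1.0
    v[:, 2] *= -1.0
    return trimesh.Trimesh(vertices=v, faces=np.asarray(mesh.faces)[:, ::-1], process=False)


def build_triplet(
    mesh: trimesh.Trimesh,
    opposing: trimesh.Trimesh,
    skeleton,
    config: ProjectionConfig = ProjectionConfig(),
    mask_radius: float = 2.5,
    groove_width: float = 0.9,
) -> SampleTriplet:
    """Project a crown/antagonist pair into a (x, op, y) training triplet.

    x  : crown depth image with a disk of radius ``mask_radius`` (mm) around
         the footprint centroid forced to 0 (the missing occlusal region).
    op : depth image of the opposing tooth viewed from its own occlusal side.
    y  : crown depth image restricted to the fissure band - pixels whose grid
         position lies within ``groove_width`` (mm) of the skeleton polyline.

    x and y share the crown's projection grid exactly.
    """
    full = project_mesh(mesh, config)
    meta = full.meta
    res = config.resolution

    jj, ii = np.meshgrid(np.arange(res), np.arange(res), indexing="xy")
    gx = meta.origin[0] + (jj + 0.5) * meta.spacing
    gy = meta.origin[1] - (ii + 0.5) * meta.spacing

    lo, hi = mesh.bounds
    cx, cy = 0.5 * (lo[0] + hi[0]), 0.5 * (lo[1] + hi[1])
    x_pixels = full.pixels.copy()
    x_pixels[np.hypot(gx - cx, gy - cy) <= mask_radius] = 0
    x_img = DepthImage(pixels=x_pixels, meta=meta)

    band = _segment_distance(gx, gy, skeleton) <= groove_width if len(skeleton) else np.zeros((res, res), bool)
    y_pixels = np.where(band, full.pixels, 0).astype(np.uint8)
    y_img = DepthImage(pixels=y_pixels, meta=meta)

    op_img = project_mesh(_flip_for_projection(opposing), config)
    return SampleTriplet(x=x_img, op=op_img, y=y_img)


def _default_skeleton(cusp_centers):
    """Closed fissure ring through the inter-cusp saddles, plus spokes to the
    central pit - the connected valley network of a molar-like surface.

    The polyline starts with the k saddle points (ring part, closed back to
    the first), then traverses center-to-saddle spokes; repeated vertices are
    harmless for distance-to-skeleton computations.
    """
    centers = np.asarray(cusp_centers, dtype=float)
    angles = np.sort(np.arctan2(centers[:, 1], centers[:, 0]))
    gaps = (angles + np.roll(angles, -1) + np.where(np.roll(angles, -1) < angles, 2 * np.pi, 0)) / 2.0
    radius = 0.9 * float(np.linalg.norm(centers, axis=1).mean())
    saddles = [(radius * np.cos(g), radius * np.sin(g)) for g in gaps]
    pts: list[tuple[float, float]] = list(saddles) + [saddles[0]]
    for s in saddles:
        pts.append((0.0, 0.0))
        pts.append(s)
    return tuple(pts)


def random_tooth_spec(rng: np.random.Generator, grid_resolution: int = 129) -> ToothSpec:
    """Draw a molar-like spec: 3-5 cusps on a ring, star fissure skeleton."""
    k = int(rng.integers(3, 6))
    base_angle = rng.uniform(0, 2 * np.pi)
    ring = rng.uniform(1.9, 2.4)
    centers = []
    for m in range(k):
        a = base_angle + 2 * np.pi * m / k + rng.normal(0, 0.08)
        r = ring * rng.uniform(0.9, 1.1)
        centers.append((r * np.cos(a), r * np.sin(a)))
    heights = tuple(float(rng.uniform(1.2, 2.0)) for _ in range(k))
    widths = tuple(float(rng.uniform(0.9, 1.3)) for _ in range(k))
    return ToothSpec(
        cusp_centers=tuple(centers),
        cusp_heights=heights,
        cusp_widths=widths,
        skeleton=_default_skeleton(centers),
        groove_depth=float(rng.uniform(0.6, 1.0)),
        groove_width=float(rng.uniform(0.7, 1.1)),
        dome_height=float(rng.uniform(1.6, 2.2)),
        dome_width=float(rng.uniform(2.8, 3.6)),
        grid_resolution=grid_resolution,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n_samples: int,
    seed: int,
    outdir: str | os.PathLike,
    config: ProjectionConfig = ProjectionConfig(),
    clearance: float = 0.5,
    train_fraction: float = 0.75,
    grid_resolution: int = 129,
) -> list[dict]:
    """Write ``n_samples`` randomized triplets to ``outdir`` and a JSONL manifest.

    The first ``round(train_fraction * n)`` samples are labelled train, the
    rest test (75/25 by default, i.e. 300/100 at n=400).  Fully deterministic
    for a fixed seed: identical manifests and identical image bytes.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    outdir = os.fspath(outdir)
    try:
        os.makedirs(outdir, exist_ok=True)
        probe = os.path.join(outdir, ".write_probe")
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as exc:
        raise IOError(f"output directory not writable: {outdir}: {exc}") from exc

    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n_samples))
    manifest: list[dict] = []
    for i in range(n_samples):
        spec = random_tooth_spec(rng, grid_resolution=grid_resolution)
        mesh = generate_tooth_mesh(spec)
        opposing = generate_opposing_mesh(mesh, clearance=clearance)
        triplet = build_triplet(
            mesh, opposing, spec.skeleton, config, groove_width=spec.groove_width
        )
        sid = f"sample_{i:04d}"
        paths = {}
        for tag, img in (("x", triplet.x), ("op", triplet.op), ("y", triplet.y)):
            p = os.path.join(outdir, f"{sid}_{tag}.png")
            img.save(p)
            paths[f"{tag}_path"] = p
        entry = {
            "id": sid,
            "role": "train" if i < n_train else "test",
            **paths,
            "seed": spec.seed,
        }
        manifest.append(entry)

    with open(os.path.join(outdir, "manifest.jsonl"), "w") as fh:
        for entry in manifest:
            fh.write(json.dumps(entry) + "\n")
    return manifest


def load_manifest(path: str | os.PathLike) -> list[dict]:
    path = os.fspath(path)
    if os.path.isdir(path):
        path = os.path.join(path, "manifest.jsonl")
    if not os.path.exists(path):
        raise IOError(f"manifest not found: {path}")
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def random_patch_mesh(
    n_vertices: int, seed: int, z_scale: float = 0.3
) -> trimesh.Trimesh:
    """Small random triangulated surface patch (Delaunay of random XY points).

    Used as a compact, always-valid test substrate for the path search.
    """
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(seed)
    while True:
        xy = rng.uniform(-1, 1, size=(n_vertices, 2))
        try:
            tri = Delaunay(xy)
        except Exception:
            continue
        if len(tri.simplices) >= 1:
            break
    z = rng.uniform(0, z_scale, size=n_vertices)
    v = np.column_stack([xy, z])
    return trimesh.Trimesh(vertices=v, faces=tri.simplices, process=False)
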