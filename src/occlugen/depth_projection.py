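"""Depth-map projection of crown meshes and its inverse.

A crown mesh (occlusal surface facing +Z) is orthographically projected onto
a square pixel grid placed a clearance ``gamma`` above the model's top.  The
vertical distance d from the projection plane to the surface is encoded as an
8-bit pixel value

    Pixel = round(255 - 255 * (d / h)**n)

where h is the limit-plane distance (surface points farther than h map to 0)
and n is an image-enhancement exponent redistributing grey levels.  n is
chosen by maximizing the Shannon entropy of the projected images; entropy
peaks at an intermediate exponent because very small or very large n crushes
the histogram toward one end of the grey range.

The mapping is invertible up to quantization: d = h * (1 - p/255)**(1/n),
which back-projects a depth image into a 3-D point cloud.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import trimesh
from PIL import Image

from ._raster import rasterize_max_z
from .mesh_core import MeshValidationError, bounding_box

__all__ = [
    "ProjectionConfig",
    "DepthImage",
    "pixel_from_distance",
    "distance_from_pixel",
    "distance_grid",
    "project_mesh",
    "backproject",
    "image_entropy",
    "select_enhancement",
]


def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class ProjectionConfig:
    """Geometry and encoding parameters of the orthographic depth projection.

    resolution : pixels per image side.
    h          : limit-plane distance from the projection plane (mm); surface
                 points farther than h encode as pixel 0.
    n          : enhancement exponent of the depth-to-pixel mapping.
    gamma      : clearance between the model's top and the projection plane (mm).
    margin     : fractional bounding-box margin when the grid is derived.
    origin, spacing, plane_z : explicit grid (mm); derived from the mesh
                 bounding box when left as None.
    pre_transform : optional 4x4 rigid transform applied before projection
                 (replaces interactive posture adjustment).
    """

    resolution: int = 256
    h: float = 6.5
    n: float = 1.4
    gamma: float = 1.0
    margin: float = 0.05
    origin: tuple[float, float] | None = None  # (x0, y0): min-x / max-y corner
    spacing: float | None = None  # mm per pixel
    plane_z: float | None = None
    pre_transform: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")
        if self.h <= 0 or self.n <= 0:
            raise ValueError("h and n must be positive")
        if self.spacing is not None and self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass(frozen=True)
class ProjectionMeta:
    """Resolved grid of a projected image; sufficient to invert the projection."""

    origin: tuple[float, float]
    spacing: float
    plane_z: float
    h: float
    n: float
    gamma: float

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing": self.spacing,
            "plane_z": self.plane_z,
            "h": self.h,
            "n": self.n,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionMeta":
        return cls(
            origin=(float(d["origin"][0]), float(d["origin"][1])),
            spacing=float(d["spacing"]),
            plane_z=float(d["plane_z"]),
            h=float(d["h"]),
            n=float(d["n"]),
            gamma=float(d["gamma"]),
        )


@dataclass
class DepthImage:
    """8-bit single-channel depth image plus the grid metadata to invert it."""

    pixels: np.ndarray  # (res, res) uint8
    meta: ProjectionMeta

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values outside [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def resolution(self) -> int:
        return self.pixels.shape[0]

    def save(self, path: str | os.PathLike) -> None:
        """Write PNG plus a JSON metadata sidecar (<path>.json)."""
        path = os.fspath(path)
        Image.fromarray(self.pixels, mode="L").save(path)
        with open(path + ".json", "w") as fh:
            json.dump(self.meta.to_dict(), fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DepthImage":
        path = os.fspath(path)
        pixels = np.asarray(Image.open(path).convert("L"))
        sidecar = path + ".json"
        if not os.path.exists(sidecar):
            raise MeshValidationError(f"missing projection metadata sidecar: {sidecar}")
        with open(sidecar) as fh:
            meta = ProjectionMeta.from_dict(json.load(fh))
        return cls(pixels=pixels, meta=meta)


def pixel_from_distance(d: np.ndarray | float, h: float = 6.5, n: float = 1.4):
    """Encode plane-to-surface distance (mm) as an 8-bit pixel value.

    ``round(255 - 255 * (d/h)**n)`` clamped to [0, 255]; distances beyond the
    limit plane (d > h) encode as 0.
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be non-negative")
    with np.errstate(over="ignore"):
        p = _round_half_up(255.0 - 255.0 * (d / h) ** n)
    p = np.where(d > h, 0.0, np.clip(p, 0.0, 255.0))
    return p.astype(np.int64) if p.ndim else int(p)


def distance_from_pixel(p: np.ndarray | float, h: float = 6.5, n: float = 1.4):
    """Invert the unrounded pixel encoding: ``d = h * (1 - p/255)**(1/n)`` (mm)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 255).any():
        raise ValueError("pixel value outside [0, 255]")
    d = h * (1.0 - p / 255.0) ** (1.0 / n)
    return d if d.ndim else float(d)


def _resolve_grid(mesh: trimesh.Trimesh, config: ProjectionConfig):
    lo, hi = bounding_box(mesh)
    if config.spacing is not None:
        spacing = config.spacing
    else:
        extent = max(hi[0] - lo[0], hi[1] - lo[1])
        spacing = extent * (1.0 + 2.0 * config.margin) / config.resolution
        if spacing <= 0:
            raise MeshValidationError("degenerate XY footprint")
    if config.origin is not None:
        x0, y0 = config.origin
    else:
        cx = 0.5 * (lo[0] + hi[0])
        cy = 0.5 * (lo[1] + hi[1])
        half = spacing * config.resolution / 2.0
        x0, y0 = cx - half, cy + half
    plane_z = config.plane_z if config.plane_z is not None else float(hi[2]) + config.gamma
    return (float(x0), float(y0)), float(spacing), float(plane_z)


def distance_grid(mesh: trimesh.Trimesh, config: ProjectionConfig = ProjectionConfig()):
    """Per-pixel plane-to-surface distance and hit mask (before encoding).

    Returns (d, hit, meta): d is NaN where no surface is hit.
    """
    if len(mesh.faces) == 0:
        raise MeshValidationError("cannot project an empty mesh")
    if config.pre_transform is not None:
        mesh = mesh.copy()
        mesh.apply_transform(np.asarray(config.pre_transform, dtype=float))
    (x0, y0), spacing, plane_z = _resolve_grid(mesh, config)
    zbuf = rasterize_max_z(
        mesh.vertices, mesh.faces, x0, y0, spacing, config.resolution
    )
    hit = np.isfinite(zbuf)
    d = np.where(hit, plane_z - zbuf, np.nan)
    # a surface poking through the projection plane would give negative d
    d = np.where(hit & (d < 0), 0.0, d)
    meta = ProjectionMeta(
        origin=(x0, y0), spacing=spacing, plane_z=plane_z,
        h=config.h, n=config.n, gamma=config.gamma,
    )
    return d, hit, meta


def project_mesh(mesh: trimesh.Trimesh, config: ProjectionConfig = ProjectionConfig()) -> DepthImage:
    """Orthographic depth image of a mesh (occlusal side facing +Z).

    One -Z ray per pixel center; the intersection nearest the projection
    plane wins.  Pixels with no intersection, or whose surface lies beyond
    the limit plane, are 0.
    """
    d, hit, meta = distance_grid(mesh, config)
    pixels = np.zeros((config.resolution, config.resolution), dtype=np.uint8)
    if hit.any():
        pixels[hit] = pixel_from_distance(d[hit], config.h, config.n).astype(np.uint8)
    return DepthImage(pixels=pixels, meta=meta)


def backproject(img: DepthImage) -> np.ndarray:
    """Convert a depth image back into a point cloud (one point per nonzero pixel).

    Pixel (i, j) with value p maps to x = x0 + (j+0.5)*s, y = y0 - (i+0.5)*s,
    z = plane_z - distance_from_pixel(p).  Zero pixels (background / beyond
    the limit plane) emit no point.
    """
    meta = img.meta
    if meta is None:
        raise MeshValidationError("depth image has no projection metadata")
    ii, jj = np.nonzero(img.pixels)
    if len(ii) == 0:
        return np.empty((0, 3), dtype=float)
    p = img.pixels[ii, jj].astype(float)
    x = meta.origin[0] + (jj + 0.5) * meta.spacing
    y = meta.origin[1] - (ii + 0.5) * meta.spacing
    z = meta.plane_z - distance_from_pixel(p, meta.h, meta.n)
    return np.column_stack([x, y, z])


def image_entropy(img: DepthImage | np.ndarray) -> float:
    """Shannon entropy (bits) of the 8-bit grey-level histogram; in [0, 8]."""
    pixels = img.pixels if isinstance(img, DepthImage) else np.asarray(img)
    if pixels.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(pixels.astype(np.uint8).ravel(), minlength=256)
    p = counts[counts > 0] / pixels.size
    return float(-(p * np.log2(p)).sum()) + 0.0  # avoid -0.0 for constant images


def select_enhancement(
    meshes: list[trimesh.Trimesh],
    candidate_ns: np.ndarray,
    config: ProjectionConfig = ProjectionConfig(),
) -> tuple[float, list[tuple[float, float]]]:
    """Pick the enhancement exponent maximizing mean image entropy.

    Projects every mesh at every candidate n, averages the entropy across
    meshes, and returns (best n, [(n, mean entropy), ...]).  Ties break to
    the smallest n.  The projection geometry does not depend on n, so the
    distance grid is computed once per mesh.
    """
    if not meshes:
        raise ValueError("need at least one mesh")
    ns = np.asarray(list(candidate_ns), dtype=float)
    if ns.size == 0 or (ns <= 0).any():
        raise ValueError("candidate n grid must be non-empty and positive")
    order = np.argsort(ns, kind="stable")
    ns = ns[order]

    grids = [distance_grid(m, config) for m in meshes]
    curve: list[tuple[float, float]] = []
    for n in ns:
        es = []
        for d, hit, _ in grids:
            pixels = np.zeros_like(hit, dtype=np.uint8)
            if hit.any():
                pixels[hit] = pixel_from_distance(d[hit], config.h, n).astype(np.uint8)
            es.append(image_entropy(pixels))
        curve.append((float(n), float(np.mean(es))))
    best = max(range(len(curve)), key=lambda i: (curve[i][1], -curve[i][0]))
    return curve[best][0], curve
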