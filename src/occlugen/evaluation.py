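"""Image-quality metrics and 3-D surface-deviation statistics.

PSNR and SSIM are computed in the exact dialect the method reports: SSIM uses
global image statistics (one value per pair, no sliding window) with
stabilization constants C1 = 6.5 and C2 = 58.5 on the 0-255 scale, and PSNR
uses MAX = 255 with an infinity sentinel for identical images.  Surface
deviation reports the standard deviation and the root-mean-square of
unsigned nearest-surface distances from a point cloud to a reference mesh.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass

import numpy as np
import trimesh
from PIL import Image

__all__ = [
    "SsimParams",
    "MetricsReport",
    "DeviationReport",
    "mse",
    "psnr",
    "ssim",
    "surface_deviation",
    "evaluate_pair",
    "evaluate_batch",
]


@dataclass(frozen=True)
class SsimParams:
    """Stabilization constants of the structural-similarity index (0-255 scale)."""

    c1: float = 6.5
    c2: float = 58.5

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("SSIM constants must be positive")


@dataclass
class MetricsReport:
    mse: float
    psnr_db: float  # math.inf for identical images
    ssim: float


@dataclass
class DeviationReport:
    """Signed point-to-surface deviations (mm) and their summary statistics.

    The sign records which side of the reference surface a point lies on
    (along the nearest face normal); SD is the standard deviation of the
    signed deviations, RMSE their root mean square.  For an unbiased
    deviation field the two statistics agree; a constant offset shows up in
    the RMSE but not the SD.
    """

    distances: np.ndarray
    std: float
    rmse: float


def _as_images(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"image dimensions differ: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty image")
    return x, y


def mse(x, y) -> float:
    """Mean squared pixel difference, (1/mn) * sum (X - Y)^2."""
    x, y = _as_images(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x, y, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio 10*log10(MAX^2 / MSE) in dB; inf at MSE=0."""
    err = mse(x, y)
    if err == 0.0:
        return math.inf
    return float(10.0 * np.log10(max_value**2 / err))


def ssim(x, y, params: SsimParams = SsimParams()) -> float:
    """Structural similarity from global means, variances and covariance.

    (2 mu_x mu_y + C1)(2 sigma_xy + C2) /
    ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))
    """
    x, y = _as_images(x, y)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(
        (2 * mx * my + params.c1)
        * (2 * cov + params.c2)
        / ((mx**2 + my**2 + params.c1) * (vx + vy + params.c2))
    )


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point to p[i] on triangle tri[i] (n,3),(n,3,3)->(n,3).

    Vectorized barycentric region walk (the standard closest-point-on-triangle
    construction).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
    v = vb / denom
    w = vc / denom
    out = a + v[:, None] * ab + w[:, None] * ac  # interior case

    # edge/vertex regions overwrite the interior guess
    t_ab = np.clip(d1 / np.where(d1 - d3 == 0, 1e-300, d1 - d3), 0, 1)
    on_ab = a + t_ab[:, None] * ab
    t_ac = np.clip(d2 / np.where(d2 - d6 == 0, 1e-300, d2 - d6), 0, 1)
    on_ac = a + t_ac[:, None] * ac
    t_bc = np.clip(
        (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1e-300, (d4 - d3) + (d5 - d6)), 0, 1
    )
    on_bc = b + t_bc[:, None] * (c - b)

    out = np.where((vc <= 0)[:, None] & (d1 >= 0)[:, None] & (d3 <= 0)[:, None], on_ab, out)
    out = np.where((vb <= 0)[:, None] & (d2 >= 0)[:, None] & (d6 <= 0)[:, None], on_ac, out)
    out = np.where(
        (va <= 0)[:, None] & ((d4 - d3) >= 0)[:, None] & ((d5 - d6) >= 0)[:, None], on_bc, out
    )
    out = np.where((d1 <= 0)[:, None] & (d2 <= 0)[:, None], a, out)
    out = np.where((d3 >= 0)[:, None] & (d4 <= d3)[:, None], b, out)
    out = np.where((d6 >= 0)[:, None] & (d5 <= d6)[:, None], c, out)
    return out


def _nearest_on_mesh(pts: np.ndarray, mesh: trimesh.Trimesh, k: int = 32):
    """Nearest surface point and owning face for each query point.

    Broad phase: KD-tree over triangle centroids (k candidates per query,
    k grown until the best exact distance is certified against the centroid
    lower bound); narrow phase: exact point-triangle distance.
    """
    from scipy.spatial import cKDTree

    triangles = mesh.triangles
    centroids = triangles.mean(axis=1)
    # max distance from a centroid to its own triangle's vertices
    reach = np.linalg.norm(triangles - centroids[:, None, :], axis=2).max()
    tree = cKDTree(centroids)
    nf = len(triangles)
    k = min(k, nf)
    while True:
        cd, ci = tree.query(pts, k=k)
        cd = np.atleast_2d(cd.T).T
        ci = np.atleast_2d(ci.T).T
        best_pts = np.empty_like(pts)
        best_d = np.full(len(pts), np.inf)
        best_f = np.zeros(len(pts), dtype=int)
        for j in range(ci.shape[1]):
            cand = _closest_on_triangles(pts, triangles[ci[:, j]])
            d = np.linalg.norm(pts - cand, axis=1)
            better = d < best_d
            best_d[better] = d[better]
            best_pts[better] = cand[better]
            best_f[better] = ci[better, j]
        # certified when no unexamined centroid could beat the best distance
        if k == nf or (best_d <= cd[:, -1] - reach).all():
            return best_pts, best_d, best_f
        k = min(nf, 2 * k)


def surface_deviation(cloud: np.ndarray, reference: trimesh.Trimesh) -> DeviationReport:
    """Nearest-surface deviation statistics of a point cloud against a mesh.

    Each point contributes its distance to the nearest surface point, signed
    by the side of the surface it lies on (dot product with the nearest
    face's normal).  Reports the standard deviation and the root-mean-square
    of the signed deviations, in mm.
    """
    pts = np.asarray(cloud, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("empty point cloud")
    if len(reference.faces) == 0:
        raise ValueError("empty reference mesh")
    closest, dist, tri_id = _nearest_on_mesh(pts, reference)
    normals = reference.face_normals[tri_id]
    side = np.sign(((pts - closest) * normals).sum(axis=1))
    side[side == 0] = 1.0
    dist = np.abs(dist) * side
    return DeviationReport(
        distances=dist,
        std=float(dist.std()),
        rmse=float(np.sqrt(np.mean(dist**2))),
    )


def _load_gray(path) -> np.ndarray:
    return np.asarray(Image.open(os.fspath(path)).convert("L"), dtype=float)


def evaluate_pair(generated, target, params: SsimParams = SsimParams()) -> MetricsReport:
    """MSE / PSNR / SSIM for one generated-vs-target pair.

    Accepts arrays or PNG paths; 8-bit single channel, same size.
    """
    g = _load_gray(generated) if isinstance(generated, (str, os.PathLike)) else np.asarray(generated, float)
    t = _load_gray(target) if isinstance(target, (str, os.PathLike)) else np.asarray(target, float)
    if g.shape != t.shape:
        raise ValueError(f"generated/target size mismatch: {g.shape} vs {t.shape}")
    return MetricsReport(mse=mse(g, t), psnr_db=psnr(g, t), ssim=ssim(g, t, params))


def evaluate_batch(pairs, csv_path=None, params: SsimParams = SsimParams()) -> list[dict]:
    """Evaluate [(id, generated, target), ...]; optionally write CSV rows.

    CSV columns: id, mse, psnr_db, ssim (infinite PSNR serialized as "inf").
    """
    rows = []
    for pair_id, g, t in pairs:
        r = evaluate_pair(g, t, params)
        rows.append({"id": pair_id, "mse": r.mse, "psnr_db": r.psnr_db, "ssim": r.ssim})
    if csv_path is not None:
        with open(os.fspath(csv_path), "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["id", "mse", "psnr_db", "ssim"])
            w.writeheader()
            for row in rows:
                out = dict(row)
                if math.isinf(out["psnr_db"]):
                    out["psnr_db"] = "inf"
                w.writerow(out)
    return rows
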