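"""Orthographic z-max rasterization of a triangle soup onto a pixel grid.

For every pixel center a -Z ray is cast; the kept depth is the surface point
nearest the projection plane, i.e. the maximum z among covering triangles.
The inner loop is numba-jitted when numba is importable; a pure-python
fallback with identical semantics is used otherwise.
"""

from __future__ import annotations

import numpy as np


def _raster_kernel(v0, v1, v2, x0, y0, spacing, zbuf):
    """Accumulate max-z of each triangle into zbuf.

    Pixel (i, j) center sits at x = x0 + (j+0.5)*spacing,
    y = y0 - (i+0.5)*spacing (top-left raster convention).
    """
    res = zbuf.shape[0]
    n = v0.shape[0]
    for t in range(n):
        ax, ay, az = v0[t, 0], v0[t, 1], v0[t, 2]
        bx, by, bz = v1[t, 0], v1[t, 1], v1[t, 2]
        cx, cy, cz = v2[t, 0], v2[t, 1], v2[t, 2]
        # signed double area in the XY plane
        d = (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)
        if d == 0.0:
            continue
        xmin = min(ax, bx, cx)
        xmax = max(ax, bx, cx)
        ymin = min(ay, by, cy)
        ymax = max(ay, by, cy)
        j0 = int(np.floor((xmin - x0) / spacing - 0.5))
        j1 = int(np.ceil((xmax - x0) / spacing - 0.5))
        i0 = int(np.floor((y0 - ymax) / spacing - 0.5))
        i1 = int(np.ceil((y0 - ymin) / spacing - 0.5))
        if j0 < 0:
            j0 = 0
        if i0 < 0:
            i0 = 0
        if j1 > res - 1:
            j1 = res - 1
        if i1 > res - 1:
            i1 = res - 1
        for i in range(i0, i1 + 1):
            py = y0 - (i + 0.5) * spacing
            for j in range(j0, j1 + 1):
                px = x0 + (j + 0.5) * spacing
                w0 = ((bx - px) * (cy - py) - (cx - px) * (by - py)) / d
                w1 = ((cx - px) * (ay - py) - (ax - px) * (cy - py)) / d
                w2 = 1.0 - w0 - w1
                if w0 < -1e-12 or w1 < -1e-12 or w2 < -1e-12:
                    continue
                z = w0 * az + w1 * bz + w2 * cz
                if z > zbuf[i, j]:
                    zbuf[i, j] = z


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _raster_kernel = njit(cache=True)(_raster_kernel)
except ImportError:  # pragma: no cover
    pass


def rasterize_max_z(
    vertices: np.ndarray,
    faces: np.ndarray,
    x0: float,
    y0: float,
    spacing: float,
    resolution: int,
) -> np.ndarray:
    """Return a (resolution, resolution) z-buffer; -inf where no triangle covers."""
    v = np.ascontiguousarray(vertices, dtype=np.float64)
    f = np.asarray(faces, dtype=np.int64)
    zbuf = np.full((resolution, resolution), -np.inf, dtype=np.float64)
    if len(f):
        _raster_kernel(
            v[f[:, 0]], v[f[:, 1]], v[f[:, 2]], float(x0), float(y0), float(spacing), zbuf
        )
    return zbuf
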