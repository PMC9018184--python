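"""Orthographic z-buffer rasterization of triangle meshes.

Projects a mesh along -z onto a regular pixel grid, keeping the highest
surface z under each pixel centre (the occlusal view of a height field is
single-valued, so the z-max rule is exact for the meshes this package
produces and a sane convention for any other watertight-on-top surface).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _raster_zmax(vertices, faces, x0, y0, mm_per_pixel, height, width):
    """Fill a (height, width) z-buffer with the max surface z per pixel.

    Pixel (row i, col j) has centre (x0 + j*mmpp, y0 + i*mmpp). Background
    stays at -inf.
    """
    zbuf = np.full((height, width), -np.inf)
    for f in range(faces.shape[0]):
        i0, i1, i2 = faces[f, 0], faces[f, 1], faces[f, 2]
        ax, ay, az = vertices[i0, 0], vertices[i0, 1], vertices[i0, 2]
        bx, by, bz = vertices[i1, 0], vertices[i1, 1], vertices[i1, 2]
        cx, cy, cz = vertices[i2, 0], vertices[i2, 1], vertices[i2, 2]
        # pixel bounding box of the triangle
        xmin = min(ax, min(bx, cx))
        xmax = max(ax, max(bx, cx))
        ymin = min(ay, min(by, cy))
        ymax = max(ay, max(by, cy))
        j_lo = int(np.ceil((xmin - x0) / mm_per_pixel - 1e-12))
        j_hi = int(np.floor((xmax - x0) / mm_per_pixel + 1e-12))
        i_lo = int(np.ceil((ymin - y0) / mm_per_pixel - 1e-12))
        i_hi = int(np.floor((ymax - y0) / mm_per_pixel + 1e-12))
        if j_hi < 0 or i_hi < 0 or j_lo >= width or i_lo >= height:
            continue
        j_lo = max(j_lo, 0)
        i_lo = max(i_lo, 0)
        j_hi = min(j_hi, width - 1)
        i_hi = min(i_hi, height - 1)
        # barycentric setup
        d00x, d00y = bx - ax, by - ay
        d01x, d01y = cx - ax, cy - ay
        denom = d00x * d01y - d01x * d00y
        if abs(denom) < 1e-15:
            continue
        inv = 1.0 / denom
        for i in range(i_lo, i_hi + 1):
            py = y0 + i * mm_per_pixel
            for j in range(j_lo, j_hi + 1):
                px = x0 + j * mm_per_pixel
                wx, wy = px - ax, py - ay
                u = (wx * d01y - d01x * wy) * inv
                v = (d00x * wy - wx * d00y) * inv
                if u < -1e-12 or v < -1e-12 or u + v > 1.0 + 1e-12:
                    continue
                z = az + u * (bz - az) + v * (cz - az)
                if z > zbuf[i, j]:
                    zbuf[i, j] = z
    return zbuf


def rasterize_height(vertices: np.ndarray, faces: np.ndarray,
                     x0: float, y0: float, mm_per_pixel: float,
                     height: int, width: int) -> np.ndarray:
    """Vector-friendly wrapper; returns z-buffer with -inf background."""
    return _raster_zmax(
        np.ascontiguousarray(vertices, dtype=np.float64),
        np.ascontiguousarray(faces, dtype=np.int64),
        float(x0), float(y0), float(mm_per_pixel), int(height), int(width),
    )
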