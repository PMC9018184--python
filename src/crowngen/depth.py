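"""Pose standardization and the reversible depth-map encoding.

A standardized tooth model (occlusal direction along +z, mesiodistal along
+x, bounding-box centre at the origin) is orthographically projected along
-z onto a pixel grid. Per-pixel distance d (mm) from the reference plane is
mapped to an 8-bit level by

    pixel = round(255 * (h^alpha - d^alpha) / h^alpha),   0 <= d <= h

with visual distance h (default 6 mm) and enhancement factor alpha; surface
farther than h from the plane, and empty background, encode as 0. The
mapping is invertible up to quantization, so a depth map plus its encoding
parameters reconstructs the 3D surface. alpha is chosen by maximizing the
Shannon entropy of the rendered image.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .mesh import GeometryError, ToothMesh
from .raster import rasterize_height

__all__ = [
    "DepthEncoding",
    "DepthMap",
    "depth_to_pixel",
    "pixel_to_depth",
    "quantization_bound",
    "standardize_pose",
    "project_mesh",
    "image_entropy",
    "select_alpha",
    "reconstruct_mesh",
]


@dataclasses.dataclass
class DepthEncoding:
    """Parameters of the pixel-distance mapping and the projection grid.

    alpha : enhancement-factor exponent (> 0).
    h : visual distance in mm; surface beyond h is not projected.
    mm_per_pixel : grid resolution.
    width, height : image size in pixels.
    reference_z : z of the projection plane (mm); resolved to the mesh
        z-maximum at projection time when None.
    origin_x, origin_y : world coordinates of pixel (row 0, col 0) centre;
        resolved to centre the mesh in frame when None.
    """

    alpha: float = 2.0
    h: float = 6.0
    mm_per_pixel: float = 0.1
    width: int = 128
    height: int = 128
    reference_z: float | None = None
    origin_x: float | None = None
    origin_y: float | None = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if not self.h > 0:
            raise ValueError("h must be > 0")
        if not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be > 0")

    def resolved(self) -> "DepthEncoding":
        if self.reference_z is None or self.origin_x is None or self.origin_y is None:
            raise ValueError("encoding has unresolved reference plane / origin")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DepthEncoding":
        return cls(**d)


@dataclasses.dataclass
class DepthMap:
    """An 8-bit depth image plus the encoding that produced it."""

    pixels: np.ndarray
    encoding: DepthEncoding

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def foreground(self) -> np.ndarray:
        return self.pixels > 0

    def save(self, png_path: str | Path) -> None:
        """Write the PNG plus a JSON sidecar carrying the encoding."""
        png_path = Path(png_path)
        iio.imwrite(png_path, self.pixels)
        sidecar = png_path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.encoding.to_dict(), indent=1))

    @classmethod
    def load(cls, png_path: str | Path) -> "DepthMap":
        png_path = Path(png_path)
        pixels = iio.imread(png_path)
        enc = DepthEncoding.from_dict(
            json.loads(png_path.with_suffix(".json").read_text())
        )
        return cls(pixels, enc)


# ---------------------------------------------------------------------------
# pixel <-> distance mapping


def depth_to_pixel(d, enc: DepthEncoding):
    """Map distance-from-plane d (mm) to an 8-bit level.

    Monotone non-increasing in d; d > h maps to 0. Rounding is
    half-away-from-zero. Accepts scalars or arrays.
    """
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    frac = (enc.h**enc.alpha - d**enc.alpha) / enc.h**enc.alpha
    level = np.floor(255.0 * frac + 0.5)  # half-away-from-zero for x >= 0
    level = np.where(d > enc.h, 0.0, np.clip(level, 0, 255))
    out = level.astype(np.uint8)
    return out if out.ndim else int(out)


def pixel_to_depth(p, enc: DepthEncoding):
    """Inverse of the un-rounded mapping: d = h * (1 - p/255)^(1/alpha)."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or np.any(p > 255):
        raise ValueError("pixel levels must lie in [0, 255]")
    out = enc.h * (1.0 - p / 255.0) ** (1.0 / enc.alpha)
    return out if out.ndim else float(out)


def quantization_bound(enc: DepthEncoding) -> float:
    """Largest depth difference between adjacent 8-bit levels.

    Brute force over all 256 levels; the encode->decode round trip error is
    bounded by this step everywhere in [0, h].
    """
    depths = pixel_to_depth(np.arange(256), enc)
    return float(np.max(np.abs(np.diff(depths))))


# ---------------------------------------------------------------------------
# pose standardization


def _principal_axes(vertices: np.ndarray) -> np.ndarray:
    """Columns = principal directions, sorted by descending variance."""
    c = vertices - vertices.mean(axis=0)
    cov = c.T @ c / len(c)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    return evecs[:, order]


def _render_entropy(vertices, faces, size=32, h=6.0) -> float:
    """Entropy of a coarse occlusal render; used only for sign disambiguation."""
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    span = max(hi[0] - lo[0], hi[1] - lo[1])
    if span <= 0:
        return 0.0
    mmpp = span / (size - 1)
    zbuf = rasterize_height(vertices, faces, lo[0], lo[1], mmpp, size, size)
    d = hi[2] - zbuf
    img = np.zeros((size, size), dtype=np.uint8)
    fg = np.isfinite(zbuf) & (d <= h)
    frac = (h**2 - d[fg] ** 2) / h**2
    img[fg] = np.floor(255.0 * frac + 0.5).astype(np.uint8)
    return image_entropy(img)


def standardize_pose(mesh: ToothMesh) -> ToothMesh:
    """Rotate/translate a tooth mesh into the canonical occlusal frame.

    Principal axes align with the coordinate axes (largest spread, the
    mesiodistal direction, along x; smallest along z), the bounding-box
    centre moves to the origin, and the occlusal side is made to face +z by
    choosing the z-orientation whose occlusal render has the higher image
    entropy (the detailed, cusped side carries more information than the
    smooth underside). Rigid transform only.
    """
    v = mesh.vertices
    if len(v) < 3:
        raise GeometryError("mesh needs at least 3 vertices")
    centered = v - v.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise GeometryError("mesh vertices are collinear; pose is undefined")

    axes = _principal_axes(v)
    e1, e3 = axes[:, 0], axes[:, 2]
    # x sign pinned by the third moment of the mesiodistal projection
    if np.sum((centered @ e1) ** 3) < 0:
        e1 = -e1
    # z sign: the occlusal (detailed) side faces +z — pick the orientation
    # whose occlusal render has the higher entropy; y completes the
    # right-handed frame
    cand = []
    for ez in (e3, -e3):
        basis = np.column_stack([e1, np.cross(ez, e1), ez])
        rot = centered @ basis
        cand.append((_render_entropy(rot, mesh.faces), rot))
    rot = cand[0][1] if cand[0][0] >= cand[1][0] else cand[1][1]

    bounds = np.stack([rot.min(axis=0), rot.max(axis=0)])
    rot = rot - bounds.mean(axis=0)
    return ToothMesh(rot, mesh.faces.copy(), pose_standardized=True)


# ---------------------------------------------------------------------------
# projection / entropy / alpha selection


def project_mesh(mesh: ToothMesh, enc: DepthEncoding, return_zbuffer: bool = False):
    """Orthographic -z projection of a standardized mesh to a depth map.

    Per pixel, d = reference_z minus the highest surface z under the pixel
    centre; reference_z defaults to the mesh z-maximum (the highest cusp has
    d = 0). Pixels with no surface, or with d > h, are 0. With
    ``return_zbuffer`` the raw per-pixel surface height (mm, -inf background)
    is returned alongside the quantized map.
    """
    if not mesh.pose_standardized:
        raise GeometryError("project_mesh requires a pose-standardized mesh")
    ref_z = enc.reference_z
    if ref_z is None:
        ref_z = float(mesh.vertices[:, 2].max())
    if enc.origin_x is None or enc.origin_y is None:
        lo = mesh.vertices.min(axis=0)
        hi = mesh.vertices.max(axis=0)
        cx, cy = (lo[0] + hi[0]) / 2, (lo[1] + hi[1]) / 2
        ox = cx - (enc.width - 1) / 2 * enc.mm_per_pixel
        oy = cy - (enc.height - 1) / 2 * enc.mm_per_pixel
    else:
        ox, oy = enc.origin_x, enc.origin_y

    zbuf = rasterize_height(
        mesh.vertices, mesh.faces, ox, oy, enc.mm_per_pixel, enc.height, enc.width
    )
    hit = np.isfinite(zbuf)
    if not hit.any():
        raise GeometryError("empty projection: mesh lies outside the frame")
    d = np.where(hit, ref_z - zbuf, np.inf)
    d = np.clip(d, 0.0, None)  # surface above the plane clamps to d = 0
    pixels = np.zeros((enc.height, enc.width), dtype=np.uint8)
    inside = hit & (d <= enc.h)
    if inside.any():
        frac = (enc.h**enc.alpha - d[inside] ** enc.alpha) / enc.h**enc.alpha
        pixels[inside] = np.floor(255.0 * frac + 0.5).astype(np.uint8)
    out_enc = dataclasses.replace(
        enc, reference_z=ref_z, origin_x=float(ox), origin_y=float(oy)
    )
    dm = DepthMap(pixels, out_enc)
    if return_zbuffer:
        return dm, zbuf
    return dm


def image_entropy(dm) -> float:
    """Shannon entropy (bits) of the 8-bit level histogram, 0*log 0 := 0."""
    pixels = dm.pixels if isinstance(dm, DepthMap) else np.asarray(dm)
    if pixels.size == 0:
        raise ValueError("entropy of an empty image is undefined")
    counts = np.bincount(pixels.ravel().astype(np.int64), minlength=256)
    p = counts[counts > 0] / pixels.size
    return float(-(p * np.log2(p)).sum())


def select_alpha(mesh: ToothMesh, candidates, enc: DepthEncoding | None = None) -> float:
    """Return the candidate alpha maximizing rendered image entropy.

    Ties break toward the smallest alpha.
    """
    cands = sorted(float(a) for a in candidates)
    if not cands:
        raise ValueError("need at least one candidate alpha")
    template = enc if enc is not None else DepthEncoding()
    best_a, best_h = None, -np.inf
    for a in cands:
        e = dataclasses.replace(template, alpha=a)
        ent = image_entropy(project_mesh(mesh, e))
        if ent > best_h + 1e-12:
            best_a, best_h = a, ent
    return best_a


# ---------------------------------------------------------------------------
# inverse: depth map -> mesh


def reconstruct_mesh(dm: DepthMap, discontinuity_mm: float = 0.5) -> ToothMesh:
    """Back-project a depth map into a triangulated surface.

    Every foreground pixel becomes a vertex at
    (x, y, reference_z - pixel_to_depth(p)). Triangulation grows over the
    pixel grid: each 2x2 cell whose four pixels are all foreground and whose
    in-cell depth discontinuity stays below ``discontinuity_mm`` contributes
    two triangles, so background holes and cliffs are never bridged.
    """
    enc = dm.encoding.resolved()
    fg = dm.foreground
    n_fg = int(fg.sum())
    if n_fg < 3:
        raise GeometryError("need at least 3 foreground pixels")

    depth = pixel_to_depth(dm.pixels.astype(np.float64), enc)
    z = enc.reference_z - depth
    rows, cols = np.nonzero(fg)
    index = -np.ones(fg.shape, dtype=np.int64)
    index[rows, cols] = np.arange(n_fg)
    verts = np.column_stack(
        [
            enc.origin_x + cols * enc.mm_per_pixel,
            enc.origin_y + rows * enc.mm_per_pixel,
            z[rows, cols],
        ]
    )

    # 2x2 cells: top-left corner (i, j)
    cell_ok = fg[:-1, :-1] & fg[:-1, 1:] & fg[1:, :-1] & fg[1:, 1:]
    if cell_ok.any():
        z00, z01 = z[:-1, :-1], z[:-1, 1:]
        z10, z11 = z[1:, :-1], z[1:, 1:]
        zmin = np.minimum(np.minimum(z00, z01), np.minimum(z10, z11))
        zmax = np.maximum(np.maximum(z00, z01), np.maximum(z10, z11))
        cell_ok = cell_ok & ((zmax - zmin) < discontinuity_mm)
    ci, cj = np.nonzero(cell_ok)
    v00 = index[ci, cj]
    v01 = index[ci, cj + 1]
    v10 = index[ci + 1, cj]
    v11 = index[ci + 1, cj + 1]
    faces = np.concatenate(
        [
            np.column_stack([v00, v01, v10]),
            np.column_stack([v01, v11, v10]),
        ]
    )
    return ToothMesh(verts, faces, pose_standardized=True)
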