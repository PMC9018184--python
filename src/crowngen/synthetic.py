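"""Seeded generator of molar-like crowns and fully conditioned training cases.

Emulates, at desk scale, the structure of a clinical occlusal-reconstruction
dataset for mandibular first molars: a crown with 4-5 cusps around a central
groove, mesial/distal neighbours, an opposing tooth hanging above with a
small inter-jaw gap, a preparation obtained by cutting the crown at a margin
line, occlusal-fingerprint contact patches where the jaws nearly touch, and
a per-pixel gap-distance field.

Crowns are analytic height fields: a smooth dome plus Gaussian cusp bumps
minus a groove valley. Every quantity is reproducible bit-for-bit from the
integer seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from ._channels import GLOBAL_CHANNELS, LOCAL_CHANNELS
from .depth import DepthEncoding, project_mesh
from .mesh import GeometryError, ToothMesh

__all__ = [
    "CrownParams",
    "CrownField",
    "CaseSample",
    "generate_crown",
    "crown_field",
    "generate_case",
    "generate_dataset",
    "load_manifest",
]


@dataclasses.dataclass
class CrownParams:
    """Parametric description of one molar crown (all lengths in mm)."""

    n_cusps: int = 4
    cusp_height: float = 1.5
    cusp_sigma: float = 1.0
    groove_depth: float = 0.7
    groove_width: float = 0.8
    crown_diameter: float = 10.0
    base_height: float = 3.5
    asymmetry_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cusps not in (4, 5):
            raise ValueError(f"n_cusps must be 4 or 5, got {self.n_cusps}")
        for name in ("cusp_sigma", "groove_width", "crown_diameter", "base_height"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("cusp_height", "groove_depth", "asymmetry_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.groove_depth > 0 and not self.groove_depth < self.cusp_height:
            raise ValueError("groove_depth must be < cusp_height")

    def replace(self, **kw) -> "CrownParams":
        return dataclasses.replace(self, **kw)


class CrownField:
    """Analytic occlusal height field of one crown.

    Exposes ``height(x, y)`` (mm, 0 outside the footprint), the elliptical
    ``footprint(x, y)`` and the central-groove ``groove_mask(x, y)``, so
    geometric oracles can integrate the surface without rasterization.
    """

    def __init__(self, params: CrownParams):
        self.params = params
        rng = np.random.default_rng(params.seed)
        p = params
        r = p.crown_diameter / 2.0
        # slight mesiodistal elongation keeps the principal axes distinct
        self.ax = 1.05 * r
        self.ay = 0.92 * r
        n = p.n_cusps
        jit = p.asymmetry_jitter
        # cusp ring: offset by pi/n so the central groove (along x) passes
        # between cusps, not through them
        theta = np.pi / n + 2 * np.pi * np.arange(n) / n
        theta = theta + rng.normal(0.0, 0.12 * jit, n)
        radius = 0.55 * r * (1.0 + rng.normal(0.0, 0.10 * jit, n))
        self.cusp_x = radius * np.cos(theta) * (self.ax / r)
        self.cusp_y = radius * np.sin(theta) * (self.ay / r)
        self.cusp_h = p.cusp_height * (1.0 + rng.normal(0.0, 0.10 * jit, n))
        self.cusp_h = np.clip(self.cusp_h, 0.0, None)
        # groove path: gentle seeded wiggle of the central line y = 0
        self.groove_amp = 0.25 * p.groove_width * (1.0 + jit * rng.uniform(-1, 1))
        self.groove_freq = 2 * np.pi / (2.2 * self.ax)
        self.groove_phase = rng.uniform(0, 2 * np.pi)

    # -- analytic pieces ---------------------------------------------------

    def _rho(self, x, y):
        return np.sqrt((x / self.ax) ** 2 + (y / self.ay) ** 2)

    def footprint(self, x, y):
        return self._rho(x, y) <= 1.0

    def groove_path(self, x):
        return self.groove_amp * np.sin(self.groove_freq * x + self.groove_phase)

    def groove_mask(self, x, y):
        """Groove region: within one groove_width of the path, on the crown."""
        p = self.params
        near = np.abs(y - self.groove_path(x)) <= p.groove_width
        return near & (self._rho(x, y) <= 0.88)

    def height(self, x, y):
        """Occlusal height z(x, y) in mm; exactly 0 outside the footprint."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        p = self.params
        rho = self._rho(x, y)
        inside = rho <= 1.0
        base = p.base_height * (1.0 - np.minimum(rho, 1.0) ** 6)
        z = base
        if p.cusp_height > 0:
            s2 = 2.0 * p.cusp_sigma**2
            for cx, cy, ch in zip(self.cusp_x, self.cusp_y, self.cusp_h):
                z = z + ch * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / s2)
        if p.groove_depth > 0:
            w2 = 2.0 * p.groove_width**2
            valley = p.groove_depth * np.exp(-((y - self.groove_path(x)) ** 2) / w2)
            # taper so the valley never undercuts the crown rim
            valley = valley * np.exp(-(np.minimum(rho, 1.0) / 0.85) ** 8)
            z = z - valley
        return np.where(inside, np.clip(z, 0.0, None), 0.0)

    def max_height(self, grid_step: float = 0.02) -> float:
        """Brute-force maximum of the height field on a fine grid."""
        g = np.arange(-self.ax, self.ax + grid_step, grid_step)
        xx, yy = np.meshgrid(g, g)
        return float(self.height(xx, yy).max())

    # -- meshing -----------------------------------------------------------

    def mesh(self, grid_step: float = 0.1) -> ToothMesh:
        """Triangulate the height field over its elliptical footprint."""
        gx = np.arange(-self.ax, self.ax + grid_step / 2, grid_step)
        gy = np.arange(-self.ay, self.ay + grid_step / 2, grid_step)
        xx, yy = np.meshgrid(gx, gy)
        inside = self.footprint(xx, yy)
        z = self.height(xx, yy)
        idx = -np.ones(inside.shape, dtype=np.int64)
        idx[inside] = np.arange(int(inside.sum()))
        verts = np.column_stack([xx[inside], yy[inside], z[inside]])
        ok = inside[:-1, :-1] & inside[:-1, 1:] & inside[1:, :-1] & inside[1:, 1:]
        ci, cj = np.nonzero(ok)
        v00, v01 = idx[ci, cj], idx[ci, cj + 1]
        v10, v11 = idx[ci + 1, cj], idx[ci + 1, cj + 1]
        faces = np.concatenate(
            [np.column_stack([v00, v01, v10]), np.column_stack([v01, v11, v10])]
        )
        if len(verts) < 3 or len(faces) == 0:
            raise GeometryError("crown footprint too small for the grid step")
        return ToothMesh(verts, faces, pose_standardized=True).prune_unreferenced()


def crown_field(params: CrownParams) -> CrownField:
    """Analytic height field for ``params`` (the meshing/rendering oracle)."""
    return CrownField(params)


def generate_crown(params: CrownParams, grid_step: float = 0.1) -> ToothMesh:
    """Deterministic molar-like crown mesh for ``params``.

    A smooth elliptical dome carrying ``n_cusps`` Gaussian cusps on a ring,
    cut by a central groove valley; coordinates in mm, occlusal side up,
    reproducible bit-for-bit from ``params.seed``.
    """
    return CrownField(params).mesh(grid_step=grid_step)


# ---------------------------------------------------------------------------
# conditioned cases


@dataclasses.dataclass
class CaseSample:
    """One training/inference case.

    ``input_stack`` is the (4, H, W) float32 conditioning stack in channel
    order ``x1, c1, c2, d`` (see :mod:`crowngen._channels`);
    ``local_input_stack`` is the (4, hl, wl) defect-crop stack
    ``x1p, c1p, c3, dp``. Targets are single-channel images in [0, 1].
    ``local_rows``/``local_cols`` are the nearest-neighbour index maps that
    cut the local crop out of any full-frame image.
    """

    input_stack: np.ndarray
    local_input_stack: np.ndarray
    target_global: np.ndarray
    target_local: np.ndarray
    defect_mask: np.ndarray
    seed: int
    encoding: DepthEncoding | None = None
    local_rows: np.ndarray | None = None
    local_cols: np.ndarray | None = None
    groove_mask: np.ndarray | None = None
    fingerprint_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        ishape = self.input_stack.shape[1:]
        lshape = self.local_input_stack.shape[1:]
        if self.target_global.shape != ishape or self.defect_mask.shape != ishape:
            raise ValueError("global channels disagree in spatial size")
        if self.target_local.shape != lshape:
            raise ValueError("local channels disagree in spatial size")
        for m in (self.defect_mask, self.input_stack[2], self.local_input_stack[2]):
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask channels must be binary")

    def crop_local(self, image: np.ndarray) -> np.ndarray:
        """Cut the defect crop out of a full-frame image (NN resampling)."""
        return image[np.ix_(self.local_rows, self.local_cols)]


def _local_index_maps(mask: np.ndarray, local_size: int):
    """Square, 10%-padded bounding box of the mask as NN index maps."""
    rows, cols = np.nonzero(mask)
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())
    side = max(r1 - r0 + 1, c1 - c0 + 1)
    side = int(np.ceil(side * 1.2))  # 10% padding each side
    side = min(side, mask.shape[0], mask.shape[1])
    rc, cc = (r0 + r1) / 2.0, (c0 + c1) / 2.0
    r_start = int(round(rc - side / 2.0))
    c_start = int(round(cc - side / 2.0))
    r_start = int(np.clip(r_start, 0, mask.shape[0] - side))
    c_start = int(np.clip(c_start, 0, mask.shape[1] - side))
    lin = np.floor(np.arange(local_size) * side / local_size).astype(np.int64)
    return r_start + lin, c_start + lin


def generate_case(
    seed: int,
    crown_params: CrownParams | None = None,
    image_size: int = 64,
    local_size: int = 32,
    margin_fraction: float = 0.5,
    contact_threshold: float = 0.15,
    alpha: float = 2.0,
    h: float = 6.0,
    grid_step: float = 0.12,
) -> CaseSample:
    """Build one fully conditioned case from an integer seed.

    The target scene is the crown flanked by two neighbours; the opposing
    crown hangs mirrored above it with a seeded minimum inter-jaw gap. The
    preparation deletes the crown above ``margin_fraction`` of its height.
    Occlusal fingerprints are the pixels whose inter-jaw gap is below
    ``contact_threshold`` (mm).
    """
    if not local_size < image_size:
        raise ValueError("local_size must be < image_size")
    rng = np.random.default_rng(seed)
    if crown_params is None:
        crown_params = CrownParams(
            n_cusps=int(rng.choice([4, 5])),
            cusp_height=float(rng.uniform(1.2, 1.8)),
            groove_depth=float(rng.uniform(0.5, 0.9)),
            seed=seed,
        )
    center = CrownField(crown_params.replace(seed=seed * 4 + 0))
    adj_l = CrownField(
        crown_params.replace(seed=seed * 4 + 1, crown_diameter=crown_params.crown_diameter * 0.92)
    )
    adj_r = CrownField(
        crown_params.replace(seed=seed * 4 + 2, crown_diameter=crown_params.crown_diameter * 0.95)
    )
    opposing = CrownField(crown_params.replace(seed=seed * 4 + 3))

    spacing = crown_params.crown_diameter * 1.08
    pieces = [(center, 0.0, 0.0), (adj_l, -spacing, 0.0), (adj_r, spacing, 0.0)]

    # frame: three crowns across, small margin
    half_w = spacing + center.ax * 1.15
    mm_per_pixel = 2 * half_w / image_size
    enc = DepthEncoding(
        alpha=alpha,
        h=h,
        mm_per_pixel=mm_per_pixel,
        width=image_size,
        height=image_size,
        origin_x=-(image_size - 1) / 2 * mm_per_pixel,
        origin_y=-(image_size - 1) / 2 * mm_per_pixel,
    )

    def scene_mesh(fields, carve_margin: float | None = None) -> ToothMesh:
        verts, faces, off = [], [], 0
        for k, (f, dx, dy) in enumerate(fields):
            m = f.mesh(grid_step=grid_step)
            v = m.vertices.copy()
            v[:, 0] += dx
            v[:, 1] += dy
            if carve_margin is not None and k == 0:
                v[:, 2] = np.minimum(v[:, 2], carve_margin)
            verts.append(v)
            faces.append(m.faces + off)
            off += len(v)
        return ToothMesh(np.concatenate(verts), np.concatenate(faces), True)

    target_mesh = scene_mesh(pieces)
    ref_z = float(target_mesh.vertices[:, 2].max())
    enc = dataclasses.replace(enc, reference_z=ref_z)

    z_margin = margin_fraction * center.max_height(grid_step=0.05)
    prep_mesh = scene_mesh(pieces, carve_margin=z_margin)

    z1_dm, z1_buf = project_mesh(target_mesh, enc, return_zbuffer=True)
    x1_dm, x1_buf = project_mesh(prep_mesh, enc, return_zbuffer=True)
    if not z1_dm.foreground.any():
        raise GeometryError("empty projection for the target scene")

    # defect: pixels whose rendered surface height changed when carving
    both = np.isfinite(z1_buf) & np.isfinite(x1_buf)
    defect = np.zeros((image_size, image_size), dtype=np.uint8)
    defect[both] = (z1_buf[both] - x1_buf[both]) > 1e-9

    # pixel-centre world coordinates
    px = enc.origin_x + np.arange(image_size) * mm_per_pixel
    py = enc.origin_y + np.arange(image_size) * mm_per_pixel
    xx, yy = np.meshgrid(px, py)

    # opposing jaw: mirrored crown hanging above the centre tooth
    opp_h = opposing.height(xx, yy)
    opp_fp = opposing.footprint(xx, yy)
    gap_min = float(rng.uniform(0.02, 0.10))
    z_target_grid = np.where(np.isfinite(z1_buf), z1_buf, -np.inf)
    overlap = opp_fp & np.isfinite(z1_buf)
    if not overlap.any():
        raise GeometryError("opposing tooth does not overlap the scene")
    c_level = gap_min + float((z_target_grid + opp_h)[overlap].max())
    z_opp_surf = np.where(opp_fp, c_level - opp_h, np.inf)

    gap_mm = np.full((image_size, image_size), h, dtype=np.float64)
    fg = np.isfinite(z1_buf)
    gap_mm[fg] = np.clip(z_opp_surf[fg] - z1_buf[fg], 0.0, h)

    # opposing-tooth depth map, rendered from its own mesh on the same grid
    opp_mesh = opposing.mesh(grid_step=grid_step)
    c1_dm = project_mesh(opp_mesh, dataclasses.replace(enc, reference_z=None))

    groove = center.groove_mask(xx, yy).astype(np.uint8)
    fingerprint = (fg & (gap_mm < contact_threshold)).astype(np.uint8)
    c2 = np.maximum(groove, fingerprint)

    x1 = x1_dm.pixels.astype(np.float32) / 255.0
    z1 = z1_dm.pixels.astype(np.float32) / 255.0
    c1 = c1_dm.pixels.astype(np.float32) / 255.0
    d = (gap_mm / h).astype(np.float32)

    input_stack = np.stack([x1, c1, c2.astype(np.float32), d])
    lr, lc = _local_index_maps(defect, local_size)
    sub = np.ix_(lr, lc)
    local_stack = np.stack(
        [x1[sub], c1[sub], groove.astype(np.float32)[sub], d[sub]]
    )
    return CaseSample(
        input_stack=input_stack,
        local_input_stack=local_stack,
        target_global=z1,
        target_local=z1[sub],
        defect_mask=defect,
        seed=seed,
        encoding=z1_dm.encoding,
        local_rows=lr,
        local_cols=lc,
        groove_mask=groove,
        fingerprint_mask=fingerprint,
    )


# ---------------------------------------------------------------------------
# datasets on disk


def _case_seed(base_seed: int, i: int) -> int:
    return int((base_seed * 1_000_003 + i * 7919 + 1) % (2**31))


def split_sizes(n: int, ratios=(0.85, 0.09, 0.06)) -> tuple[int, int, int]:
    """Train/val/test sizes from ratios (largest-remainder rounding)."""
    raw = np.array(ratios, dtype=float) * n / sum(ratios)
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for k in range(rem):
        base[order[k % 3]] += 1
    return int(base[0]), int(base[1]), int(base[2])


def generate_dataset(
    n: int,
    base_seed: int,
    out_dir: str | Path,
    ratios=(0.85, 0.09, 0.06),
    image_size: int = 64,
    local_size: int = 32,
    crown_params: CrownParams | None = None,
    **case_kw,
) -> dict:
    """Write ``n`` cases as per-channel PNGs plus a JSON manifest.

    The split defaults to 85/9/6 percent train/val/test. Returns the
    manifest dict (also written to ``out_dir/manifest.json``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise IOError(f"cannot create output directory {out_dir}: {e}") from e

    n_train, n_val, n_test = split_sizes(n, ratios)
    warnings_list = []
    if n_val == 0 or n_test == 0:
        warnings_list.append(
            f"dataset of n={n} leaves an empty validation or test split; "
            "all remaining cases assigned to train"
        )
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test

    cases = []
    for i in range(n):
        seed = _case_seed(base_seed, i)
        case = generate_case(
            seed,
            crown_params=crown_params,
            image_size=image_size,
            local_size=local_size,
            **case_kw,
        )
        cdir = out_dir / f"case_{i:04d}"
        cdir.mkdir(exist_ok=True)
        channels = {}
        imgs = {
            "x1": case.input_stack[0],
            "c1": case.input_stack[1],
            "c2": case.input_stack[2],
            "d": case.input_stack[3],
            "z1": case.target_global,
            "defect_mask": case.defect_mask.astype(np.float32),
            "x1p": case.local_input_stack[0],
            "c1p": case.local_input_stack[1],
            "c3": case.local_input_stack[2],
            "dp": case.local_input_stack[3],
            "z1p": case.target_local,
        }
        for name, img in imgs.items():
            path = cdir / f"{name}.png"
            iio.imwrite(path, np.floor(img * 255.0 + 0.5).astype(np.uint8))
            channels[name] = str(path.relative_to(out_dir))
        cases.append(
            {
                "case_id": f"case_{i:04d}",
                "seed": seed,
                "split": splits[i],
                "channels": channels,
                "local_rows": case.local_rows.tolist(),
                "local_cols": case.local_cols.tolist(),
            }
        )

    manifest = {
        "n": n,
        "base_seed": base_seed,
        "image_size": image_size,
        "local_size": local_size,
        "ratios": list(ratios),
        "split_sizes": {"train": n_train, "val": n_val, "test": n_test},
        "warnings": warnings_list,
        "cases": cases,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())


def cases_from_manifest(manifest: dict, split: str | None = None, **case_kw):
    """Regenerate CaseSamples from the seeds recorded in a manifest."""
    out = []
    for entry in manifest["cases"]:
        if split is not None and entry["split"] != split:
            continue
        out.append(
            generate_case(
                entry["seed"],
                image_size=manifest["image_size"],
                local_size=manifest["local_size"],
                **case_kw,
            )
        )
    return out
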