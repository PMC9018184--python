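"""Image-quality metrics and 3D surface-deviation statistics.

PSNR and SSIM follow their standard definitions (SSIM through scikit-image
with the original Wang et al. configuration: 11x11 Gaussian window,
sigma 1.5, K1=0.01, K2=0.03, population covariance). FSIM is implemented
from its definition: per-pixel similarity of phase congruency (log-Gabor,
4 scales x 4 orientations) and Scharr gradient magnitude, combined
multiplicatively and averaged with max-phase-congruency weights. Surface
deviation reports the RMS and standard deviation of signed point-to-surface
distances between two meshes sharing the standardized frame.
"""

from __future__ import annotations

import dataclasses
import csv
from pathlib import Path

import numpy as np
from scipy.ndimage import convolve
from skimage.metrics import structural_similarity

from .mesh import GeometryError, ToothMesh

PSNR_CAP_DB = 100.0


class MetricError(ValueError):
    pass


@dataclasses.dataclass
class MetricReport:
    """PSNR/FSIM/SSIM and surface deviations for one generated result."""

    psnr: float
    fsim: float
    ssim: float
    sd_mm: float | None = None
    rms_mm: float | None = None

    def as_row(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# PSNR


def psnr(a, b, peak: float = 255.0, cap: float = PSNR_CAP_DB, return_flag=False):
    """10*log10(peak^2 / MSE); identical images return the documented cap."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise MetricError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return (cap, True) if return_flag else cap
    value = min(10.0 * np.log10(peak**2 / mse), cap)
    return (value, False) if return_flag else value


# ---------------------------------------------------------------------------
# SSIM


def ssim(a, b, data_range: float | None = None) -> float:
    """Mean local SSIM (original 11x11 Gaussian-window convention)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise MetricError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise MetricError("image smaller than the 11x11 SSIM window")
    if data_range is None:
        data_range = 255.0 if a.max() > 1.5 or b.max() > 1.5 else 1.0
    return float(
        structural_similarity(
            a,
            b,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


# ---------------------------------------------------------------------------
# FSIM


_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=np.float64) / 16.0
_SCHARR_Y = _SCHARR_X.T


def _gradient_magnitude(img):
    gx = convolve(img, _SCHARR_X, mode="nearest")
    gy = convolve(img, _SCHARR_Y, mode="nearest")
    return np.sqrt(gx**2 + gy**2)


def _phase_congruency(img, n_scales=4, n_orient=4, min_wavelength=6.0,
                      mult=2.0, sigma_on_f=0.55, d_theta_sigma=1.2):
    """Log-Gabor phase congruency, simplified (no noise compensation)."""
    rows, cols = img.shape
    fy = np.fft.fftfreq(rows)
    fx = np.fft.fftfreq(cols)
    u2, u1 = np.meshgrid(fy, fx, indexing="ij")
    radius = np.sqrt(u1**2 + u2**2)
    radius[0, 0] = 1.0
    theta = np.arctan2(-u2, u1)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)
    imf = np.fft.fft2(img)
    theta_sigma = np.pi / n_orient / d_theta_sigma

    sum_energy = np.zeros_like(img)
    sum_an = np.zeros_like(img)
    for o in range(n_orient):
        angle = o * np.pi / n_orient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * theta_sigma**2))
        sum_e = np.zeros_like(img)
        sum_o = np.zeros_like(img)
        an_o = np.zeros_like(img)
        for s in range(n_scales):
            wavelength = min_wavelength * mult**s
            f0 = 1.0 / wavelength
            log_gabor = np.exp(
                -(np.log(radius / f0) ** 2) / (2 * np.log(sigma_on_f) ** 2)
            )
            log_gabor *= lowpass
            log_gabor[0, 0] = 0.0
            response = np.fft.ifft2(imf * log_gabor * spread)
            sum_e += np.real(response)
            sum_o += np.imag(response)
            an_o += np.abs(response)
        sum_energy += np.sqrt(sum_e**2 + sum_o**2)
        sum_an += an_o
    return sum_energy / (sum_an + 1e-8)


def fsim(a, b) -> float:
    """Feature similarity index in [0, 1].

    Per-pixel phase-congruency and gradient-magnitude similarities are
    multiplied and averaged with weights max(PC_a, PC_b).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise MetricError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 32:
        raise MetricError("FSIM needs images of at least 32x32")
    # work on the 8-bit scale regardless of input normalization
    if a.max() <= 1.5 and b.max() <= 1.5:
        a, b = a * 255.0, b * 255.0
    identical = np.array_equal(a, b)
    pc_a = _phase_congruency(a)
    pc_b = _phase_congruency(b)
    gm_a = _gradient_magnitude(a)
    gm_b = _gradient_magnitude(b)
    t1, t2 = 0.85, 160.0
    s_pc = (2 * pc_a * pc_b + t1) / (pc_a**2 + pc_b**2 + t1)
    s_gm = (2 * gm_a * gm_b + t2) / (gm_a**2 + gm_b**2 + t2)
    pcm = np.maximum(pc_a, pc_b)
    denom = pcm.sum()
    if denom <= 0:
        if identical:
            return 1.0
        raise MetricError("degenerate images: zero phase congruency everywhere")
    return float((s_pc * s_gm * pcm).sum() / denom)


# ---------------------------------------------------------------------------
# surface deviation


def surface_deviation(gen: ToothMesh, target: ToothMesh,
                      icp: bool = False) -> tuple[float, float]:
    """(SD, RMS) of signed point-to-surface distances, both in mm.

    Every generator vertex is measured against the target surface. The
    meshes are assumed to share the standardized frame (the adjacent teeth
    register them); an optional rigid ICP pre-alignment is off by default.
    """
    import trimesh

    if gen.n_vertices == 0 or target.n_faces == 0:
        raise GeometryError("surface deviation needs non-empty meshes")
    points = gen.vertices
    tm = target.to_trimesh()
    if icp:
        matrix, _, _ = trimesh.registration.icp(points, tm, max_iterations=20)
        points = trimesh.transform_points(points, matrix)
    closest, tri = _closest_on_surface(tm, points)
    delta = points - closest
    dist = np.linalg.norm(delta, axis=1)
    normals = tm.face_normals[tri]
    sign = np.sign(np.einsum("ij,ij->i", delta, normals))
    sign[sign == 0] = 1.0
    signed = sign * dist
    rms = float(np.sqrt(np.mean(signed**2)))
    sd = float(np.std(signed))
    return sd, rms


def _closest_on_surface(tm, points, k: int = 16):
    """Closest surface point and face index per query point.

    Candidate faces come from a KD-tree over triangle centroids (k nearest),
    with exact point-triangle projection on the candidates; exact for
    meshes whose triangles are small relative to feature spacing, which
    holds for the rasterized height fields this package produces.
    """
    from scipy.spatial import cKDTree
    from trimesh.triangles import closest_point as tri_closest

    triangles = tm.triangles
    k = min(k, len(triangles))
    tree = cKDTree(triangles.mean(axis=1))
    _, cand = tree.query(points, k=k)
    cand = np.atleast_2d(cand)
    n = len(points)
    pts_rep = np.repeat(points, k, axis=0)
    tris_rep = triangles[cand.ravel()]
    cp = tri_closest(tris_rep, pts_rep)
    d2 = np.sum((cp - pts_rep) ** 2, axis=1).reshape(n, k)
    best = d2.argmin(axis=1)
    rows = np.arange(n)
    return cp.reshape(n, k, 3)[rows, best], cand[rows, best]


def crown_deviation(gen_img, target_img, encoding, region_mask,
                    discontinuity_mm: float | None = None):
    """(SD, RMS) between the reconstructed crown regions of two depth maps.

    Restricts both images to ``region_mask`` (the synthesized crown region)
    before back-projection, so the comparison covers the generated crown
    against the target crown rather than the whole scene. The region-growth
    discontinuity threshold scales with the pixel pitch unless given.
    """
    from .depth import DepthMap, reconstruct_mesh

    if discontinuity_mm is None:
        discontinuity_mm = max(0.5, 4.0 * encoding.mm_per_pixel)
    m = np.asarray(region_mask, dtype=bool)
    gen_m = np.where(m, np.asarray(gen_img), 0).astype(np.uint8)
    tgt_m = np.where(m, np.asarray(target_img), 0).astype(np.uint8)
    gen_mesh = reconstruct_mesh(DepthMap(gen_m, encoding), discontinuity_mm)
    tgt_mesh = reconstruct_mesh(DepthMap(tgt_m, encoding), discontinuity_mm)
    return surface_deviation(
        gen_mesh.prune_unreferenced(), tgt_mesh.prune_unreferenced()
    )


# ---------------------------------------------------------------------------
# batch evaluation


def evaluate_pair(gen_img, target_img, gen_mesh=None, target_mesh=None,
                  peak: float = 255.0) -> MetricReport:
    sd = rms = None
    if gen_mesh is not None and target_mesh is not None:
        sd, rms = surface_deviation(gen_mesh, target_mesh)
    return MetricReport(
        psnr=psnr(gen_img, target_img, peak=peak),
        fsim=fsim(gen_img, target_img),
        ssim=ssim(gen_img, target_img),
        sd_mm=sd,
        rms_mm=rms,
    )


def write_metric_csv(reports, path) -> None:
    """Per-case rows plus mean and SD summary rows."""
    path = Path(path)
    fields = ["case", "psnr", "fsim", "ssim", "sd_mm", "rms_mm"]
    rows = [r.as_row() for r in reports]
    with path.open("w", newline="") as f:
        wtr = csv.DictWriter(f, fieldnames=fields)
        wtr.writeheader()
        for i, row in enumerate(rows):
            wtr.writerow({"case": i, **row})
        for stat, fn in (("mean", np.mean), ("sd", np.std)):
            summary = {"case": stat}
            for k in fields[1:]:
                vals = [r[k] for r in rows if r[k] is not None]
                summary[k] = float(fn(vals)) if vals else ""
            wtr.writerow(summary)
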