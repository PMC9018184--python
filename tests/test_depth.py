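"""Depth codec, projection, entropy, pose and reconstruction contracts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from crowngen.depth import (
    DepthEncoding,
    DepthMap,
    depth_to_pixel,
    image_entropy,
    pixel_to_depth,
    project_mesh,
    quantization_bound,
    reconstruct_mesh,
    select_alpha,
    standardize_pose,
)
from crowngen.mesh import GeometryError, ToothMesh
from crowngen.synthetic import crown_field

from conftest import plane_mesh


def enc(alpha, **kw):
    return DepthEncoding(alpha=alpha, h=kw.pop("h", 6.0), mm_per_pixel=0.1, **kw)


class TestPixelDistanceMapping:
    def test_zero_distance_is_full_brightness(self):
        for a in (0.5, 1.0, 2.0, 4.0):
            assert depth_to_pixel(0.0, enc(a)) == 255

    def test_plane_boundary_is_zero(self):
        for a in (0.5, 1.0, 2.0, 4.0):
            assert depth_to_pixel(6.0, enc(a)) == 0
            assert depth_to_pixel(6.0001, enc(a)) == 0

    def test_hand_evaluated_level(self):
        # 255 * (36 - 9) / 36 = 191.25 -> 191
        assert depth_to_pixel(3.0, enc(2.0)) == 191

    def test_inverse_endpoints(self):
        assert pixel_to_depth(255, enc(2.0)) == 0.0
        assert pixel_to_depth(0, enc(2.0)) == 6.0

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 4.0])
    def test_round_trip_within_quantization_step(self, alpha):
        e = enc(alpha)
        bound = quantization_bound(e)
        d = np.arange(0.0, 6.0 + 1e-9, 0.01)
        back = pixel_to_depth(depth_to_pixel(d, e).astype(float), e)
        assert np.max(np.abs(back - d)) <= bound

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 1.0, 2.0, 4.0, 7.5])
    def test_monotone_non_increasing(self, alpha):
        e = enc(alpha)
        d = np.linspace(0, 7, 2001)
        levels = depth_to_pixel(d, e).astype(int)
        assert (np.diff(levels) <= 0).all()


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert image_entropy(np.full((32, 32), 77, dtype=np.uint8)) == 0.0

    def test_two_equiprobable_levels_one_bit(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:, 8:] = 255
        assert image_entropy(img) == pytest.approx(1.0)

    def test_uniform_256_levels_eight_bits(self):
        img = np.repeat(np.arange(256, dtype=np.uint8), 4).reshape(32, 32)
        assert image_entropy(img) == pytest.approx(8.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        h = image_entropy(img)
        assert 0.0 <= h <= 8.0
        assert image_entropy(rng.permutation(img.ravel())) == pytest.approx(h)


class TestProjection:
    def test_plane_at_reference_renders_255(self):
        m = plane_mesh(z=1.0)
        e = dataclasses.replace(enc(2.0), width=32, height=32, reference_z=1.0)
        dm = project_mesh(m, e)
        assert (dm.pixels == 255).all()

    def test_plane_h_below_reference_renders_0(self):
        m = plane_mesh(z=0.0)
        e = dataclasses.replace(enc(2.0), width=32, height=32, reference_z=6.0)
        assert (project_mesh(m, e).pixels == 0).all()

    def test_unstandardized_mesh_rejected(self):
        m = plane_mesh(standardized=False)
        with pytest.raises(GeometryError):
            project_mesh(m, enc(2.0))

    def test_empty_projection_raises(self):
        m = plane_mesh(z=0.0)
        e = dataclasses.replace(
            enc(2.0), width=16, height=16, origin_x=500.0, origin_y=500.0,
            reference_z=0.0,
        )
        with pytest.raises(GeometryError):
            project_mesh(m, e)

    def test_gaussian_bump_matches_closed_form(self):
        """Rendered levels agree with direct formula evaluation to 1 level."""
        from crowngen.mesh import ToothMesh

        g = np.linspace(-4, 4, 161)  # fine vertex grid
        xx, yy = np.meshgrid(g, g)
        zz = 3.0 * np.exp(-(xx**2 + yy**2) / (2 * 1.5**2))
        n = len(g)
        idx = np.arange(n * n).reshape(n, n)
        faces = np.concatenate(
            [
                np.column_stack(
                    [idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()]
                ),
                np.column_stack(
                    [idx[:-1, 1:].ravel(), idx[1:, 1:].ravel(), idx[1:, :-1].ravel()]
                ),
            ]
        )
        mesh = ToothMesh(
            np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]),
            faces,
            pose_standardized=True,
        )
        e = DepthEncoding(alpha=2.0, h=6.0, mm_per_pixel=0.125, width=64, height=64)
        dm = project_mesh(mesh, e)
        out = dm.encoding
        px = out.origin_x + np.arange(64) * out.mm_per_pixel
        py = out.origin_y + np.arange(64) * out.mm_per_pixel
        gx, gy = np.meshgrid(px, py)
        z_true = 3.0 * np.exp(-(gx**2 + gy**2) / (2 * 1.5**2))
        d_true = out.reference_z - z_true
        expected = np.floor(255 * (36 - d_true**2) / 36 + 0.5)
        assert np.max(np.abs(dm.pixels.astype(int) - expected)) <= 1

    def test_alpha_reweights_levels(self, crown_mesh, encoding_96):
        imgs = [
            project_mesh(crown_mesh, dataclasses.replace(encoding_96, alpha=a)).pixels
            for a in (1.0, 2.0)
        ]
        assert not np.array_equal(imgs[0], imgs[1])


class TestSelectAlpha:
    def test_single_candidate(self, crown_mesh, encoding_96):
        assert select_alpha(crown_mesh, [3.0], encoding_96) == 3.0

    def test_agrees_with_exhaustive_scan(self, crown_mesh, encoding_96):
        cands = [0.5, 1.0, 2.0, 4.0]
        entropies = {
            a: image_entropy(
                project_mesh(crown_mesh, dataclasses.replace(encoding_96, alpha=a))
            )
            for a in cands
        }
        best = min(cands, key=lambda a: (-entropies[a], a))
        assert select_alpha(crown_mesh, cands, encoding_96) == best

    def test_tie_breaks_toward_smaller_alpha(self):
        m = plane_mesh(z=0.0)
        e = dataclasses.replace(
            DepthEncoding(mm_per_pixel=0.5, width=16, height=16), reference_z=0.0
        )
        # a flat plane renders 255 everywhere for every alpha: all ties
        assert select_alpha(m, [4.0, 1.0, 2.0], e) == 1.0


class TestStandardizePose:
    def test_idempotent(self, crown_mesh):
        once = standardize_pose(crown_mesh)
        twice = standardize_pose(once)
        assert np.max(np.abs(once.vertices - twice.vertices)) < 1e-9

    def test_recovers_known_rotation(self, crown_mesh):
        ref = standardize_pose(crown_mesh)
        rot = Rotation.from_euler("xyz", [30, 45, 10], degrees=True)
        moved = ToothMesh(
            rot.apply(crown_mesh.vertices) + np.array([5.0, -3.0, 2.0]),
            crown_mesh.faces,
        )
        back = standardize_pose(moved)
        assert np.max(np.abs(back.vertices - ref.vertices)) < 1e-6

    def test_bounding_box_centered(self, crown_mesh):
        out = standardize_pose(crown_mesh)
        assert np.max(np.abs(out.bounds().mean(axis=0))) < 1e-9
        assert out.pose_standardized

    def test_degenerate_geometry_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            standardize_pose(ToothMesh(line, np.array([[0, 1, 2]])))


class TestReconstruction:
    def test_flat_plane_round_trip_exact(self):
        m = plane_mesh(z=2.0)
        e = dataclasses.replace(enc(2.0), width=32, height=32, reference_z=3.0)
        dm = project_mesh(m, e)
        rec = reconstruct_mesh(dm)
        bound = quantization_bound(e)
        assert np.max(np.abs(rec.vertices[:, 2] - 2.0)) <= bound

    def test_crown_round_trip_rms_within_codec_bound(self, crown_mesh):
        from crowngen.metrics import surface_deviation

        e = DepthEncoding(alpha=2.0, h=6.0, mm_per_pixel=0.09, width=128, height=128)
        dm = project_mesh(crown_mesh, e)
        rec = reconstruct_mesh(dm)
        _, rms = surface_deviation(rec, crown_mesh)
        assert rms <= 2 * quantization_bound(e)

    def test_interior_hole_not_bridged(self):
        e = DepthEncoding(
            alpha=1.0, h=6.0, mm_per_pixel=0.5, width=16, height=16,
            reference_z=0.0, origin_x=0.0, origin_y=0.0,
        )
        img = np.full((16, 16), 128, dtype=np.uint8)
        img[6:10, 6:10] = 0  # background hole
        rec = reconstruct_mesh(DepthMap(img, e))
        hole_lo, hole_hi = 6 * 0.5, 9 * 0.5
        centroids = rec.vertices[rec.faces].mean(axis=1)
        inside = (
            (centroids[:, 0] > hole_lo) & (centroids[:, 0] < hole_hi)
            & (centroids[:, 1] > hole_lo) & (centroids[:, 1] < hole_hi)
        )
        assert not inside.any()

    def test_too_few_foreground_pixels(self):
        e = dataclasses.replace(
            enc(2.0), width=8, height=8, reference_z=0.0, origin_x=0.0, origin_y=0.0
        )
        img = np.zeros((8, 8), dtype=np.uint8)
        img[0, 0] = 10
        with pytest.raises(GeometryError):
            reconstruct_mesh(DepthMap(img, e))

    def test_discontinuity_threshold_respected(self):
        e = dataclasses.replace(
            enc(1.0), width=8, height=8, reference_z=0.0, origin_x=0.0, origin_y=0.0
        )
        img = np.full((8, 8), 250, dtype=np.uint8)
        img[:, 4:] = 50  # ~4.7 mm cliff
        rec = reconstruct_mesh(DepthMap(img, e), discontinuity_mm=0.5)
        # no face connects the two plateaus across the cliff
        left = rec.vertices[:, 2] > -1.0
        spans = left[rec.faces].any(axis=1) & (~left[rec.faces]).any(axis=1)
        assert not spans.any()


def test_depth_map_png_round_trip(tmp_path, crown_mesh, encoding_96):
    dm = project_mesh(crown_mesh, encoding_96)
    dm.save(tmp_path / "crown.png")
    back = DepthMap.load(tmp_path / "crown.png")
    assert np.array_equal(back.pixels, dm.pixels)
    assert back.encoding == dm.encoding
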