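"""Parametric crown generator and conditioned-case contracts."""

import hashlib
import json

import numpy as np
import pytest

from crowngen.synthetic import (
    CrownParams,
    crown_field,
    generate_case,
    generate_crown,
    generate_dataset,
    split_sizes,
)


def _grid_height(field, step=0.05):
    g = np.arange(-field.ax, field.ax + step, step)
    xx, yy = np.meshgrid(g, g)
    return xx, yy, field.height(xx, yy)


def _count_local_maxima(z, min_height):
    """8-neighbour strict local maxima above min_height (brute force)."""
    count = 0
    for i in range(1, z.shape[0] - 1):
        for j in range(1, z.shape[1] - 1):
            c = z[i, j]
            if c < min_height:
                continue
            neigh = z[i - 1 : i + 2, j - 1 : j + 2].copy()
            neigh[1, 1] = -np.inf
            if c > neigh.max():
                count += 1
    return count


class TestCrownParams:
    @pytest.mark.parametrize(
        "kw,field",
        [
            (dict(n_cusps=3), "n_cusps"),
            (dict(crown_diameter=0.0), "crown_diameter"),
            (dict(cusp_sigma=-1.0), "cusp_sigma"),
            (dict(groove_depth=2.5, cusp_height=2.0), "groove_depth"),
        ],
    )
    def test_invalid_parameters_name_the_field(self, kw, field):
        with pytest.raises(ValueError, match=field):
            CrownParams(**kw)


class TestGenerateCrown:
    def test_degenerate_flat_crown(self):
        p = CrownParams(cusp_height=0.0, groove_depth=0.0, seed=1)
        m = generate_crown(p)
        assert m.vertices[:, 2].max() == pytest.approx(p.base_height, abs=1e-9)

    def test_bit_identical_determinism(self, crown_params):
        a = generate_crown(crown_params)
        b = generate_crown(crown_params)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_four_cusps_give_four_local_maxima(self, crown_params):
        # brute-force 8-neighbour scan of the rasterized height field
        field = crown_field(crown_params)
        _, _, z = _grid_height(field, step=0.05)
        n = _count_local_maxima(z, min_height=crown_params.base_height * 0.5)
        assert n == 4

    def test_groove_lower_than_cusp_maxima(self, crown_params):
        """Morphological plausibility on the analytic height field."""
        field = crown_field(crown_params)
        xx, yy, z = _grid_height(field, step=0.05)
        groove = field.groove_mask(xx, yy)
        assert groove.any()
        assert z[groove].max() < z.max() - 0.25 * crown_params.groove_depth


class TestGenerateCase:
    def test_channel_shapes_and_binary_masks(self, case64):
        assert case64.input_stack.shape == (4, 64, 64)
        assert case64.local_input_stack.shape == (4, 32, 32)
        assert case64.target_global.shape == (64, 64)
        assert case64.target_local.shape == (32, 32)
        for m in (case64.defect_mask, case64.groove_mask, case64.fingerprint_mask):
            assert set(np.unique(m)).issubset({0, 1})

    def test_outside_defect_preparation_equals_target(self, case64):
        mismatch = (case64.input_stack[0] != case64.target_global) & (
            case64.defect_mask == 0
        )
        assert mismatch.sum() == 0

    def test_defect_strictly_inside_change_region(self, case64):
        assert case64.defect_mask.any()
        # the defect never covers background-only pixels
        assert (case64.defect_mask & (case64.target_global == 0)).sum() == 0

    def test_c2_is_union_of_fingerprint_and_groove(self, case64):
        union = np.maximum(case64.groove_mask, case64.fingerprint_mask)
        assert np.array_equal(case64.input_stack[2], union.astype(np.float32))

    def test_zero_contact_threshold_gives_groove_only(self):
        case = generate_case(5, image_size=48, local_size=24, contact_threshold=0.0)
        assert case.fingerprint_mask.sum() == 0
        assert np.array_equal(
            case.input_stack[2], case.groove_mask.astype(np.float32)
        )

    def test_local_size_must_be_smaller(self):
        with pytest.raises(ValueError):
            generate_case(1, image_size=32, local_size=32)

    def test_defect_area_matches_analytic_fraction(self):
        """Defect pixel fraction ~ analytic area fraction above the margin."""
        seed, margin = 3, 0.5
        case = generate_case(seed, image_size=128, local_size=48,
                             margin_fraction=margin, grid_step=0.05)
        # oracle: brute-force integration of the centre crown's height field
        from crowngen.synthetic import CrownField
        rng = np.random.default_rng(seed)
        params = CrownParams(
            n_cusps=int(rng.choice([4, 5])),
            cusp_height=float(rng.uniform(1.2, 1.8)),
            groove_depth=float(rng.uniform(0.5, 0.9)),
            seed=seed,
        )
        field = CrownField(params.replace(seed=seed * 4 + 0))
        step = 0.02
        g = np.arange(-field.ax, field.ax + step, step)
        xx, yy = np.meshgrid(g, g)
        z = field.height(xx, yy)
        inside = field.footprint(xx, yy)
        z_margin = margin * z.max()
        frac_analytic = (z[inside] > z_margin).sum() / inside.sum()
        # rendered: defect pixels / centre-crown footprint pixels
        enc = case.encoding
        px = enc.origin_x + np.arange(128) * enc.mm_per_pixel
        py = enc.origin_y + np.arange(128) * enc.mm_per_pixel
        gx, gy = np.meshgrid(px, py)
        fp_pixels = field.footprint(gx, gy).sum()
        frac_rendered = case.defect_mask.sum() / fp_pixels
        assert frac_rendered == pytest.approx(frac_analytic, abs=0.02)

    def test_seed_isolation(self):
        a = generate_case(11, image_size=48, local_size=24)
        b = generate_case(12, image_size=48, local_size=24)
        c = generate_case(11, image_size=48, local_size=24)
        assert not np.array_equal(a.input_stack, b.input_stack)
        assert np.array_equal(a.input_stack, c.input_stack)
        assert np.array_equal(a.target_global, c.target_global)


class TestGenerateDataset:
    def test_deterministic_bytes_on_disk(self, tmp_path):
        def digest(root):
            h = hashlib.sha256()
            for p in sorted(root.rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        generate_dataset(4, 1, tmp_path / "a", image_size=48, local_size=24)
        generate_dataset(4, 1, tmp_path / "b", image_size=48, local_size=24)
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_split_sizes_mirror_the_design(self):
        assert split_sizes(100) == (85, 9, 6)
        assert split_sizes(1) == (1, 0, 0)
        assert sum(split_sizes(17)) == 17

    def test_single_case_all_train_with_warning(self, tmp_path):
        manifest = generate_dataset(1, 2, tmp_path, image_size=48, local_size=24)
        assert manifest["split_sizes"] == {"train": 1, "val": 0, "test": 0}
        assert manifest["warnings"]
        on_disk = json.loads((tmp_path / "manifest.json").read_text())
        assert on_disk["cases"][0]["split"] == "train"

    def test_manifest_channels_exist(self, tmp_path):
        manifest = generate_dataset(2, 3, tmp_path, image_size=48, local_size=24)
        for entry in manifest["cases"]:
            for rel in entry["channels"].values():
                assert (tmp_path / rel).exists()
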