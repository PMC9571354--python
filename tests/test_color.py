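"""Color correction and Beer-Lambert deconvolution contracts."""

import numpy as np
import pytest

from cishquant.color import (
    DEFAULT_BASIS,
    DyeBasis,
    build_od_matrix,
    color_correct,
    deconvolve,
    estimate_basis,
    nuclei_channel_image,
    synthesize_rgb,
)
from cishquant.synthetic import SceneSpec, generate_scene, render_scene

# a mild stain/scanner drift of the reference: primaries move by a few gray
# levels and the transfer keeps an in-gamut image in gamut (no clipping)
SHIFTED_BASIS = DyeBasis(
    p_nuclei=(82.0, 74.0, 152.0),
    p_cep17=(186.0, 70.0, 128.0),
    p_her2=(39.0, 40.0, 41.0),
    io=(242.0, 244.0, 246.0),
)


class TestDyeBasis:
    def test_rejects_out_of_range_components(self):
        with pytest.raises(ValueError):
            DyeBasis(p_nuclei=(0.0, 80.0, 160.0), p_cep17=(180.0, 60.0, 140.0), p_her2=(40.0, 40.0, 40.0))

    def test_rejects_singular_primaries(self):
        with pytest.raises(ValueError):
            DyeBasis(p_nuclei=(100.0, 100.0, 100.0), p_cep17=(100.0, 100.0, 100.0), p_her2=(40.0, 40.0, 40.0))

    def test_yaml_round_trip(self, tmp_path):
        DEFAULT_BASIS.to_yaml(tmp_path / "b.yaml")
        assert DyeBasis.from_yaml(tmp_path / "b.yaml") == DEFAULT_BASIS


class TestEstimateBasis:
    def test_constant_regions_recovered_exactly(self):
        img = np.zeros((4, 8, 3))
        img[:, :2] = (70, 80, 160)
        img[:, 2:4] = (180, 60, 140)
        img[:, 4:6] = (40, 40, 40)
        img[:, 6:] = (245, 245, 245)
        cols = np.arange(8)[None, :].repeat(4, axis=0)
        basis = estimate_basis(img, cols < 2, (cols >= 2) & (cols < 4), (cols >= 4) & (cols < 6), cols >= 6)
        assert basis == DEFAULT_BASIS

    def test_rendered_dye_patches_recovered_within_two_gray_levels(self):
        # one pure patch per dye rendered through the forward model, with a
        # 1-px anti-aliased rim included in each mask (as ground-truth masks
        # would include it), then quantised to 8 bits
        from cishquant.synthetic import _disk_density

        dens = np.zeros((128, 128, 3))
        masks = []
        for d, center in enumerate([(32, 32), (32, 96), (96, 32)]):
            patch = _disk_density((128, 128), center, 24.0)
            dens[..., d] += patch
            masks.append(patch >= 0.5)
        od = build_od_matrix(DEFAULT_BASIS)
        img = np.clip(np.rint(synthesize_rgb(dens, od, DEFAULT_BASIS.io)), 0, 255).astype(np.uint8)
        est = estimate_basis(img, masks[0], masks[1], masks[2], None)
        for got_vec, want_vec in [
            (est.p_nuclei, DEFAULT_BASIS.p_nuclei),
            (est.p_cep17, DEFAULT_BASIS.p_cep17),
            (est.p_her2, DEFAULT_BASIS.p_her2),
            (est.io, DEFAULT_BASIS.io),
        ]:
            for got, want in zip(got_vec, want_vec):
                assert abs(got - want) <= 2.0

    def test_identical_masks_for_two_dyes_rejected(self):
        img = np.zeros((4, 8, 3))
        img[:, :4] = (70, 80, 160)
        img[:, 4:] = (245, 245, 245)
        cols = np.arange(8)[None, :].repeat(4, axis=0)
        same = cols < 4
        with pytest.raises(ValueError):
            estimate_basis(img, same, same, cols >= 4, cols >= 4)

    def test_empty_mask_rejected(self):
        img = np.full((4, 4, 3), 100.0)
        some = np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="empty"):
            estimate_basis(img, np.zeros((4, 4), bool), some, some, some)


class TestColorCorrect:
    def test_identity_when_reference_equals_input(self, clean_scene):
        _, image, _ = clean_scene
        out = color_correct(image, DEFAULT_BASIS, DEFAULT_BASIS)
        assert np.max(np.abs(out.astype(int) - image.astype(int))) <= 1

    def test_input_primary_maps_to_reference_primary(self):
        img = np.array(DEFAULT_BASIS.p_nuclei, dtype=float).reshape(1, 1, 3)
        out = color_correct(img, DEFAULT_BASIS, SHIFTED_BASIS)
        assert out[0, 0] == pytest.approx(SHIFTED_BASIS.p_nuclei, abs=1e-9)

    def test_round_trip_within_one_gray_level(self, clean_scene):
        _, image, _ = clean_scene
        there = color_correct(image, DEFAULT_BASIS, SHIFTED_BASIS)
        back = color_correct(there, SHIFTED_BASIS, DEFAULT_BASIS)
        assert np.max(np.abs(back.astype(int) - image.astype(int))) <= 1

    def test_linear_before_clipping(self):
        # pixels built inside the dye gamut so no clipping is triggered
        rng = np.random.default_rng(4)
        P = DEFAULT_BASIS.primary_matrix()
        a = (rng.uniform(0, 0.4, (5, 5, 3)) @ P.T)
        b = (rng.uniform(0, 0.4, (5, 5, 3)) @ P.T)
        lam = 0.3
        mix = color_correct(lam * a + (1 - lam) * b, DEFAULT_BASIS, SHIFTED_BASIS)
        parts = lam * color_correct(a, DEFAULT_BASIS, SHIFTED_BASIS) + (1 - lam) * color_correct(
            b, DEFAULT_BASIS, SHIFTED_BASIS
        )
        assert mix == pytest.approx(parts, abs=1e-9)


class TestOdMatrix:
    def test_dye_equal_to_glass_gives_zero_row(self):
        basis = DyeBasis(
            p_nuclei=(70.0, 80.0, 160.0),
            p_cep17=(180.0, 60.0, 140.0),
            p_her2=(245.0, 245.0, 245.0),
            io=(245.0, 245.0, 245.0),
        )
        od = build_od_matrix(basis)
        assert od.m[2] == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_direct_log_ratio(self):
        basis = DyeBasis(
            p_nuclei=(100.0, 200.0, 200.0),
            p_cep17=(200.0, 100.0, 200.0),
            p_her2=(200.0, 200.0, 100.0),
            io=(200.0, 200.0, 200.0),
        )
        od = build_od_matrix(basis)
        assert od.m[0] == pytest.approx((np.log(2), 0.0, 0.0), abs=1e-12)

    def test_halving_a_channel_adds_log_two(self):
        b1 = DyeBasis(p_nuclei=(120.0, 80.0, 160.0), p_cep17=(180.0, 60.0, 140.0), p_her2=(40.0, 40.0, 40.0))
        b2 = DyeBasis(p_nuclei=(60.0, 80.0, 160.0), p_cep17=(180.0, 60.0, 140.0), p_her2=(40.0, 40.0, 40.0))
        m1, m2 = build_od_matrix(b1).m, build_od_matrix(b2).m
        assert m2[0, 0] - m1[0, 0] == pytest.approx(np.log(2), abs=1e-12)

    def test_dye_brighter_than_glass_names_entries(self):
        basis = DyeBasis.__new__(DyeBasis)
        object.__setattr__(basis, "p_nuclei", (70.0, 80.0, 160.0))
        object.__setattr__(basis, "p_cep17", (250.0, 60.0, 140.0))
        object.__setattr__(basis, "p_her2", (40.0, 40.0, 40.0))
        object.__setattr__(basis, "io", (245.0, 245.0, 245.0))
        with pytest.raises(ValueError, match="cep17/R"):
            build_od_matrix(basis)


class TestDeconvolve:
    def test_glass_pixel_has_zero_density(self):
        od = build_od_matrix(DEFAULT_BASIS)
        img = np.array(DEFAULT_BASIS.io, dtype=float).reshape(1, 1, 3)
        ch = deconvolve(img, od, DEFAULT_BASIS.io)
        assert ch.stack() == pytest.approx(np.zeros((1, 1, 3)), abs=1e-12)

    def test_forward_model_round_trip_to_1e6(self):
        rng = np.random.default_rng(9)
        od = build_od_matrix(DEFAULT_BASIS)
        dens = rng.uniform(0.0, 1.5, (16, 16, 3))
        img = synthesize_rgb(dens, od, DEFAULT_BASIS.io)
        rec = deconvolve(img, od, DEFAULT_BASIS.io, intensity_floor=1e-9).stack()
        assert np.max(np.abs(rec - dens)) / np.max(dens) < 1e-6

    def test_clean_scene_round_trip_to_1e6(self, clean_scene):
        spec, _, _ = clean_scene
        image, dens, _ = render_scene(spec)
        od = build_od_matrix(spec.dye_basis)
        rec = deconvolve(image, od, spec.dye_basis.io, intensity_floor=1e-9).stack()
        assert np.max(np.abs(rec - dens)) / np.max(dens) < 1e-6

    def test_pure_nucleus_pixel_has_little_cross_talk(self, clean_scene):
        spec, _, _ = clean_scene
        image, dens, gt = render_scene(spec)
        od = build_od_matrix(spec.dye_basis)
        ch = deconvolve(image, od, spec.dye_basis.io, intensity_floor=1e-9)
        pure = (dens[..., 0] >= 0.999) & (dens[..., 1] == 0) & (dens[..., 2] == 0)
        assert pure.any()
        assert np.max(ch.a_cep17[pure]) < 0.01 * np.mean(ch.a_nuclei[pure])
        assert np.max(ch.a_her2[pure]) < 0.01 * np.mean(ch.a_nuclei[pure])

    def test_correction_then_reference_deconvolution_matches_native(self, clean_scene):
        spec, _, _ = clean_scene
        from dataclasses import replace

        shifted_spec = replace(spec, dye_basis=SHIFTED_BASIS)
        image, dens, _ = render_scene(shifted_spec)
        native = deconvolve(image, build_od_matrix(SHIFTED_BASIS), SHIFTED_BASIS.io, intensity_floor=1e-9)
        corrected = color_correct(image, SHIFTED_BASIS, DEFAULT_BASIS)
        via_ref = deconvolve(
            corrected, build_od_matrix(DEFAULT_BASIS), DEFAULT_BASIS.io, intensity_floor=1e-9
        )
        # agreement within a small density tolerance on tissue pixels
        diff = np.abs(via_ref.a_nuclei - native.a_nuclei)
        assert np.quantile(diff, 0.99) < 0.15
        assert np.mean(diff) < 0.03


class TestNucleiChannel:
    def test_all_glass_tile_is_zero(self):
        od = build_od_matrix(DEFAULT_BASIS)
        img = np.tile(np.array(DEFAULT_BASIS.io), (8, 8, 1))
        ch = deconvolve(img, od, DEFAULT_BASIS.io)
        assert (nuclei_channel_image(ch) == 0).all()

    def test_fixed_ceiling_keeps_tiles_comparable(self, clean_scene):
        spec, _, _ = clean_scene
        image, dens, _ = render_scene(spec)
        od = build_od_matrix(spec.dye_basis)
        ch = deconvolve(image, od, spec.dye_basis.io, intensity_floor=1e-9)
        out = nuclei_channel_image(ch, ceiling=2.0)
        # same density -> same value regardless of the rest of the tile
        sub = nuclei_channel_image(
            deconvolve(image[:64, :64], od, spec.dye_basis.io, intensity_floor=1e-9), ceiling=2.0
        )
        assert np.array_equal(out[:64, :64], sub)
        assert out.min() >= 0 and out.max() <= 1
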