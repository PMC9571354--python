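"""Quality gate: grayscale, white check, blurriness, noise, model fit, assess."""

import warnings

import numpy as np
import pytest

from cishquant.quality import (
    NoEdgeWarning,
    QualityModel,
    assess,
    blurriness,
    fit_quality_model,
    noise_index,
    to_grayscale,
    white_fraction,
)
from cishquant.synthetic import SceneSpec, degrade, generate_scene


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255.0), ((255, 0, 0), 76.245), ((0, 0, 0), 0.0)],
    )
    def test_luma_coefficients(self, rgb, expected):
        img = np.full((2, 2, 3), rgb, dtype=np.uint8)
        assert to_grayscale(img) == pytest.approx(np.full((2, 2), expected))

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4)))


class TestWhiteFraction:
    def test_extremes_and_halves(self):
        assert white_fraction(np.full((10, 10), 255.0)) == 1.0
        half = np.zeros((10, 10))
        half[:5] = 255.0
        assert white_fraction(half) == 0.5

    def test_boundary_value_200_counts_as_white(self):
        img = np.zeros((10, 10))
        img[0, 0] = 200.0
        assert white_fraction(img) == pytest.approx(0.01)

    def test_invariant_to_pixel_permutation(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (20, 20))
        shuffled = rng.permutation(img.ravel()).reshape(20, 20)
        assert white_fraction(img) == white_fraction(shuffled)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            white_fraction(np.zeros((0, 0)))


def _brute_force_widths(profile, threshold):
    """Independent oracle: exhaustive local-extrema scan of one profile."""
    widths = []
    p = list(profile)
    for i in range(len(p) - 1):
        g = p[i + 1] - p[i]
        if abs(g) <= threshold:
            continue
        s = 1 if g > 0 else -1
        left = i
        while left > 0 and s * (p[left] - p[left - 1]) > 0:
            left -= 1
        right = i + 1
        while right < len(p) - 1 and s * (p[right + 1] - p[right]) > 0:
            right += 1
        widths.append(right - left)
    return widths


class TestBlurriness:
    def test_constant_image_has_no_edges(self):
        with pytest.warns(NoEdgeWarning):
            assert blurriness(np.full((8, 8), 40.0)) == 0.0

    def test_ideal_step_has_width_one(self):
        profile = np.array([0, 0, 0, 255, 255, 255], dtype=float)
        img = np.tile(profile, (6, 1))
        assert _brute_force_widths(profile, 20) == [1]
        # horizontal scans see width-1 edges; vertical scans see none
        assert blurriness(img) == pytest.approx(1.0)

    def test_blur_increases_edge_width(self):
        profile = np.array([0, 0, 0, 0, 255, 255, 255, 255], dtype=float)
        blurred = np.convolve(profile, np.ones(3) / 3, mode="same")
        sharp_w = np.mean(_brute_force_widths(profile, 20))
        blurred_w = np.mean(_brute_force_widths(blurred, 20))
        assert blurred_w > sharp_w
        img, bimg = np.tile(profile, (6, 1)), np.tile(blurred, (6, 1))
        assert blurriness(bimg) > blurriness(img)
        assert blurriness(img) == pytest.approx(sharp_w)
        assert blurriness(bimg) == pytest.approx(blurred_w)

    def test_invariant_to_intensity_offset(self):
        img, _ = generate_scene(SceneSpec(seed=3))
        gray = to_grayscale(img)
        assert blurriness(gray + 30.0) == pytest.approx(blurriness(gray))


class TestNoiseIndex:
    def test_constant_image_is_zero(self):
        assert noise_index(np.full((8, 8), 7.0)) == 0.0

    def test_isolated_hot_pixel_matches_brute_force(self):
        img = np.zeros((10, 10))
        img[5, 5] = 255.0
        # independent evaluation: unsharp-mask outliers, minus pixels on an
        # edge of the smoothed image, then squared minimum 3x3 difference
        from scipy.ndimage import uniform_filter

        sm = uniform_filter(img, 3, mode="nearest")
        hp = img - sm
        gy, gx = np.gradient(sm)
        cand = (np.abs(hp) > hp.std()) & ~(np.hypot(gy, gx) > 10.0)
        cand[0, :] = cand[-1, :] = cand[:, 0] = cand[:, -1] = False
        dmins = []
        for r in range(1, 9):
            for c in range(1, 9):
                if not cand[r, c]:
                    continue
                diffs = [
                    abs(img[r, c] - img[r + dr, c + dc])
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (dr, dc) != (0, 0)
                ]
                dmins.append(min(diffs) ** 2)
        expected = np.mean(dmins)
        assert dmins.count(255.0**2) == 1  # the hot pixel itself survives
        assert noise_index(img) == pytest.approx(expected)
        assert noise_index(img) == pytest.approx(255.0**2)

    def test_monotone_in_added_noise(self):
        from cishquant.workflows import QUALITY_SCENE

        from dataclasses import replace

        img, _ = generate_scene(replace(QUALITY_SCENE, seed=5))
        gray = to_grayscale(img)
        means = []
        for sd in [0.0, 2.0, 5.0, 10.0]:
            vals = [noise_index(degrade(gray, 0.0, sd, seed=s)) for s in range(10)]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            noise_index(np.zeros((2, 5)))


@pytest.fixture(scope="module")
def originals():
    from dataclasses import replace

    from cishquant.workflows import QUALITY_SCENE

    grays = []
    for i in range(4):
        img, _ = generate_scene(replace(QUALITY_SCENE, seed=20 + i))
        grays.append(to_grayscale(img))
    return grays


@pytest.fixture(scope="module")
def fitted_model():
    from cishquant.workflows import fit_quality_protocol

    return fit_quality_protocol(n_scenes=4, seed=2)


class TestFitQualityModel:

    def test_identity_degradations_give_zero_model(self, originals):
        model = fit_quality_model(originals, [(0.0, 0.0), (0.0, 0.0)], seed=0)
        assert model.alpha == pytest.approx(0.0, abs=1e-9)
        assert model.beta == pytest.approx(0.0, abs=1e-9)
        assert model.gamma == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear_responses_recovered(self, originals):
        grid = [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0), (0.0, 5.0), (0.0, 10.0), (1.5, 7.0)]
        responses = []
        for j, gray in enumerate(originals):
            for k, (bs, ns) in enumerate(grid):
                deg = degrade(gray, bs, ns, seed=7919 * j + k)
                responses.append(
                    2.0 + 3.0 * blurriness(deg, 20.0) + 5.0 * noise_index(deg, 20.0)
                )
        model = fit_quality_model(originals, grid, seed=0, responses=responses)
        assert model.alpha == pytest.approx(2.0, abs=1e-8)
        assert model.beta == pytest.approx(3.0, abs=1e-8)
        assert model.gamma == pytest.approx(5.0, abs=1e-8)

    def test_fit_tracks_true_mse(self, originals):
        from cishquant.workflows import QUALITY_EDGE_THRESHOLD, QUALITY_GRID

        model = fit_quality_model(
            originals, QUALITY_GRID, seed=1, edge_gradient_threshold=QUALITY_EDGE_THRESHOLD
        )
        assert model.beta > 0 and model.gamma > 0
        assert model.r_squared > 0.64  # r > 0.8
        # Q rises monotonically along a fresh degradation ladder
        gray = originals[0]
        qs = []
        th = model.edge_gradient_threshold
        for bs, ns in [(0.0, 0.0), (0.7, 4.0), (1.4, 8.0), (2.0, 12.0)]:
            deg = degrade(gray, bs, ns, seed=99)
            qs.append(model.q_index(blurriness(deg, th), noise_index(deg, th)))
        assert all(a < b for a, b in zip(qs, qs[1:]))

    def test_single_level_rejected(self, originals):
        with pytest.raises(ValueError):
            fit_quality_model(originals, [(1.0, 1.0)])


class TestAssess:

    def test_all_white_tile_rejected_without_quality_check(self, fitted_model):
        white = np.full((64, 64, 3), 255, dtype=np.uint8)
        report = assess(white, fitted_model)
        assert not report.tissue_ok and not report.quality_ok
        assert np.isnan(report.q_index)

    def test_clean_scene_passes_with_qth_above_its_q(self, fitted_model):
        from dataclasses import replace as dc_replace

        from cishquant.workflows import QUALITY_SCENE

        img, _ = generate_scene(dc_replace(QUALITY_SCENE, seed=33))
        report = assess(img, fitted_model)
        assert report.tissue_ok
        assert report.q_index <= fitted_model.qth * 1.5  # in the clean band
        # with Qth set above this scene's Q, both flags are true
        m2 = dc_replace(fitted_model, qth=report.q_index + 1.0)
        report2 = assess(img, m2)
        assert report2.tissue_ok and report2.quality_ok

    def test_degraded_scene_fails_quality(self, fitted_model):
        from dataclasses import replace as dc_replace

        from cishquant.workflows import QUALITY_SCENE

        img, _ = generate_scene(dc_replace(QUALITY_SCENE, seed=33))
        bad = degrade(img, 4.0, 25.0, seed=0)
        report = assess(bad, fitted_model)
        assert report.tissue_ok
        assert not report.quality_ok
        assert report.q_index > fitted_model.qth

    def test_model_round_trips_through_json(self, fitted_model, tmp_path):
        fitted_model.save(tmp_path / "m.json")
        loaded = QualityModel.load(tmp_path / "m.json")
        assert loaded == fitted_model
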