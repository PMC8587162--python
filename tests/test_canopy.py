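"""Gap-fraction analysis and the canopy-architecture equation engine."""

import numpy as np
import pandas as pd
import pytest

from vinemetrics import canopy, synthetic
from vinemetrics.canopy import (
    BinarizationMethod,
    CanopyImage,
    analyze_canopy_image,
    binarize_canopy,
    classify_gaps,
    clumping_index,
    compute_metrics,
    crown_porosity,
    lai_from_porosity,
    metrics_from_cover_fractions,
)

# published group-mean rows (lai, fc, ff, phi, omega) used as an arithmetic oracle
GROUP_MEANS = {
    "chardonnay_g1": (2.13, 0.67, 0.80, 0.16, 0.75),
    "chardonnay_g2": (1.99, 0.64, 0.78, 0.18, 0.76),
    "chardonnay_g3": (1.93, 0.66, 0.81, 0.19, 0.80),
    "shiraz_g1": (1.27, 0.49, 0.67, 0.28, 0.78),
    "shiraz_g2": (1.61, 0.57, 0.72, 0.21, 0.75),
    "shiraz_g3": (2.00, 0.68, 0.84, 0.19, 0.82),
}


def _image(arr):
    return CanopyImage(pixels=arr)


def test_all_white_image_is_all_sky():
    img = _image(np.full((64, 64, 3), 255, dtype=np.uint8))
    gm = binarize_canopy(img)
    assert gm.gap_fraction == 1.0
    assert gm.warnings  # degenerate, flagged not raised


def test_all_black_image_is_all_canopy():
    img = _image(np.zeros((64, 64, 3), dtype=np.uint8))
    gm = binarize_canopy(img)
    assert gm.gap_fraction == 0.0
    assert gm.warnings


def test_half_sky_scene_recovers_half_gap_fraction():
    arr = np.zeros((64, 64, 3), dtype=np.uint8)
    arr[:, 32:] = 255  # right half sky
    gm = binarize_canopy(_image(arr))
    assert gm.gap_fraction == pytest.approx(0.50, abs=0.01)


def test_fixed_threshold_requires_value():
    img = _image(np.zeros((64, 64, 3), dtype=np.uint8))
    with pytest.raises(ValueError):
        binarize_canopy(img, method=BinarizationMethod.fixed)


def test_binarization_thresholds_blue_channel():
    arr = np.zeros((64, 64, 3), dtype=np.uint8)
    arr[:, :32, 2] = 250  # blue-bright half = sky; red/green stay dark
    arr[:, 32:, 0] = 250  # red-bright half must not read as sky
    gm = binarize_canopy(_image(arr), method="fixed", fixed_threshold=128)
    assert gm.sky_mask[:, :32].all() and not gm.sky_mask[:, 32:].any()


class TestClassifyGaps:
    def test_single_dominant_gap_is_large(self):
        arr = np.zeros((100, 100, 3), dtype=np.uint8)
        arr[:40, :, 2] = 255  # 40% of the frame
        gm = classify_gaps(binarize_canopy(_image(arr), "fixed", 128), 0.10)
        assert [c.label for c in gm.components] == ["large"]

    def test_isolated_pixels_are_small(self):
        arr = np.zeros((256, 256, 3), dtype=np.uint8)
        rows, cols = np.mgrid[4:256:24, 4:256:24]
        arr[rows.ravel()[:100], cols.ravel()[:100], 2] = 255
        gm = classify_gaps(binarize_canopy(_image(arr), "fixed", 128), 0.01)
        assert len(gm.components) == 100
        assert all(c.label == "small" for c in gm.components)

    def test_generated_scene_has_expected_large_gap_count(self):
        arr = np.zeros((200, 200, 3), dtype=np.uint8)
        arr[10:50, 10:90, 2] = 255   # 8% gap
        arr[120:160, 100:180, 2] = 255  # 8% gap
        rng = np.random.default_rng(0)
        speck = rng.choice(200 * 200, size=60, replace=False)  # speckle < 0.5%
        mask = np.zeros(200 * 200, dtype=bool)
        mask[speck] = True
        arr[..., 2][mask.reshape(200, 200) & (arr[..., 2] == 0)] = 255
        gm = classify_gaps(binarize_canopy(_image(arr), "fixed", 128), 0.01)
        assert sum(c.label == "large" for c in gm.components) == 2

    def test_component_counts_sum_to_sky_pixels(self, canopy_scene):
        img, _ = canopy_scene
        gm = classify_gaps(binarize_canopy(img), 0.01)
        assert sum(c.pixel_count for c in gm.components) == int(gm.sky_mask.sum())

    def test_threshold_bounds(self, canopy_scene):
        img, _ = canopy_scene
        gm = binarize_canopy(img)
        with pytest.raises(ValueError):
            classify_gaps(gm, 0.0)


class TestEquationEngine:
    @pytest.mark.parametrize("row", GROUP_MEANS.values(), ids=GROUP_MEANS.keys())
    def test_porosity_identity_matches_published_means(self, row):
        """1 - fc/ff reproduces the published porosity within one printed ulp."""
        _, fc, ff, phi, _ = row
        assert round(crown_porosity(fc, ff), 2) == pytest.approx(phi, abs=0.0101)

    @pytest.mark.parametrize("key", ["shiraz_g3", "chardonnay_g3"])
    def test_lai_equation_matches_published_means(self, key):
        lai, _, ff, phi, _ = GROUP_MEANS[key]
        assert lai_from_porosity(ff, phi, k=0.7) == pytest.approx(lai, abs=0.02)

    @pytest.mark.parametrize("key", ["shiraz_g1", "shiraz_g3", "chardonnay_g1"])
    def test_clumping_equation_matches_published_means(self, key):
        _, fc, _, phi, omega = GROUP_MEANS[key]
        assert clumping_index(fc, phi) == pytest.approx(omega, abs=0.02)

    def test_porosity_identity_exact(self, rng):
        for _ in range(50):
            ff = rng.uniform(0.2, 1.0)
            phi = rng.uniform(0.01, 0.9)
            m = metrics_from_cover_fractions(fc=ff * (1 - phi), ff=ff)
            assert m.phi == pytest.approx(1 - m.fc / m.ff, abs=1e-9)
            assert m.lai_e == pytest.approx(m.omega * m.lai, abs=1e-9)

    def test_lai_monotone_decreasing_in_porosity(self):
        lais = [lai_from_porosity(0.8, phi) for phi in np.linspace(0.05, 0.9, 20)]
        assert all(a >= b for a, b in zip(lais, lais[1:]))

    def test_lai_proportional_to_crown_cover(self):
        assert lai_from_porosity(0.8, 0.2) == pytest.approx(2 * lai_from_porosity(0.4, 0.2))


class TestComputeMetrics:
    def _gapmap(self, total, sky_large, sky_small):
        """GapMap with exact pixel bookkeeping, bypassing rendering."""
        side = int(np.sqrt(total))
        assert side * side == total
        mask = np.zeros(total, dtype=bool)
        mask[:sky_large + sky_small] = True
        comps = []
        if sky_large:
            comps.append(canopy.GapComponent(1, sky_large, "large"))
        if sky_small:
            comps.append(canopy.GapComponent(2, sky_small, "small"))
        return canopy.GapMap(sky_mask=mask.reshape(side, side), total_pixels=total,
                             components=comps, large_gap_threshold=0.01)

    def test_fractions_from_pixel_counts(self):
        # fc = 0.68, ff = 0.84 in exact pixels
        gm = self._gapmap(10000, sky_large=1600, sky_small=1600)
        m = compute_metrics(gm, k=0.7)
        assert m.fc == pytest.approx(0.68)
        assert m.ff == pytest.approx(0.84)
        assert round(m.phi, 2) == 0.19

    def test_no_small_gaps_clamps_porosity(self):
        gm = self._gapmap(10000, sky_large=1600, sky_small=0)
        m = compute_metrics(gm)
        assert m.fc == pytest.approx(m.ff)
        assert m.phi == pytest.approx(canopy.PHI_CLAMP[0])
        assert m.warnings

    def test_all_large_gap_degenerate(self):
        gm = self._gapmap(10000, sky_large=10000, sky_small=0)
        with pytest.warns(UserWarning):
            m = compute_metrics(gm)
        assert m.fc == 0.0 and m.ff == 0.0 and m.lai == 0.0


class TestEndToEnd:
    def test_recovers_generator_ground_truth(self, canopy_scene):
        img, truth = canopy_scene
        m = analyze_canopy_image(img)
        assert m.ff == pytest.approx(truth.params["ff"], abs=0.02)
        assert m.phi == pytest.approx(truth.params["phi"], abs=0.03)

    def test_gap_fraction_equals_brute_force_count(self, canopy_scene):
        img, _ = canopy_scene
        gm = classify_gaps(binarize_canopy(img), 0.01)
        brute = np.count_nonzero(gm.sky_mask) / gm.sky_mask.size
        m = compute_metrics(gm)
        assert 1 - m.fc == pytest.approx(brute, abs=1e-12)

    def test_all_canopy_image(self):
        img = _image(np.zeros((64, 64, 3), dtype=np.uint8))
        m = analyze_canopy_image(img)
        assert m.fc == 1.0 and m.ff == 1.0
        assert np.isfinite(m.lai) and m.lai > 5
        assert m.warnings

    def test_all_sky_image(self):
        img = _image(np.full((64, 64, 3), 255, dtype=np.uint8))
        with pytest.warns(UserWarning):
            m = analyze_canopy_image(img)
        assert m.fc == 0.0 and m.lai == 0.0


def test_manifest_batch_averages_sides(tmp_path):
    import imageio.v3 as iio

    paths = []
    for i, (ff, phi) in enumerate([(0.8, 0.2), (0.7, 0.25)]):
        img, _ = synthetic.make_canopy_scene(ff, phi, rng_seed=20 + i)
        p = tmp_path / f"side{i}.png"
        iio.imwrite(p, img.pixels)
        paths.append(p)
    manifest = pd.DataFrame({
        "source_id": ["a", "b"], "path": [str(p) for p in paths],
        "plant_id": ["v1", "v1"], "side": ["east", "west"],
    })
    out = canopy.analyze_manifest(manifest)
    imgs = out[out.level == "image"]
    plant = out[out.level == "plant"].iloc[0]
    assert len(imgs) == 2
    assert plant.ff == pytest.approx(imgs.ff.mean())
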