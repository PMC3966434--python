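import numpy as np
import pytest

from symseg.config import PipelineConfig
from symseg.errors import ParameterError
from symseg.metrics import dice, region_report
from symseg.pipelines import (
    ehasa_mask,
    ehasa_threshold,
    localize_high_intensity,
    map_mask,
    run_chanvese_baseline,
    run_ehasa,
    run_hasa,
)
from symseg.symmetry import DifferenceImage, difference_image, reflect


def _diff_from(rectified):
    rect = np.asarray(rectified, dtype=float)
    return DifferenceImage(signed=rect.copy(), rectified=rect)


def _flood_components(mask):
    """8-connected components by explicit flood fill (oracle)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < mask.shape[0]
                                and 0 <= cc < mask.shape[1]
                                and mask[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


class TestLocalizeHighIntensity:
    def test_zero_field_gives_empty_list(self):
        assert localize_high_intensity(_diff_from(np.zeros((16, 16)))) == []

    def test_below_noise_floor_gives_empty_list(self):
        rect = np.zeros((16, 16))
        rect[4, 4] = 0.04
        assert localize_high_intensity(_diff_from(rect), noise_floor=0.05) == []

    def test_two_blobs_sorted_by_mass_matches_floodfill_oracle(self):
        rect = np.zeros((32, 32))
        rect[2:12, 2:7] = 0.6  # 50 px
        rect[20:24, 20:25] = 0.6  # 20 px
        seeds = localize_high_intensity(_diff_from(rect), frac=0.5, min_area=5)
        oracle = sorted(_flood_components(rect > 0.3), key=len, reverse=True)
        assert len(seeds) == len(oracle) == 2
        assert seeds[0].area_px == 50 and seeds[1].area_px == 20
        assert seeds[0].mass > seeds[1].mass
        assert seeds[0].centroid == pytest.approx(
            tuple(np.mean(oracle[0], axis=0)), abs=1e-12
        )

    def test_small_blob_filtered_by_min_area(self):
        rect = np.zeros((16, 16))
        rect[5, 5:8] = 1.0  # 3 px
        assert localize_high_intensity(_diff_from(rect), min_area=10) == []

    def test_bad_frac_rejected(self):
        with pytest.raises(ParameterError):
            localize_high_intensity(_diff_from(np.ones((8, 8))), frac=1.5)


class TestEhasaThreshold:
    def test_quarter_of_unit_maximum(self):
        image = np.zeros((8, 8))
        image[3, 3] = 1.0
        assert ehasa_threshold(image) == pytest.approx(0.25)

    def test_zero_image_gives_zero(self):
        assert ehasa_threshold(np.zeros((8, 8))) == 0.0

    def test_fraction_scales_with_max(self):
        image = np.full((8, 8), 0.1)
        image[0, 0] = 0.8
        assert ehasa_threshold(image, 0.25) == pytest.approx(0.2)


class TestEhasaMask:
    def test_zero_field_gives_empty_mask(self):
        assert not ehasa_mask(_diff_from(np.zeros((8, 8))), 0.1).any()

    def test_pixel_count_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            rect = rng.uniform(size=(16, 16))
            t = float(rng.uniform(0.2, 0.8))
            mask = ehasa_mask(_diff_from(rect), t)
            oracle = sum(1 for v in rect.ravel() if v > t)
            assert int(mask.sum()) == oracle

    def test_zero_threshold_on_positive_field_is_all_true(self):
        assert ehasa_mask(_diff_from(np.full((8, 8), 0.3)), 0.0).all()

    def test_raising_threshold_never_adds_pixels(self):
        rng = np.random.default_rng(18)
        rect = rng.uniform(size=(16, 16))
        lo = ehasa_mask(_diff_from(rect), 0.3)
        hi = ehasa_mask(_diff_from(rect), 0.5)
        assert not (hi & ~lo).any()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ParameterError):
            ehasa_mask(_diff_from(np.zeros((8, 8))), -0.1)


class TestMapMask:
    def test_identity_and_annihilator(self):
        rng = np.random.default_rng(19)
        image = rng.uniform(size=(8, 8))
        np.testing.assert_array_equal(map_mask(np.ones((8, 8), bool), image), image)
        assert map_mask(np.zeros((8, 8), bool), image).sum() == 0.0

    def test_matches_elementwise_product_oracle(self):
        rng = np.random.default_rng(20)
        image = rng.uniform(size=(8, 8))
        mask = rng.uniform(size=(8, 8)) > 0.5
        out = map_mask(mask, image)
        for i in range(8):
            for j in range(8):
                assert out[i, j] == (image[i, j] if mask[i, j] else 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            map_mask(np.ones((8, 9), bool), np.zeros((8, 8)))


class TestPipelinesOnPhantoms:
    def test_symmetric_phantom_gives_empty_masks(self, runs):
        for method in ("hasa", "ehasa"):
            result = runs[(method, "symmetric")]
            assert result.n_regions == 0
            assert not result.mask.any()

    @pytest.mark.parametrize("method", ["hasa", "ehasa"])
    @pytest.mark.parametrize("name", ["left-lesion", "right-lesion"])
    def test_single_lesion_recovered(self, runs, phantoms, method, name):
        result = runs[(method, name)]
        _, truth = phantoms[name]
        assert result.n_regions == 1
        assert dice(result.mask, truth) >= 0.85

    @pytest.mark.parametrize("method", ["hasa", "ehasa"])
    def test_two_lesions_found_one_region_each(self, runs, phantoms, method):
        result = runs[(method, "bilateral-two-lesions")]
        _, truth = phantoms["bilateral-two-lesions"]
        report = region_report(result, truth)
        assert result.n_regions == 2
        assert report["truth_lesions_hit"] == 2
        assert report["false_regions"] == 0

    @pytest.mark.parametrize("method", ["hasa", "ehasa"])
    def test_midline_lesion_is_the_documented_failure(self, runs, phantoms, method):
        result = runs[(method, "midline-lesion")]
        _, truth = phantoms["midline-lesion"]
        assert dice(result.mask, truth) < 0.2

    def test_laterality_equivariance_is_pixel_exact(self, runs):
        for method in ("hasa", "ehasa"):
            left = runs[(method, "left-lesion")].mask
            right = runs[(method, "right-lesion")].mask
            np.testing.assert_array_equal(right, left[:, ::-1])

    def test_ehasa_no_worse_than_hasa_on_artifact_phantom(self, runs, phantoms):
        _, truth = phantoms["lesion-plus-artifact"]
        hasa_false = region_report(runs[("hasa", "lesion-plus-artifact")], truth)["false_regions"]
        ehasa_false = region_report(runs[("ehasa", "lesion-plus-artifact")], truth)["false_regions"]
        assert ehasa_false <= hasa_false

    def test_ehasa_threshold_stage_suppresses_the_artifact(self, phantoms, suite):
        # the artifact is clearly present in the rectified difference but is
        # cut by the 25%-of-max binarization before the contour runs
        image, _ = phantoms["lesion-plus-artifact"]
        result = run_ehasa(image, PipelineConfig())
        art_row, art_col = suite["lesion-plus-artifact"].artifacts[0].center
        r, c = int(art_row), int(art_col)
        assert result.intermediates["difference_rectified"][r - 2 : r + 3, c - 2 : c + 3].max() > 0.1
        assert not result.intermediates["binary_mask"][r - 2 : r + 3, c - 2 : c + 3].any()

    def test_baseline_segments_more_regions_than_hasa(self, runs):
        baseline = runs[("baseline", "left-lesion")]
        hasa = runs[("hasa", "left-lesion")]
        assert baseline.n_regions > hasa.n_regions

    def test_baseline_recovers_two_phase_disk(self, disk_image):
        image, truth = disk_image
        result = run_chanvese_baseline(image, PipelineConfig())
        assert dice(result.mask, truth) >= 0.98

    def test_baseline_on_constant_image_is_empty(self):
        result = run_chanvese_baseline(np.full((32, 32), 0.5), PipelineConfig())
        assert result.n_regions == 0

    def test_pipelines_are_deterministic(self, phantoms, default_config, runs):
        image, _ = phantoms["left-lesion"]
        again = run_hasa(image, default_config)
        np.testing.assert_array_equal(again.mask, runs[("hasa", "left-lesion")].mask)

    def test_result_regions_sorted_by_area_and_counted(self, runs):
        result = runs[("hasa", "bilateral-two-lesions")]
        areas = [r.area_px for r in result.regions]
        assert areas == sorted(areas, reverse=True)
        assert result.n_regions == len(result.regions)

    def test_verbose_intermediates_present(self, runs):
        hasa = runs[("hasa", "left-lesion")]
        assert {"reflection", "difference_signed", "difference_rectified"} <= set(
            hasa.intermediates
        )
        ehasa = runs[("ehasa", "left-lesion")]
        assert {"binary_mask", "mapped", "final_mask"} <= set(ehasa.intermediates)

    def test_mean_of_difference_threshold_variant_runs(self, phantoms):
        image, truth = phantoms["left-lesion"]
        result = run_ehasa(image, PipelineConfig(ehasa_use_mean=True))
        # the mean-of-D threshold is far lower, so the mask is a superset
        assert result.mask.sum() >= 0
        assert dice(result.mask, truth) > 0.0
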