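"""Tests for tissue masking, grid extraction and the geometric adapters."""

import numpy as np
import pytest

from histomil.patching import (PatchManifest, TissueMask, center_crop_resize,
                               extract_annotation_patches, extract_patches,
                               resize_for_mil, tissue_mask)


def _white(h=256, w=256):
    return np.full((h, w, 3), 255, dtype=np.uint8)


class TestTissueMask:
    def test_pure_white_gives_empty_mask(self):
        mask = tissue_mask(_white(), downsample=8)
        assert not mask.mask.any()

    def test_saturated_rectangle_recovered(self):
        img = _white(256, 256)
        img[64:192, 32:224] = (255, 0, 255)  # saturated magenta
        mask = tissue_mask(img, downsample=8, min_object_px=4, min_hole_px=4)
        full = mask.full_res((256, 256))
        expected = np.zeros((256, 256), dtype=bool)
        expected[64:192, 32:224] = True
        jac = (full & expected).sum() / (full | expected).sum()
        assert jac > 0.95

    def test_matches_generator_ground_truth(self, small_slide):
        mask = tissue_mask(small_slide.image, downsample=8,
                           min_object_px=8, min_hole_px=8)
        truth = small_slide.morphology_mask != 255
        full = mask.full_res(truth.shape)
        jac = (full & truth).sum() / (full | truth).sum()
        assert jac >= 0.9

    def test_cleanup_idempotent_on_own_output(self, small_slide):
        from skimage.morphology import (remove_small_holes,
                                        remove_small_objects)
        mask = tissue_mask(small_slide.image, downsample=8,
                           min_object_px=8, min_hole_px=8).mask
        again = remove_small_holes(remove_small_objects(mask, max_size=7),
                                   max_size=7)
        assert np.array_equal(mask, again)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            tissue_mask(np.zeros((10, 10), dtype=np.uint8))

    def test_mask_shape_is_ceil_of_slide_over_downsample(self):
        mask = tissue_mask(_white(100, 130), downsample=16)
        assert mask.mask.shape == (7, 9)


class TestExtractPatches:
    def test_full_mask_grid_arithmetic(self):
        mask = TissueMask(np.ones((64, 64), dtype=bool), downsample=16)
        man = extract_patches((1024, 1024), mask, size=512,
                              min_tissue_fraction=0.2)
        assert len(man) == 4
        assert (man.df["tissue_fraction"] == 1.0).all()
        origins = set(zip(man.df["row"], man.df["col"]))
        assert origins == {(0, 0), (0, 512), (512, 0), (512, 512)}

    def test_empty_mask_empty_manifest(self):
        mask = TissueMask(np.zeros((64, 64), dtype=bool), downsample=16)
        assert len(extract_patches((1024, 1024), mask, size=512)) == 0

    def test_oversized_patch_warns_and_empties(self):
        mask = TissueMask(np.ones((8, 8), dtype=bool), downsample=16)
        with pytest.warns(UserWarning):
            man = extract_patches((128, 128), mask, size=512)
        assert len(man) == 0

    def test_higher_threshold_manifest_is_subset(self):
        img = _white(512, 512)
        img[:, :320] = (180, 80, 160)  # tissue band: third grid column half-covered
        mask = tissue_mask(img, downsample=8, min_object_px=4, min_hole_px=4)
        loose = extract_patches(img, mask, size=128, min_tissue_fraction=0.2)
        strict = extract_patches(img, mask, size=128, min_tissue_fraction=0.9)
        loose_set = set(zip(loose.df["row"], loose.df["col"]))
        strict_set = set(zip(strict.df["row"], strict.df["col"]))
        assert strict_set <= loose_set
        assert len(strict_set) < len(loose_set)

    def test_tissue_fraction_equals_bruteforce_pixel_count(self, small_slide):
        mask = tissue_mask(small_slide.image, downsample=8,
                           min_object_px=8, min_hole_px=8)
        man = extract_patches(small_slide.image, mask, size=64,
                              min_tissue_fraction=0.0)
        full = mask.full_res(small_slide.image.shape[:2])
        for _, rec in man.df.iterrows():
            r, c = int(rec["row"]), int(rec["col"])
            brute = full[r:r + 64, c:c + 64].mean()
            assert rec["tissue_fraction"] == brute

    def test_grid_tiles_without_overlap(self, small_slide):
        mask = tissue_mask(small_slide.image, downsample=8,
                           min_object_px=8, min_hole_px=8)
        man = extract_patches(small_slide.image, mask, size=64,
                              min_tissue_fraction=0.0)
        # zero threshold accepts every grid cell exactly once
        assert len(man) == (512 // 64) ** 2
        assert not man.df.duplicated(["row", "col"]).any()

    def test_duplicate_origins_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"slide_id": ["s", "s"], "row": [0, 0],
                           "col": [0, 0], "size": [64, 64],
                           "tissue_fraction": [1.0, 1.0]})
        with pytest.raises(ValueError, match="duplicate"):
            PatchManifest(df)


class TestAnnotationPatches:
    def test_region_covering_exact_cell_labelled(self):
        region = np.zeros((256, 256), dtype=bool)
        region[64:128, 64:128] = True
        man = extract_annotation_patches({"tumor": region}, size=64,
                                         min_region_fraction=0.75)
        assert len(man) == 1
        rec = man.df.iloc[0]
        assert (rec["row"], rec["col"]) == (64, 64)
        assert rec["annotation_fraction"] == 1.0
        assert rec["morphology_call"] == "tumor"

    def test_half_coverage_empty_at_075(self):
        region = np.zeros((128, 128), dtype=bool)
        region[:, ::2] = True  # 50% of every cell
        man = extract_annotation_patches({"stroma": region}, size=64)
        assert len(man) == 0

    def test_counts_match_bruteforce_on_generator_mask(self, small_slide):
        man = extract_annotation_patches(small_slide.morphology_mask, size=64,
                                         min_region_fraction=0.75)
        # brute force: count cells whose class fraction reaches 0.75
        m = small_slide.morphology_mask
        expected = {}
        for i in range(0, 512, 64):
            for j in range(0, 512, 64):
                cell = m[i:i + 64, j:j + 64]
                vals, cnts = np.unique(cell, return_counts=True)
                for v, c in zip(vals, cnts):
                    if v != 255 and c / cell.size >= 0.75:
                        name = [x.name for x in
                                __import__("histomil.synthetic",
                                           fromlist=["MORPHOLOGY_CLASSES"])
                                .MORPHOLOGY_CLASSES if x.index == v][0]
                        expected[name] = expected.get(name, 0) + 1
        got = man.df["morphology_call"].value_counts().to_dict()
        assert got == expected

    def test_overlap_without_precedence_rejected(self):
        a = np.ones((64, 64), dtype=bool)
        b = np.ones((64, 64), dtype=bool)
        with pytest.raises(ValueError, match="precedence"):
            extract_annotation_patches({"tumor": a, "stroma": b}, size=64)


class TestGeometryAdapters:
    def test_center_crop_constant_patch(self):
        patch = np.full((1024, 1024, 3), 77, dtype=np.uint8)
        out = center_crop_resize(patch)
        assert out.shape == (448, 448, 3)
        assert np.all(out == 77)

    def test_center_crop_selects_rows_256_to_767(self):
        patch = np.zeros((1024, 1024, 3), dtype=np.uint8)
        patch[256:768, 256:768] = 200  # exactly the central 512 window
        out = center_crop_resize(patch)
        assert np.all(out == 200)
        # corners of the original must not survive
        patch2 = np.full((1024, 1024, 3), 200, dtype=np.uint8)
        patch2[:256, :256] = 0
        assert np.all(center_crop_resize(patch2) == 200)

    def test_center_marker_survives_corners_do_not(self):
        patch = np.zeros((1024, 1024, 3), dtype=np.uint8)
        patch[500:524, 500:524] = 255  # center marker
        patch[0:24, 0:24] = 255        # corner marker
        out = center_crop_resize(patch)
        assert out.max() > 200          # center marker present
        assert np.all(out[:40, :40] < 50)  # corner excluded by the crop

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            center_crop_resize(np.zeros((512, 512, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            resize_for_mil(np.zeros((512, 512, 3), dtype=np.uint8))

    def test_resize_for_mil_constant(self):
        patch = np.full((1024, 1024, 3), 42, dtype=np.uint8)
        out = resize_for_mil(patch)
        assert out.shape == (224, 224, 3)
        assert np.all(out == 42)

    def test_checkerboard_downscale_preserves_mean(self):
        tile = np.indices((1024, 1024)).sum(axis=0) % 2
        patch = (tile * 255).astype(np.uint8)[..., None].repeat(3, axis=2)
        out = resize_for_mil(patch)
        assert out.mean() == pytest.approx(patch.mean(), rel=0.01)
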