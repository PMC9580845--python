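"""The four-step mask clean-up: tissue bounds, blob removal, recombination."""

import numpy as np
import pytest

from lungmet.core_io import BinaryMask, LabelStack, VolumeStack, split_multiclass
from lungmet.phantom import PhantomSpec, generate_phantom
from lungmet.postprocess import (
    PostprocessParams,
    blank_nontissue,
    clean_binary_mask,
    detect_tissue_bounds,
    postprocess_stack,
    recombine_masks,
)


class _Slab:
    """Tissue occupying z in [z0, z1] with a constant disc cross-section."""

    def __init__(self, z0, z1, cy, cx, radius):
        self.z0, self.z1, self.cy, self.cx, self.radius = z0, z1, cy, cx, radius

    def contains(self, zz, yy, xx):
        inside_z = (zz >= self.z0) & (zz <= self.z1)
        inside_disc = (yy - self.cy) ** 2 + (xx - self.cx) ** 2 <= self.radius**2
        return inside_z & inside_disc


def test_default_params_match_published_values():
    p = PostprocessParams()
    assert (p.log_sigma, p.tissue_threshold) == (7.0, 1.0)
    assert (p.min_blob_lung, p.min_blob_met) == (10, 3)
    with pytest.raises(ValueError):
        PostprocessParams(min_blob_lung=2, min_blob_met=5)


class TestTissueBounds:
    def test_all_zero_stack_has_no_tissue(self):
        assert detect_tissue_bounds(VolumeStack(np.zeros((8, 32, 32)))) is None

    def test_bounds_match_constructed_slab(self):
        spec = PhantomSpec(
            dims=(16, 48, 48),
            body=_Slab(4, 11, 24.0, 24.0, 18.0),
            lung_ellipsoids=(),
            vessels=(),
            n_noise_slices_each_end=2,
            noise_sigma=0.02,
            seed=1,
        )
        stack, _ = generate_phantom(spec)
        assert detect_tissue_bounds(stack) == (4, 11)

    def test_pure_noise_stack_scores_below_threshold(self, rng):
        noise = np.clip(rng.normal(0.0, 0.02, (6, 64, 64)), 0, 1).astype(np.float32)
        assert detect_tissue_bounds(VolumeStack(noise)) is None


class TestBlankNontissue:
    def test_none_bounds_blank_everything(self):
        mask = LabelStack(np.ones((4, 8, 8), dtype=int))
        assert blank_nontissue(mask, None).data.sum() == 0

    def test_full_bounds_are_identity(self):
        data = np.ones((4, 8, 8), dtype=int)
        out = blank_nontissue(LabelStack(data), (0, 3))
        np.testing.assert_array_equal(out.data, data)

    def test_partial_bounds_keep_interior_only(self):
        mask = LabelStack(np.ones((8, 4, 4), dtype=int))
        out = blank_nontissue(mask, (2, 5))
        per_slice = out.data.reshape(8, -1).sum(axis=1)
        np.testing.assert_array_equal(per_slice, [0, 0, 16, 16, 16, 16, 0, 0])


class TestCleanBinaryMask:
    def _blob(self, n_pixels):
        # compact blob away from the image border (5 px wide rows)
        m = np.zeros((16, 16), dtype=np.uint8)
        for i in range(n_pixels):
            m[5 + i // 5, 4 + i % 5] = 1
        return BinaryMask(m)

    def test_nine_pixel_lung_blob_removed_ten_kept(self):
        assert clean_binary_mask(self._blob(9), min_blob=10).data.sum() == 0
        assert clean_binary_mask(self._blob(10), min_blob=10).data.sum() >= 10

    def test_two_pixel_metastasis_blob_removed(self):
        assert clean_binary_mask(self._blob(2), min_blob=3).data.sum() == 0
        assert clean_binary_mask(self._blob(3), min_blob=3).data.sum() >= 3

    def test_closing_bridges_one_pixel_gap(self):
        from skimage.measure import label

        m = np.zeros((5, 5), dtype=np.uint8)
        m[:, :2] = 1
        m[:, 3:] = 1  # two segments separated by the empty column 2
        cleaned = clean_binary_mask(BinaryMask(m), min_blob=3)
        assert label(cleaned.data, connectivity=2).max() == 1

    def test_idempotent_on_clean_isolated_blob(self):
        m = np.zeros((12, 12), dtype=np.uint8)
        m[3:9, 3:9] = 1
        once = clean_binary_mask(BinaryMask(m), min_blob=10)
        twice = clean_binary_mask(once, min_blob=10)
        np.testing.assert_array_equal(once.data, twice.data)


class TestRecombine:
    def test_metastasis_precedence_on_overlap(self):
        lung = BinaryMask(np.ones((4, 4), dtype=np.uint8), "lung")
        met = BinaryMask(np.eye(4, dtype=np.uint8), "metastasis")
        out = recombine_masks(lung, met)
        assert (np.diag(out) == 2).all()
        assert (out[out != 2] == 1).all()

    def test_both_empty(self):
        z = BinaryMask(np.zeros((4, 4), dtype=np.uint8))
        assert recombine_masks(z, z).sum() == 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            recombine_masks(
                BinaryMask(np.zeros((4, 4), dtype=np.uint8)),
                BinaryMask(np.zeros((5, 5), dtype=np.uint8)),
            )

    def test_split_recombine_roundtrip(self, rng):
        data = rng.integers(0, 3, size=(3, 8, 8))
        lung, met = split_multiclass(LabelStack(data))
        np.testing.assert_array_equal(recombine_masks(lung, met), data)


class TestPostprocessStack:
    def _phantom(self):
        spec = PhantomSpec.random(
            dims=(16, 48, 48), n_metastases=2, seed=21, radius_range=(1.8, 2.4)
        )
        return generate_phantom(spec)

    def test_clean_ground_truth_survives(self):
        stack, labels = self._phantom()
        out = postprocess_stack(labels, stack)
        # ground-truth blobs are large and inside tissue bounds: the pipeline
        # may at most close tiny gaps, so the masks stay essentially equal
        assert (out.data != labels.data).mean() < 0.01
        assert set(np.unique(out.data)) <= {0, 1, 2}

    def test_small_blob_in_noise_slice_is_blanked(self):
        stack, labels = self._phantom()
        pred = labels.data.copy()
        pred[0, 5:7, 5] = 2  # 2-px metastasis speck in a pure-noise slice
        out = postprocess_stack(LabelStack(pred), stack)
        assert (out.data[0] == 0).all()

    def test_large_blob_in_noise_slice_is_still_blanked(self):
        # blanking precedes blob filtering: even a blob large enough to
        # survive the size filter disappears when it sits outside tissue
        stack, labels = self._phantom()
        pred = labels.data.copy()
        pred[0, 10:20, 10:20] = 1
        out = postprocess_stack(LabelStack(pred), stack)
        assert (out.data[0] == 0).all()

    def test_small_met_blob_in_tissue_slice_removed(self):
        stack, labels = self._phantom()
        pred = labels.data.copy()
        z = 8
        pred[z, 2, 2] = 2  # isolated 1-px speck far from the lungs
        out = postprocess_stack(LabelStack(pred), stack)
        assert out.data[z, 2, 2] == 0

    def test_shape_mismatch_rejected(self):
        stack, labels = self._phantom()
        with pytest.raises(ValueError):
            postprocess_stack(LabelStack(labels.data[:4]), stack)
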