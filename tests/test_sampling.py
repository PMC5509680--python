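import numpy as np
import pytest

from patchseg.sampling import (
    B1,
    B2,
    B3,
    T,
    PatchSet,
    decompose,
    extract_patch,
    physical_ball,
    sample_patches,
)
from patchseg.preprocess import standardize_volume
from patchseg.phantom import generate_phantom
from patchseg.volume import CHANNEL_ORDER, LabelMap

from conftest import make_volume


def brute_force_strata(vol, mask, spacing, radius=10.0, threshold=2.0):
    """Independent per-voxel reclassification by exhaustive physical distance."""
    shape = vol.shape
    tumour_idx = np.argwhere(mask)
    out = np.empty(shape, dtype=np.uint8)
    sp = np.asarray(spacing)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if mask[i, j, k]:
                    out[i, j, k] = T
                    continue
                d = np.sqrt(
                    (((np.array([i, j, k]) - tumour_idx) * sp) ** 2).sum(axis=1)
                ).min()
                if d <= radius + 1e-9:
                    out[i, j, k] = B1
                elif vol[i, j, k] > threshold:
                    out[i, j, k] = B2
                else:
                    out[i, j, k] = B3
    return out


class TestPhysicalBall:
    def test_anisotropic_half_widths(self):
        ball = physical_ball((2.0, 2.0, 5.0), 10.0)
        assert ball.shape == (11, 11, 5)  # half-widths (5, 5, 2)
        # centre included; extreme corners excluded
        assert ball[5, 5, 2]
        assert not ball[0, 0, 0]

    def test_offsets_match_brute_force(self):
        spacing, radius = (2.0, 2.0, 5.0), 10.0
        ball = physical_ball(spacing, radius)
        half = [(s - 1) // 2 for s in ball.shape]
        for idx in np.ndindex(ball.shape):
            off = np.array(idx) - half
            d2 = sum((o * s) ** 2 for o, s in zip(off, spacing))
            assert ball[idx] == (d2 <= radius**2 + 1e-9)


class TestDecompose:
    def test_single_voxel_b1_count(self):
        # oracle: voxels within 10 mm physical distance of the centre voxel
        # at (2, 2, 5) mm spacing, minus the centre itself = 204
        # (81 in-plane, 61 on each adjacent slice, 1 two slices away each side)
        shape, spacing = (16, 16, 8), (2.0, 2.0, 5.0)
        mask = np.zeros(shape, dtype=np.uint8)
        mask[8, 8, 4] = 1
        vol = np.zeros(shape)
        regions = decompose(vol, LabelMap(mask=mask), spacing)
        assert regions.counts[T] == 1
        oracle = int(
            (brute_force_strata(vol, mask.astype(bool), spacing) == B1).sum()
        )
        assert regions.counts[B1] == oracle == 204

    def test_partition_and_brute_force_equivalence(self, rng):
        shape, spacing = (10, 10, 6), (2.0, 2.0, 5.0)
        for trial in range(5):
            mask = np.zeros(shape, dtype=bool)
            n_seed = rng.integers(1, 4)
            for _ in range(n_seed):
                i, j, k = (rng.integers(0, s) for s in shape)
                mask[i, j, k] = True
            vol = rng.standard_normal(shape) * 1.5
            regions = decompose(vol, mask.astype(np.uint8), spacing)
            # partition: every voxel exactly one code
            assert regions.stratum.shape == shape
            total = sum(regions.counts.values())
            assert total == np.prod(shape)
            oracle = brute_force_strata(vol, mask, spacing)
            np.testing.assert_array_equal(regions.stratum, oracle)

    def test_t_equals_label_support(self, small_phantom):
        vol, label = small_phantom
        std = standardize_volume(vol)
        regions = decompose(std.dwi_high_b, label, vol.spacing)
        np.testing.assert_array_equal(
            regions.stratum == T, label.mask.astype(bool)
        )

    def test_no_hyperintensity_means_empty_b2(self):
        shape, spacing = (12, 12, 6), (2.0, 2.0, 5.0)
        mask = np.zeros(shape, dtype=np.uint8)
        mask[6, 6, 3] = 1
        vol = np.full(shape, -1.0)
        regions = decompose(vol, LabelMap(mask=mask), spacing)
        assert regions.counts[B2] == 0
        assert regions.counts[B3] == np.prod(shape) - 1 - regions.counts[B1]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            decompose(np.zeros((8, 8, 4)), np.zeros((8, 8, 4), np.uint8), (1, 1, 1))


class TestSamplePatches:
    @pytest.fixture
    def decomposed(self, small_phantom):
        vol, label = small_phantom
        std = standardize_volume(vol)
        return std, decompose(std.dwi_high_b, label, vol.spacing)

    def test_quota_rule_n8(self, decomposed):
        std, regions = decomposed
        ps = sample_patches(std, regions, N=8, M=5, seed=0)
        assert (ps.labels == 1).sum() == 8
        assert (ps.strata == T).sum() == 8
        assert (ps.strata == B1).sum() == 2
        assert (ps.strata == B2).sum() == 4
        assert (ps.strata == B3).sum() == 2

    def test_sampled_strata_match_decomposition(self, decomposed):
        std, regions = decomposed
        ps = sample_patches(std, regions, N=16, M=5, seed=1)
        for coord, code in zip(ps.coords, ps.strata):
            assert regions.stratum[tuple(coord)] == code

    def test_determinism(self, decomposed):
        std, regions = decomposed
        a = sample_patches(std, regions, N=16, M=5, seed=99)
        b = sample_patches(std, regions, N=16, M=5, seed=99)
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.patches, b.patches)

    def test_with_replacement_when_stratum_small(self, decomposed):
        std, regions = decomposed
        n_tumour = regions.counts[T]
        ps = sample_patches(std, regions, N=4 * (n_tumour + 4), M=3, seed=2)
        tumour_coords = ps.coords[ps.strata == T]
        assert len(tumour_coords) > n_tumour  # must have repeats
        assert len(np.unique(tumour_coords, axis=0)) <= n_tumour

    def test_empty_stratum_quota_reallocated(self):
        # volume with nothing above threshold: B2 empty, quota moves to B1/B3
        shape, spacing = (16, 16, 8), (2.0, 2.0, 5.0)
        mask = np.zeros(shape, dtype=np.uint8)
        mask[8, 8, 4] = 1
        vol = make_volume(
            arrays=[np.zeros(shape), np.zeros(shape), np.full(shape, -1.0)],
            shape=shape, spacing=spacing,
        )
        regions = decompose(vol.dwi_high_b, LabelMap(mask=mask), spacing)
        assert regions.counts[B2] == 0
        ps = sample_patches(vol, regions, N=8, M=3, seed=0)
        assert (ps.labels == 0).sum() == 8
        assert (ps.strata == B2).sum() == 0
        assert (ps.strata == B1).sum() + (ps.strata == B3).sum() == 8

    def test_validation_errors(self, decomposed):
        std, regions = decomposed
        with pytest.raises(ValueError, match="divisible"):
            sample_patches(std, regions, N=6, M=5)
        with pytest.raises(ValueError, match="odd"):
            sample_patches(std, regions, N=8, M=4)

    def test_save_load_roundtrip(self, decomposed, tmp_path):
        std, regions = decomposed
        ps = sample_patches(std, regions, N=8, M=5, seed=3)
        ps.save(tmp_path / "patches")
        back = PatchSet.load(tmp_path / "patches")
        np.testing.assert_array_equal(ps.patches, back.patches)
        np.testing.assert_array_equal(ps.labels, back.labels)
        np.testing.assert_array_equal(ps.coords, back.coords)
        np.testing.assert_array_equal(ps.strata, back.strata)


class TestExtractPatch:
    def test_degenerate_m1(self):
        vol = make_volume(shape=(8, 8, 4), seed=1)
        tile = extract_patch(vol, (3, 4, 2), M=1)
        assert tile.shape == (1, 1, 3)
        expected = [getattr(vol, name)[3, 4, 2] for name in CHANNEL_ORDER]
        np.testing.assert_allclose(tile[0, 0], expected, rtol=1e-6)

    def test_corner_patch_padded(self):
        vol = make_volume(shape=(30, 30, 4), seed=2)
        tile = extract_patch(vol, (0, 0, 0), M=21)
        assert tile.shape == (21, 21, 3)
        assert (tile[:10, :, :] == 0).all() or (tile[:, :10, :] == 0).all()
        # padded margin is exactly the out-of-bounds region
        assert (tile[:10, :10, :] == 0).all()

    def test_interior_patch_centred(self):
        vol = make_volume(shape=(16, 16, 4), seed=3)
        tile = extract_patch(vol, (8, 7, 2), M=5)
        expected = [getattr(vol, name)[8, 7, 2] for name in CHANNEL_ORDER]
        np.testing.assert_allclose(tile[2, 2], expected, rtol=1e-6)
        np.testing.assert_allclose(
            tile[0, 0],
            [getattr(vol, name)[6, 5, 2] for name in CHANNEL_ORDER],
            rtol=1e-6,
        )

    def test_even_m_raises(self):
        vol = make_volume(shape=(8, 8, 4))
        with pytest.raises(ValueError, match="odd"):
            extract_patch(vol, (4, 4, 2), M=4)

    def test_outside_voxel_raises(self):
        vol = make_volume(shape=(8, 8, 4))
        with pytest.raises(ValueError, match="outside"):
            extract_patch(vol, (8, 0, 0), M=3)
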