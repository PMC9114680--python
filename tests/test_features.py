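"""Feature construction, normalization and class balancing."""

import numpy as np
import pytest

from mrseg.features import (
    FeatureError,
    FeatureMatrix,
    FeatureSetDescriptor,
    ZeroVarianceError,
    assemble_matrix,
    patient_matrix,
    sequence_features,
    t2w_features,
    undersample,
    zscore_normalize,
)
from mrseg.phantom import DME, DW, T2SW, T2W
from mrseg.volume import ImageVolume


class TestDescriptor:
    def test_fifteen_combinations(self):
        combos = FeatureSetDescriptor.all_combinations()
        assert len(combos) == 15
        assert len(set(combos)) == 15

    def test_feature_counts_additive(self):
        assert FeatureSetDescriptor.of(T2W).n_features == 9
        assert FeatureSetDescriptor.of(T2SW).n_features == 5
        assert FeatureSetDescriptor.of(DW).n_features == 7
        assert FeatureSetDescriptor.of(DME).n_features == 42
        assert FeatureSetDescriptor.of(T2W, T2SW, DW, DME).n_features == 63

    def test_members_canonicalized(self):
        d = FeatureSetDescriptor.of(DME, T2W)
        assert d.members == (T2W, DME)

    def test_empty_rejected(self):
        with pytest.raises(FeatureError):
            FeatureSetDescriptor(())


class TestT2wFeatures:
    def test_constant_image_gives_nine_copies(self):
        vol = ImageVolume(np.full((3, 5, 5), 7.0), (1, 1, 1))
        assert np.array_equal(t2w_features(vol, (1, 2, 2)), np.full(9, 7.0))

    def test_patch_sorted_ascending(self):
        vol = ImageVolume(np.zeros((1, 3, 3)), (1, 1, 1))
        vol.data[0] = np.array([[9, 1, 5], [3, 7, 2], [8, 4, 6]], dtype=float)
        assert np.array_equal(
            t2w_features(vol, (0, 1, 1)), np.arange(1.0, 10.0)
        )

    def test_corner_voxel_matches_padded_patch_oracle(self):
        rng = np.random.default_rng(0)
        vol = ImageVolume(rng.normal(size=(2, 6, 7)), (1, 1, 1))
        # oracle: explicit edge-replicated pad, then slice
        padded = np.pad(vol.data, ((0, 0), (1, 1), (1, 1)), mode="edge")
        for voxel in [(0, 0, 0), (1, 5, 6), (0, 0, 6), (1, 3, 0)]:
            z, y, x = voxel
            expect = np.sort(padded[z, y : y + 3, x : x + 3].ravel())
            assert np.allclose(t2w_features(vol, voxel), expect)

    def test_voxel_outside_volume_rejected(self):
        vol = ImageVolume(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(FeatureError):
            t2w_features(vol, (2, 0, 0))


class TestSequenceFeatures:
    def test_block_lengths(self, prep_study):
        vox = (1, 1, 1)
        assert sequence_features(prep_study, vox, FeatureSetDescriptor.of(DW)).size == 7
        assert (
            sequence_features(prep_study, vox, FeatureSetDescriptor.of(DME)).size == 42
        )
        full = FeatureSetDescriptor.of(T2W, T2SW, DW, DME)
        assert sequence_features(prep_study, vox, full).size == 63

    def test_dw_block_in_ascending_b_order(self, prep_study):
        vox = (2, 3, 4)
        vals = sequence_features(prep_study, vox, FeatureSetDescriptor.of(DW))
        expect = [
            v.data[vox] for v in sorted(prep_study.dw, key=lambda v: v.channel["b"])
        ]
        assert np.allclose(vals, expect)

    def test_missing_channel_rejected(self, prep_study):
        import copy

        broken = copy.copy(prep_study)
        broken.dw = prep_study.dw[:5]
        with pytest.raises(FeatureError, match="channels"):
            sequence_features(broken, (0, 0, 0), FeatureSetDescriptor.of(DW))


class TestAssemble:
    def test_one_row_per_roi_voxel(self, prep_study):
        m = assemble_matrix(prep_study, FeatureSetDescriptor.of(T2W))
        assert m.values.shape == (prep_study.t2w.data.size, 9)
        assert m.voxel_indices.shape[0] == m.values.shape[0]

    def test_label_sum_equals_union_voxels(self, prep_study):
        m = assemble_matrix(prep_study, FeatureSetDescriptor.of(DW))
        assert m.labels.sum() == prep_study.union.data.sum()

    def test_known_tumor_voxel_labelled_one(self, prep_study):
        m = assemble_matrix(prep_study, FeatureSetDescriptor.of(T2W))
        z, y, x = np.argwhere(prep_study.union.data)[0]
        row = np.nonzero(
            (m.voxel_indices == np.array([z, y, x])).all(axis=1)
        )[0][0]
        assert m.labels[row] == 1

    def test_interior_features_unaffected_by_cropping(self, prep_study):
        # feature extraction commutes with cropping for interior voxels
        full = assemble_matrix(prep_study, FeatureSetDescriptor.of(T2W))
        vox = tuple(np.argwhere(prep_study.union.data)[0])
        direct = t2w_features(prep_study.t2w, vox)
        row = np.nonzero((full.voxel_indices == np.array(vox)).all(axis=1))[0][0]
        assert np.allclose(full.values[row], direct)

    def test_unpreprocessed_study_rejected(self, small_study):
        with pytest.raises(FeatureError, match="preprocessed"):
            assemble_matrix(small_study, FeatureSetDescriptor.of(T2W))


def _toy_matrix(values, labels=None, descriptor=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    descriptor = descriptor or FeatureSetDescriptor.of(DW)
    if labels is None:
        labels = np.zeros(n, dtype=np.int8)
    return FeatureMatrix(
        values=values,
        voxel_indices=np.zeros((n, 3), dtype=int),
        labels=np.asarray(labels, dtype=np.int8),
        patient_id="toy",
        descriptor=descriptor,
        feature_names=tuple(f"DW_b{i}" for i in range(values.shape[1])),
    )


class TestZScore:
    def test_columns_standardized(self, prep_study):
        m = patient_matrix(prep_study, FeatureSetDescriptor.of(DW, T2SW))
        assert np.all(np.abs(m.values.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(m.values.std(axis=0) - 1) < 1e-9)
        assert m.norm_stats is not None

    def test_global_scale_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(50, 7))
        a = zscore_normalize(_toy_matrix(base))
        b = zscore_normalize(_toy_matrix(base * 3.7))
        assert np.allclose(a.values, b.values)

    def test_hand_worked_per_column_scores(self):
        # four voxels, first column [1,2,3,4]: mean 2.5, sd sqrt(5)/2
        vals = np.column_stack(
            [np.array([1.0, 2.0, 3.0, 4.0])]
            + [np.array([0.0, 1.0, 0.0, 1.0])] * 6
        )
        out = zscore_normalize(_toy_matrix(vals))
        sd = np.sqrt(1.25)
        assert np.allclose(
            out.values[:, 0], (np.array([1, 2, 3, 4]) - 2.5) / sd
        )
        assert np.allclose(np.abs(out.values[:, 1]), 1.0)

    def test_zero_variance_column_rejected(self):
        vals = np.ones((10, 7))
        vals[:, :6] = np.random.default_rng(0).normal(size=(10, 6))
        with pytest.raises(ZeroVarianceError):
            zscore_normalize(_toy_matrix(vals))


class TestUndersample:
    def _imbalanced(self, n_tumor=100, n_bg=1000, seed=0):
        rng = np.random.default_rng(seed)
        n = n_tumor + n_bg
        labels = np.zeros(n, dtype=np.int8)
        labels[:n_tumor] = 1
        return _toy_matrix(rng.normal(size=(n, 7)), labels)

    def test_balanced_counts(self):
        out = undersample(self._imbalanced(), seed=5)
        assert out.labels.size == 200
        assert out.labels.sum() == 100

    def test_tumor_fraction_exactly_half(self):
        out = undersample(self._imbalanced(37, 512), seed=5)
        assert out.labels.mean() == 0.5

    def test_all_tumor_rows_retained(self):
        m = self._imbalanced()
        out = undersample(m, seed=5)
        tumor_rows = m.values[m.labels == 1]
        kept_tumor = out.values[out.labels == 1]
        assert np.array_equal(np.sort(tumor_rows, axis=0), np.sort(kept_tumor, axis=0))

    def test_seed_reproducible(self):
        m = self._imbalanced()
        a = undersample(m, seed=9)
        b = undersample(m, seed=9)
        assert np.array_equal(a.values, b.values)
        c = undersample(m, seed=10)
        assert not np.array_equal(a.values, c.values)

    def test_fewer_background_than_tumor_warns_and_keeps_all(self):
        m = self._imbalanced(50, 20)
        with pytest.warns(UserWarning, match="fewer non-tumor"):
            out = undersample(m, seed=0)
        assert out.labels.size == 70

    def test_single_class_rejected(self):
        m = _toy_matrix(np.zeros((10, 7)), np.ones(10))
        with pytest.raises(FeatureError):
            undersample(m, seed=0)
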