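"""Time-point selection, ROI box construction, registration/resampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrseg.phantom import DME, DW, T2SW, T2W, RigidParams, generate_study
from mrseg.preprocess import (
    NOMINAL_OFFSETS,
    RoiBox,
    SelectionError,
    common_fov,
    compute_bounding_box,
    preprocess_study,
    register_and_resample,
    select_dme_timepoints,
)
from mrseg.volume import ImageVolume, mask_volume_mm3

from conftest import tiny_spec


class TestTimepointSelection:
    def test_printed_schedule_on_4s_acquisition(self):
        ts = np.arange(0.0, 604.0, 4.0)
        sel = select_dme_timepoints(ts, arrival=0.0)
        assert len(sel.indices) == 14
        assert sel.timestamps_s == (
            0, 4, 8, 12, 16, 20, 24, 28, 108, 188, 268, 348, 428, 508
        )

    def test_2s_acquisition_hits_targets_exactly(self):
        ts = np.arange(0.0, 602.0, 2.0)
        sel = select_dme_timepoints(ts, arrival=0.0)
        assert sel.timestamps_s == tuple(NOMINAL_OFFSETS)

    def test_nonzero_arrival_shifts_schedule(self):
        ts = np.arange(0.0, 640.0, 4.0)
        sel = select_dme_timepoints(ts, arrival=12.0)
        assert sel.timestamps_s == tuple(12.0 + np.asarray(NOMINAL_OFFSETS))
        assert sel.timestamps_s[0] == 12.0  # first frame is the arrival image

    @given(st.integers(0, 10_000))
    def test_jittered_acquisition_matches_bruteforce_nearest(self, seed):
        rng = np.random.default_rng(seed)
        base = np.arange(0.0, 620.0, 4.0)
        ts = np.sort(base + rng.uniform(-1.0, 1.0, size=base.size))
        assert np.all(np.diff(ts) > 0)
        sel = select_dme_timepoints(ts, arrival=float(ts[0]))
        # brute-force greedy oracle over all candidates
        used = []
        for off in NOMINAL_OFFSETS:
            target = ts[0] + off
            best = min(
                (i for i in range(ts.size) if i not in used),
                key=lambda i: (abs(ts[i] - target), ts[i]),
            )
            used.append(best)
        assert sorted(used) == list(sel.indices)
        for t_sel, off in zip(np.sort(ts[used]), NOMINAL_OFFSETS):
            assert abs(t_sel - (ts[0] + off)) <= 2.0

    def test_tie_breaks_toward_earlier_frame(self):
        # target 0: frames at -2 and +2 are equidistant -> earlier wins
        ts = np.array([-2.0, 2.0, 6.0, 10.0, 14.0, 18.0, 22.0, 26.0]
                      + list(np.arange(30.0, 620.0, 4.0)))
        sel = select_dme_timepoints(ts, arrival=0.0)
        assert sel.timestamps_s[0] == -2.0

    def test_duplicate_selection_advances_to_next_unused(self):
        # 8 s sampling: fast-phase targets 0,4 both closest to frames 0/8
        ts = np.arange(0.0, 616.0, 8.0)
        sel = select_dme_timepoints(ts, arrival=0.0)
        assert len(set(sel.indices)) == 14

    def test_selection_idempotent(self):
        ts = np.arange(0.0, 604.0, 4.0)
        sel = select_dme_timepoints(ts, arrival=0.0)
        again = select_dme_timepoints(sel.timestamps_s, arrival=0.0)
        assert again.timestamps_s == sel.timestamps_s
        assert again.indices == tuple(range(14))

    def test_arrival_after_last_frame_rejected(self):
        with pytest.raises(SelectionError, match="arrival"):
            select_dme_timepoints(np.arange(0.0, 600.0, 4.0), arrival=700.0)

    def test_short_acquisition_rejected(self):
        with pytest.raises(SelectionError):
            select_dme_timepoints(np.arange(0.0, 400.0, 4.0), arrival=0.0)

    def test_non_increasing_timestamps_rejected(self):
        with pytest.raises(SelectionError):
            select_dme_timepoints([0.0, 4.0, 4.0, 8.0], arrival=0.0)


class TestBoundingBox:
    def _point_mask(self, where_mm=(50.0, 50.0, 50.0)):
        data = np.zeros((101, 101, 101), dtype=bool)
        x, y, z = (int(v) for v in where_mm)
        data[z, y, x] = True
        return ImageVolume(data, (1.0, 1.0, 1.0))

    def test_single_voxel_with_margin(self):
        box = compute_bounding_box(self._point_mask(), margin_mm=20.0)
        assert box.lower == pytest.approx((30.0, 30.0, 30.0))
        assert box.upper == pytest.approx((70.0, 70.0, 70.0))

    def test_zero_margin_is_tight(self):
        mask = self._point_mask()
        mask.data[52, 55, 58] = True
        box = compute_bounding_box(mask, margin_mm=0.0)
        assert box.lower == pytest.approx((50.0, 50.0, 50.0))
        assert box.upper == pytest.approx((58.0, 55.0, 52.0))

    def test_clipped_to_fov(self):
        mask = self._point_mask((3.0, 50.0, 50.0))
        fov = RoiBox((0.0, 0.0, 0.0), (100.0, 100.0, 100.0))
        box = compute_bounding_box(mask, margin_mm=20.0, fov=fov)
        assert box.lower[0] == 0.0
        assert np.all(np.asarray(box.lower) >= 0.0)

    def test_empty_mask_rejected(self):
        empty = ImageVolume(np.zeros((5, 5, 5), dtype=bool), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            compute_bounding_box(empty)

    def test_disjoint_fov_rejected(self):
        fov = RoiBox((200.0, 200.0, 200.0), (300.0, 300.0, 300.0))
        with pytest.raises(ValueError, match="FOV"):
            compute_bounding_box(self._point_mask(), margin_mm=5.0, fov=fov)


def _registration_spec(noise_sigma=None, **mis):
    from mrseg.phantom import GridSpec

    g = GridSpec((36, 36, 26), (1.5, 1.5, 2.0))
    misalignment = {k: RigidParams() for k in (T2W, T2SW, DW, DME)}
    misalignment.update(mis)
    return tiny_spec(
        grids={T2W: g, T2SW: g, DW: g, DME: g},
        tumor_semiaxes_mm=(9.0, 8.0, 7.0),
        misalignment=misalignment,
        noise_sigma=noise_sigma or {T2W: 5.0, T2SW: 10.0, DW: 10.0, DME: 8.0},
    )


class TestRegistration:
    def test_aligned_noiseless_study_recovers_identity(self):
        spec = _registration_spec(
            noise_sigma={T2W: 0.0, T2SW: 0.0, DW: 0.0, DME: 0.0}
        )
        study = generate_study(spec, seed=21)
        prep = preprocess_study(study, margin_mm=10.0, estimate_transforms=True)
        for seq, tf in prep._estimated_transforms.items():
            if tf is None:
                continue
            params = np.asarray(tf.GetParameters())
            assert np.all(np.abs(params[3:]) < 0.1), seq  # mm
            assert np.all(np.abs(np.rad2deg(params[:3])) < 0.1), seq

    def test_known_translation_recovered(self):
        injected = (3.0, 0.0, 0.0)
        study = generate_study(
            _registration_spec(**{DW: RigidParams(translation_mm=injected)}), seed=22
        )
        prep = preprocess_study(study, margin_mm=10.0, estimate_transforms=True)
        tf = prep._estimated_transforms[DW]
        # the image content is shifted by T, so registration recovers T^-1
        recovered = -np.asarray(tf.GetParameters()[3:])
        assert np.all(np.abs(recovered - np.asarray(injected)) < 0.5)

    def test_output_spacing_is_isotropic_1mm(self, prep_study):
        for seq in (T2W, T2SW, DW, DME):
            for vol in prep_study.channels(seq):
                assert vol.spacing == (1.0, 1.0, 1.0)

    def test_mask_volume_preserved_within_surface_bound(self, small_study, prep_study):
        from mrseg.metrics import surface_voxels

        before = mask_volume_mm3(small_study.truth)
        after = mask_volume_mm3(prep_study.truth)
        bound = surface_voxels(small_study.truth).count * np.prod(
            small_study.truth.spacing
        )
        assert abs(after - before) <= bound

    def test_preprocessed_study_carries_selection_and_box(self, prep_study):
        sel = prep_study.dme_selection
        assert len(sel.indices) == 14
        assert len(prep_study.dme) == 14
        assert prep_study.roi_box is not None
        assert prep_study.is_preprocessed


class TestCommonFov:
    def test_fov_is_intersection_of_sequences(self, small_study):
        fov = common_fov(small_study)
        for seq in (T2W, T2SW, DW, DME):
            lo, hi = small_study.channels(seq)[0].extent()
            assert np.all(np.asarray(fov.lower) >= lo - 1e-9)
            assert np.all(np.asarray(fov.upper) <= hi + 1e-9)
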