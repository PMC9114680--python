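"""Phantom generator: signal models, geometry, observers, determinism."""

import numpy as np
import pytest

from mrseg.metrics import dice
from mrseg.phantom import (
    DME,
    DW,
    T2SW,
    T2W,
    PhantomError,
    PhantomSpec,
    dce_uptake_factor,
    dw_signal,
    generate_study,
    ground_truth_union,
    simulate_observers,
    t2star_signal,
)
from mrseg.volume import ImageVolume

from conftest import make_sphere_mask, tiny_spec


def _noiseless_spec():
    return tiny_spec(noise_sigma={T2W: 0.0, T2SW: 0.0, DW: 0.0, DME: 0.0})


class TestSignalModels:
    def test_dw_b0_equals_s0(self):
        assert dw_signal(1000.0, 0.0, 1.0e-3) == 1000.0

    def test_dw_closed_form(self):
        # S0=1000, b=1000, ADC=1e-3 -> 1000/e
        assert dw_signal(1000.0, 1000.0, 1.0e-3) == pytest.approx(367.879441, abs=1e-5)

    def test_t2star_closed_form(self):
        assert t2star_signal(500.0, 23.0, 46.0) == pytest.approx(500.0 * np.exp(-0.5))

    def test_uptake_baseline_before_arrival(self, ):
        tissue = tiny_spec().tumor
        assert dce_uptake_factor(5.0, 12.0, tissue) == 1.0

    def test_uptake_rises_then_washes_out(self):
        tissue = tiny_spec().tumor
        early = dce_uptake_factor(20.0, 12.0, tissue)
        peak = dce_uptake_factor(120.0, 12.0, tissue)
        late = dce_uptake_factor(520.0, 12.0, tissue)
        assert 1.0 < early < peak
        assert late < peak

    def test_noiseless_b0_channel_is_s0_everywhere(self):
        spec = _noiseless_spec()
        study = generate_study(spec, seed=3)
        b0 = study.dw[0]
        assert b0.channel["b"] == 0.0
        assert np.allclose(b0.data, spec.s0[DW])

    def test_noiseless_volumes_take_exact_tissue_values(self):
        spec = _noiseless_spec()
        study = generate_study(spec, seed=3)
        b1000 = next(v for v in study.dw if v.channel["b"] == 1000.0)
        expected = sorted(
            [
                dw_signal(spec.s0[DW], 1000.0, spec.tumor.adc),
                dw_signal(spec.s0[DW], 1000.0, spec.normal.adc),
            ]
        )
        assert list(np.unique(b1000.data)) == pytest.approx(expected)
        te = spec.echo_times_t2sw_ms[2]
        t2s = study.t2sw[2]
        assert t2s.channel["te_ms"] == te
        vals = sorted(np.unique(t2s.data))
        assert vals == pytest.approx(
            sorted(
                [
                    t2star_signal(spec.s0[T2SW], te, spec.tumor.t2star_ms),
                    t2star_signal(spec.s0[T2SW], te, spec.normal.t2star_ms),
                ]
            )
        )

    def test_tumor_normal_contrast_matches_adc_difference(self):
        spec = _noiseless_spec()
        study = generate_study(spec, seed=4)
        b1000 = next(v for v in study.dw if v.channel["b"] == 1000.0)
        # the DW grid equals the T2w grid in the tiny spec, so the truth
        # mask indexes the DW volume directly
        tumor_mean = b1000.data[study.truth.data].mean()
        normal_mean = b1000.data[~study.truth.data].mean()
        expected = np.exp(-1000.0 * (spec.tumor.adc - spec.normal.adc))
        assert tumor_mean / normal_mean == pytest.approx(expected, rel=1e-12)

    def test_dme_prearrival_frames_have_no_enhancement(self):
        spec = _noiseless_spec()
        study = generate_study(spec, seed=5)
        pre = [f for f, t in zip(study.dme, study.timestamps_s) if t < spec.arrival_s]
        assert pre, "split acquisition should include pre-arrival frames"
        for frame in pre:
            for vol in frame:
                te = vol.channel["te_ms"]
                vals = sorted(np.unique(vol.data))
                assert vals == pytest.approx(
                    sorted(
                        [
                            t2star_signal(spec.s0[DME], te, spec.tumor.t2star_ms),
                            t2star_signal(spec.s0[DME], te, spec.normal.t2star_ms),
                        ]
                    )
                )


class TestStudyStructure:
    def test_channel_counts(self, small_study):
        assert len(small_study.t2sw) == 5
        assert len(small_study.dw) == 7
        assert all(len(frame) == 3 for frame in small_study.dme)

    def test_reproducible_given_spec_and_seed(self):
        a = generate_study(tiny_spec(), seed=9)
        b = generate_study(tiny_spec(), seed=9)
        assert np.array_equal(a.t2w.data, b.t2w.data)
        assert np.array_equal(a.truth.data, b.truth.data)
        assert np.array_equal(a.observer_a.data, b.observer_a.data)
        for va, vb in zip(a.channels(DME), b.channels(DME)):
            assert np.array_equal(va.data, vb.data)

    def test_different_seeds_differ(self):
        a = generate_study(tiny_spec(), seed=9)
        b = generate_study(tiny_spec(), seed=10)
        assert not np.array_equal(a.t2w.data, b.t2w.data)

    def test_tumor_outside_fov_rejected(self):
        spec = tiny_spec(tumor_center_mm=(2.0, 2.0, 2.0))
        with pytest.raises(PhantomError, match="field of view"):
            generate_study(spec, seed=0)

    def test_timestamps_must_span_dynamic_schedule(self):
        spec = tiny_spec(timestamps_s=tuple(np.arange(0.0, 400.0, 4.0)))
        with pytest.raises(PhantomError, match="508"):
            generate_study(spec, seed=0)

    def test_masks_binary_and_union_contains_observers(self, small_study):
        union = small_study.union
        for m in (small_study.observer_a, small_study.observer_b, union):
            assert m.data.dtype == bool
        assert np.all(union.data[small_study.observer_a.data])
        assert np.all(union.data[small_study.observer_b.data])


class TestGroundTruthUnion:
    def test_union_of_identical_masks(self, sphere30):
        u = ground_truth_union(sphere30, sphere30)
        assert np.array_equal(u.data, sphere30.data.astype(bool))

    def test_disjoint_masks_add(self):
        a = ImageVolume(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))
        b = ImageVolume(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))
        a.data.flat[:10] = True
        b.data.flat[20:25] = True
        u = ground_truth_union(a, b)
        assert u.data.sum() == 15

    def test_union_at_least_as_large_as_each(self, small_study):
        u = small_study.union
        assert u.data.sum() >= max(
            small_study.observer_a.data.sum(), small_study.observer_b.data.sum()
        )

    def test_grid_mismatch_rejected(self, sphere30):
        other = ImageVolume(np.zeros((5, 5, 5), dtype=bool), (1, 1, 1))
        with pytest.raises(Exception):
            ground_truth_union(sphere30, other)


class TestSimulatedObservers:
    def test_zero_amplitude_returns_truth_copies(self, sphere30):
        a, b = simulate_observers(sphere30, 0.0, seed=1)
        assert dice(a, b) == 1.0
        assert np.array_equal(a.data, sphere30.data)

    def test_empty_truth_rejected(self):
        empty = ImageVolume(np.zeros((8, 8, 8), dtype=bool), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            simulate_observers(empty, 2.0, seed=0)

    def test_observers_bounded_by_eroded_and_dilated_truth(self, sphere30):
        from mrseg.phantom import _signed_distance_mm

        amp = 4.0
        sdf = _signed_distance_mm(sphere30)
        slack = 1.0  # one voxel of interpolation/discretization slack
        a, b = simulate_observers(sphere30, amp, seed=2)
        for obs in (a, b):
            assert np.all(sdf[obs.data] <= amp + slack)
            assert np.all(obs.data[sdf <= -(amp + slack)])

    def test_calibrated_amplitude_gives_clinical_interobserver_dice(self, sphere30):
        # median observer-pair Dice of the default amplitude should sit in
        # the range reported for expert rectal-tumor delineations
        amp = PhantomSpec().observer_amplitude_mm
        dices = [
            dice(*simulate_observers(sphere30, amp, seed=s)) for s in range(22)
        ]
        assert 0.78 <= float(np.median(dices)) <= 0.86

    def test_deterministic_given_seed(self, sphere30):
        a1, b1 = simulate_observers(sphere30, 3.0, seed=7)
        a2, b2 = simulate_observers(sphere30, 3.0, seed=7)
        assert np.array_equal(a1.data, a2.data)
        assert np.array_equal(b1.data, b2.data)
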