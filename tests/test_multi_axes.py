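"""Slicing, rotation, back-mapping and the two fusion rules."""

import itertools

import numpy as np
import pytest

import segscale as ss
from segscale.multi_axes import (
    PlaneTransform,
    ProbabilityVolume,
    argmax_labels,
    back_map,
    generate_plane_set,
    majority_vote,
    padded_shape_for,
    plane_slice_count,
    predict_plane,
    predict_volume,
    restack,
    rotate_volume,
    slice_volume,
    soft_vote,
    validity_mask,
)

GEOM = ss.VoxelGeometry(5.0)


class TestPlaneTransform:
    def test_redundant_combination_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            PlaneTransform("p", rotation_axis="p", rotation_deg=45.0)

    def test_rotation_angle_without_axis_rejected(self):
        with pytest.raises(ValueError):
            PlaneTransform("p", rotation_axis=None, rotation_deg=45.0)

    def test_names_are_unique(self):
        names = [t.name for t in generate_plane_set(9)]
        assert len(set(names)) == 9


class TestPlaneSets:
    def test_three_naive_planes(self):
        planes = generate_plane_set(3)
        assert [t.slicing_axis for t in planes] == ["p", "r", "c"]
        assert all(t.rotation_axis is None for t in planes)

    def test_nine_planes_six_rotated(self):
        planes = generate_plane_set(9)
        assert len(planes) == 9
        rotated = [t for t in planes if t.rotation_axis is not None]
        assert len(rotated) == 6
        assert all(t.rotation_deg == 45.0 for t in rotated)
        # no rotated plane slices along its own rotation axis
        assert all(t.slicing_axis != t.rotation_axis for t in rotated)

    def test_other_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_plane_set(6)


class TestSliceRestack:
    @pytest.mark.parametrize("axis", ["p", "r", "c"])
    def test_bijective_for_naive_planes(self, axis):
        rng = np.random.default_rng(0)
        data = rng.random((5, 6, 7)).astype(np.float32)
        t = PlaneTransform(axis)
        s = slice_volume(ss.Volume(data, GEOM), t)
        assert len(s) == data.shape[{"p": 0, "r": 1, "c": 2}[axis]]
        np.testing.assert_array_equal(restack(s, t), data)

    def test_slice_orientation_fix_p(self):
        data = np.arange(2 * 3 * 4, dtype=np.float32).reshape(2, 3, 4)
        s = slice_volume(ss.Volume(data, GEOM), PlaneTransform("p"))
        np.testing.assert_array_equal(s.slices[1], data[1, :, :])

    def test_slice_orientation_fix_r(self):
        data = np.arange(2 * 3 * 4, dtype=np.float32).reshape(2, 3, 4)
        s = slice_volume(ss.Volume(data, GEOM), PlaneTransform("r"))
        np.testing.assert_array_equal(s.slices[2], data[:, 2, :])

    def test_restack_keeps_class_axis_last(self):
        probs = np.random.default_rng(1).random((6, 4, 5, 3)).astype(np.float32)
        out = restack(probs, PlaneTransform("r"))
        assert out.shape == (4, 6, 5, 3)


class TestRotation:
    def test_padded_shape_100_cube_at_45(self):
        assert padded_shape_for((100, 100, 100), "p", 45.0) == (100, 142, 142)

    def test_padded_shape_zero_angle_is_identity(self):
        assert padded_shape_for((10, 20, 30), "r", 0.0) == (10, 20, 30)

    def test_slice_counts_reflect_padding(self):
        shape = (100, 100, 100)
        assert plane_slice_count(shape, PlaneTransform("p")) == 100
        t = PlaneTransform("r", rotation_axis="p", rotation_deg=45.0)
        assert plane_slice_count(shape, t) == 142

    def test_zero_volume_invariant(self):
        v = ss.Volume(np.zeros((20, 20, 20), np.float32), GEOM)
        out = rotate_volume(v, "c", 45.0)
        assert out.shape == (29, 29, 20)
        assert np.all(out.data == 0.0)

    def test_round_trip_small_interior_error(self, smooth_volume):
        fwd = rotate_volume(smooth_volume, "p", 45.0)
        back = rotate_volume(fwd, "p", -45.0)
        from segscale.multi_axes import _crop_to

        rec = _crop_to(back.data, smooth_volume.shape)
        mask = validity_mask(smooth_volume.shape, PlaneTransform("r", "p", 45.0))
        err = np.abs(rec - smooth_volume.data)[mask]
        assert err.mean() < 0.02


class TestBackMap:
    def test_identity_for_naive_plane(self):
        probs = np.random.default_rng(2).random((5, 6, 7, 4)).astype(np.float32)
        p = ProbabilityVolume(probs, GEOM)
        out = back_map(p, PlaneTransform("p"), (5, 6, 7))
        np.testing.assert_array_equal(out.data, probs)
        assert out.valid_mask.all()

    def test_shape_mismatch_raises(self):
        p = ProbabilityVolume(np.zeros((4, 4, 4, 2), np.float32), GEOM)
        with pytest.raises(ValueError):
            back_map(p, PlaneTransform("p"), (5, 5, 5))

    def test_rotated_constant_one_hot_recovered_on_valid_voxels(self):
        # a constant one-hot field is invariant under rotation, so back-mapping
        # the rotated field must reproduce it wherever the mask is valid
        shape = (24, 24, 24)
        t = PlaneTransform("r", rotation_axis="p", rotation_deg=45.0)
        onehot = np.zeros(shape + (3,), np.float32)
        onehot[..., 2] = 1.0
        work = padded_shape_for(shape, "p", 45.0)
        from segscale.multi_axes import _pad_to, _rotate_array

        rotated = _rotate_array(_pad_to(onehot, work + (3,)), "p", 45.0)
        out = back_map(ProbabilityVolume(rotated, GEOM), t, shape)
        assert out.valid_mask.any() and not out.valid_mask.all()
        np.testing.assert_allclose(
            out.data[out.valid_mask], onehot[out.valid_mask], atol=1e-5
        )

    def test_output_rows_sum_to_one_on_valid_voxels(self):
        shape = (16, 16, 16)
        t = PlaneTransform("c", rotation_axis="r", rotation_deg=45.0)
        work = padded_shape_for(shape, "r", 45.0)
        rng = np.random.default_rng(3)
        raw = rng.random(work + (4,)).astype(np.float32)
        raw /= raw.sum(axis=-1, keepdims=True)
        out = back_map(ProbabilityVolume(raw, GEOM), t, shape)
        sums = out.data.sum(axis=-1)
        np.testing.assert_allclose(sums[out.valid_mask], 1.0, atol=1e-5)
        # voxels entirely outside the rotated support stay at zero mass
        assert np.all((np.abs(sums - 1.0) < 1e-5) | (sums < 1.0))


def _prob(labels: np.ndarray, k: int = 4) -> ProbabilityVolume:
    return ProbabilityVolume(np.eye(k, dtype=np.float32)[labels], GEOM)


class TestSoftVote:
    def test_mean_of_two_fields(self):
        rng = np.random.default_rng(4)
        a = rng.random((3, 3, 3, 2)).astype(np.float32)
        b = rng.random((3, 3, 3, 2)).astype(np.float32)
        fused = soft_vote([ProbabilityVolume(a, GEOM), ProbabilityVolume(b, GEOM)])
        np.testing.assert_allclose(fused.data, (a + b) / 2, atol=1e-6)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(5)
        preds = [
            ProbabilityVolume(rng.random((4, 4, 4, 3)).astype(np.float32), GEOM)
            for _ in range(3)
        ]
        f1 = soft_vote(preds)
        f2 = soft_vote(preds[::-1])
        np.testing.assert_allclose(f1.data, f2.data, atol=1e-6)

    def test_invalid_voxels_excluded_from_mean(self):
        a = np.zeros((2, 2, 2, 2), np.float32)
        a[..., 0] = 1.0
        b = np.zeros((2, 2, 2, 2), np.float32)
        b[..., 1] = 1.0
        mask_b = np.zeros((2, 2, 2), bool)  # b is valid nowhere
        fused = soft_vote(
            [ProbabilityVolume(a, GEOM), ProbabilityVolume(b, GEOM, mask_b)]
        )
        np.testing.assert_allclose(fused.data[..., 0], 1.0)

    def test_uniform_fallback_when_nothing_valid(self, caplog):
        a = ProbabilityVolume(
            np.ones((2, 2, 2, 4), np.float32) / 4, GEOM, np.zeros((2, 2, 2), bool)
        )
        with caplog.at_level("WARNING", logger="segscale"):
            fused = soft_vote([a])
        np.testing.assert_allclose(fused.data, 0.25)
        assert "no valid prediction" in caplog.text

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            soft_vote([])


class TestMajorityVote:
    def test_two_of_three_wins(self):
        labs = [np.array([[[1]]]), np.array([[[1]]]), np.array([[[3]]])]
        vols = [ss.LabelVolume(l.astype(np.uint8), GEOM) for l in labs]
        assert majority_vote(vols).data[0, 0, 0] == 1

    def test_tie_breaks_to_lowest_class(self):
        labs = [np.array([[[0]]]), np.array([[[1]]]), np.array([[[2]]])]
        vols = [ss.LabelVolume(l.astype(np.uint8), GEOM) for l in labs]
        assert majority_vote(vols).data[0, 0, 0] == 0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(6)
        vols = [
            ss.LabelVolume(rng.integers(0, 4, (5, 5, 5)).astype(np.uint8), GEOM)
            for _ in range(5)
        ]
        np.testing.assert_array_equal(
            majority_vote(vols).data, majority_vote(vols[::-1]).data
        )

    def test_argmax_of_soft_equals_majority_for_one_hot_votes(self):
        # exhaustive over all label triples on a single voxel, k = 4:
        # whenever the vote is untied the two fusion rules must agree, and
        # on ties both fall back to the lowest tied class
        for combo in itertools.product(range(4), repeat=3):
            lab = [np.full((1, 1, 1), c, np.uint8) for c in combo]
            maj = majority_vote([ss.LabelVolume(l, GEOM) for l in lab])
            soft = argmax_labels(soft_vote([_prob(l) for l in lab]))
            np.testing.assert_array_equal(soft.data, maj.data)


class TestArgmaxLabels:
    def test_uniform_probability_gives_class_zero(self):
        p = ProbabilityVolume(np.full((2, 2, 2, 4), 0.25, np.float32), GEOM)
        assert np.all(argmax_labels(p).data == 0)


class TestPredictVolume:
    def test_naive_planes_exact_on_crisp_phantom(self, crisp_phantom, oracle_predictor):
        seg = predict_volume(oracle_predictor, crisp_phantom.image, planes=3)
        np.testing.assert_array_equal(seg.data, crisp_phantom.labels.data)

    def test_majority_matches_soft_on_crisp_phantom(self, crisp_phantom, oracle_predictor):
        soft = predict_volume(oracle_predictor, crisp_phantom.image, planes=3, fusion="soft")
        maj = predict_volume(
            oracle_predictor, crisp_phantom.image, planes=3, fusion="majority"
        )
        np.testing.assert_array_equal(soft.data, maj.data)

    def test_nine_planes_high_agreement_on_crisp_phantom(
        self, crisp_phantom, oracle_predictor
    ):
        # rotated planes interpolate across class boundaries, so demand near-
        # but not bit-exact agreement with the ground truth
        seg, probs = predict_volume(
            oracle_predictor, crisp_phantom.image, planes=9, return_probabilities=True
        )
        agree = (seg.data == crisp_phantom.labels.data).mean()
        assert agree >= 0.99
        assert probs.valid_mask.all()  # naive planes cover every voxel

    def test_single_rotated_plane_mask_excludes_corners(self, crisp_phantom, oracle_predictor):
        t = PlaneTransform("r", rotation_axis="p", rotation_deg=45.0)
        pv = predict_plane(oracle_predictor, crisp_phantom.image, t)
        assert pv.valid_mask.any()
        assert not pv.valid_mask.all()

    def test_consensus_overrules_one_biased_plane(self, crisp_phantom, oracle_predictor):
        class BiasedOnFirstPlane:
            """Delegates to the oracle except it always answers background on
            the first plane's slice geometry marker."""

            divisor = 1
            n_classes = 4

            def __init__(self, inner):
                self.inner = inner
                self.calls = 0

            def predict_proba(self, x):
                self.calls += 1
                if self.calls <= np.ceil(crisp_phantom.image.shape[0] / 8):
                    out = np.zeros((x.shape[0], 4) + x.shape[2:], np.float32)
                    out[:, 0] = 1.0
                    return out
                return self.inner.predict_proba(x)

        biased = BiasedOnFirstPlane(oracle_predictor)
        seg = predict_volume(biased, crisp_phantom.image, planes=3, fusion="majority")
        # the two healthy planes outvote the corrupted one everywhere
        np.testing.assert_array_equal(seg.data, crisp_phantom.labels.data)

    def test_unknown_fusion_raises(self, crisp_phantom, oracle_predictor):
        with pytest.raises(ValueError):
            predict_volume(oracle_predictor, crisp_phantom.image, planes=3, fusion="max")


def test_expected_slice_workload_for_scan_batch():
    # fourteen 1200 x 1200 x 1000 volumes sliced along all three principal axes
    shape = (1000, 1200, 1200)
    per_volume = sum(plane_slice_count(shape, t) for t in generate_plane_set(3))
    assert 14 * per_volume == 47_600
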