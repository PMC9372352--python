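import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wmhkit.core import ImageVolume, LabelVolume
from wmhkit.fusion import (build_weight_map, cohort_consistency,
                           consistency_report, fuse_pair,
                           histogram_threshold_proposal, majority_vote)
from oracles import brute_min_distances

SP = (5.0, 1.0, 1.0)


def _lv(data):
    return LabelVolume(np.asarray(data, dtype=np.int16), SP)


def _random_label(rng, shape=(4, 12, 12), p=(0.8, 0.15, 0.05)):
    return _lv(rng.choice(3, size=shape, p=p))


class TestHistogramProposal:
    def test_uniform_flair_yields_empty_proposal(self):
        flair = ImageVolume(np.full((3, 10, 10), 0.4), SP, "flair")
        mask = np.ones((3, 10, 10), bool)
        assert not histogram_threshold_proposal(flair, mask).any()

    def test_bright_blob_recovered(self):
        rng = np.random.default_rng(0)
        data = 0.4 + 0.01 * rng.standard_normal((4, 16, 16))
        blob = np.zeros_like(data, dtype=bool)
        blob[2, 5:9, 5:9] = True
        data[blob] = 0.9  # far above mean + 2.5 SD of the background
        flair = ImageVolume(data, SP, "flair")
        prop = histogram_threshold_proposal(flair, np.ones_like(blob))
        assert np.array_equal(prop, blob)

    def test_k_zero_thresholds_at_mean(self):
        data = np.zeros((2, 4, 4))
        data[1] = 1.0
        flair = ImageVolume(data, SP, "flair")
        prop = histogram_threshold_proposal(flair, np.ones_like(data, bool),
                                            k=0.0, min_voxels=1)
        assert np.array_equal(prop, data > data.mean())

    def test_empty_mask_rejected(self):
        flair = ImageVolume(np.ones((2, 4, 4)), SP, "flair")
        with pytest.raises(ValueError):
            histogram_threshold_proposal(flair, np.zeros((2, 4, 4), bool))


class TestFusePair:
    def test_identical_raters_all_definite(self):
        rng = np.random.default_rng(1)
        r = _random_label(rng)
        fus = fuse_pair(r, r)
        assert not fus.suspected_wmh.any()
        assert np.array_equal(fus.definite_wmh, r.data == 1)
        assert np.array_equal(fus.union_label.data, r.data)

    def test_disjoint_single_voxels_all_suspected(self):
        a = np.zeros((1, 4, 4), dtype=np.int16)
        b = np.zeros_like(a)
        a[0, 1, 1] = 1
        b[0, 2, 2] = 1
        fus = fuse_pair(_lv(a), _lv(b))
        assert not fus.definite_wmh.any()
        assert fus.suspected_wmh.sum() == 2

    def test_overlapping_squares_counts(self):
        """4x4 squares overlapping in 3x3: definite 9, suspected 7+7=14."""
        a = np.zeros((1, 10, 10), dtype=np.int16)
        b = np.zeros_like(a)
        a[0, 0:4, 0:4] = 1
        b[0, 1:5, 1:5] = 1
        fus = fuse_pair(_lv(a), _lv(b))
        assert fus.definite_wmh.sum() == 9
        assert fus.suspected_wmh.sum() == 14

    def test_symmetry_and_partition_invariant(self):
        rng = np.random.default_rng(2)
        a, b = _random_label(rng), _random_label(rng)
        f1, f2 = fuse_pair(a, b), fuse_pair(b, a)
        assert np.array_equal(f1.union_label.data, f2.union_label.data)
        assert np.array_equal(f1.definite_wmh, f2.definite_wmh)
        union_wmh = f1.union_label.data == 1
        assert np.array_equal(f1.definite_wmh | f1.suspected_wmh, union_wmh)
        assert not (f1.definite_wmh & f1.suspected_wmh).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_pair(_lv(np.zeros((1, 4, 4))), _lv(np.zeros((1, 4, 5))))


class TestWeightMap:
    def test_definite_weight_two_background_one(self):
        rng = np.random.default_rng(3)
        fus = fuse_pair(_random_label(rng), _random_label(rng))
        wm = build_weight_map(fus)
        assert np.all(wm.weights[fus.definite_wmh] == 2.0)
        sus = wm.weights[fus.suspected_wmh]
        assert np.all((sus >= 1.0) & (sus <= 2.0))
        other = ~fus.definite_wmh & ~fus.suspected_wmh
        assert np.all(wm.weights[other] == 1.0)

    def test_eq4_half_distance_gives_weight_1_5(self):
        """Two-component fixture evaluated by hand against the linear decay."""
        a = np.zeros((1, 3, 41), dtype=np.int16)
        b = np.zeros_like(a)
        # one definite voxel at x=0 (both raters agree)
        a[0, 1, 0] = b[0, 1, 0] = 1
        # suspected voxels at x=10 and x=20 (rater a only)
        a[0, 1, 10] = a[0, 1, 20] = 1
        fus = fuse_pair(_lv(a), _lv(b))
        wm = build_weight_map(fus, spacing=(5.0, 1.0, 1.0))
        # brute-force: dis = 10 and 20 mm to the definite centroid;
        # dis_max = 20 -> f = 0.5 and 0.0
        assert wm.weights[0, 1, 10] == pytest.approx(1.5)
        assert wm.weights[0, 1, 20] == pytest.approx(1.0)
        assert wm.weights[0, 1, 0] == 2.0

    def test_nearest_component_by_brute_force(self):
        rng = np.random.default_rng(8)
        a = _random_label(rng, p=(0.9, 0.08, 0.02))
        b = _random_label(rng, p=(0.9, 0.08, 0.02))
        fus = fuse_pair(a, b)
        wm = build_weight_map(fus)
        from scipy import ndimage
        lab, n = ndimage.label(fus.definite_wmh, np.ones((3, 3, 3), bool))
        cents = np.array(ndimage.center_of_mass(fus.definite_wmh, lab,
                                                range(1, n + 1)))
        sus = np.argwhere(fus.suspected_wmh)
        dis = brute_min_distances(sus, cents, SP)
        expected = 1.0 + (1.0 - dis / dis.max()) if dis.max() > 0 else \
            np.ones_like(dis)
        assert np.allclose(wm.weights[tuple(sus.T)], expected)

    def test_no_definite_gives_unit_suspected_weights(self):
        a = np.zeros((1, 4, 4), dtype=np.int16)
        b = np.zeros_like(a)
        a[0, 1, 1] = a[0, 2, 2] = 1
        fus = fuse_pair(_lv(a), _lv(b))
        wm = build_weight_map(fus)
        assert np.all(wm.weights[fus.suspected_wmh] == 1.0)

    def test_single_suspected_voxel_weight_one(self):
        a = np.zeros((1, 6, 6), dtype=np.int16)
        b = np.zeros_like(a)
        a[0, 2, 2] = b[0, 2, 2] = 1  # definite
        a[0, 4, 4] = 1               # lone suspected voxel: dis == dis_max
        fus = fuse_pair(_lv(a), _lv(b))
        wm = build_weight_map(fus)
        assert wm.weights[0, 4, 4] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_invariant(self, seed):
        rng = np.random.default_rng(seed)
        fus = fuse_pair(_random_label(rng, shape=(3, 8, 8)),
                        _random_label(rng, shape=(3, 8, 8)))
        w = build_weight_map(fus).weights
        assert w.min() >= 1.0 and w.max() <= 2.0


class TestMajorityVote:
    def test_identical_inputs_identity(self):
        rng = np.random.default_rng(4)
        r = _random_label(rng)
        assert np.array_equal(majority_vote([r] * 5).data, r.data)

    def test_strict_majority_wins(self):
        vols = [_lv(np.full((1, 1, 1), v)) for v in (1, 1, 1, 0, 0)]
        assert majority_vote(vols).data[0, 0, 0] == 1

    def test_tie_goes_to_lower_class_and_is_counted(self):
        vols = [_lv(np.full((1, 1, 1), v)) for v in (0, 0, 1, 1, 2)]
        out, ties = majority_vote(vols, return_ties=True)
        assert out.data[0, 0, 0] == 0
        assert ties == 1

    def test_matches_per_voxel_tally_oracle(self):
        rng = np.random.default_rng(5)
        vols = [_random_label(rng, shape=(3, 6, 6)) for _ in range(5)]
        out = majority_vote(vols)
        stack = np.stack([v.data for v in vols])
        for idx in np.ndindex(out.data.shape):
            votes = np.bincount(stack[(slice(None),) + idx], minlength=3)
            assert out.data[idx] == votes.argmax()  # argmax: lowest on ties

    def test_fewer_than_three_rejected(self):
        r = _lv(np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            majority_vote([r, r])


class TestConsistency:
    def test_identical_masks_pass(self):
        rng = np.random.default_rng(6)
        r = _random_label(rng)
        rep = consistency_report(r, r)
        assert rep.dice == 1.0 and rep.passed

    def test_disjoint_masks_fail(self):
        a = np.zeros((1, 4, 4), dtype=np.int16)
        b = np.zeros_like(a)
        a[0, 0, 0] = 1
        b[0, 3, 3] = 1
        rep = consistency_report(_lv(a), _lv(b))
        assert rep.dice == 0.0 and not rep.passed

    def test_hand_computed_dice(self):
        """16- and 16-voxel masks with 9-voxel overlap: Dice 18/32."""
        a = np.zeros((1, 10, 10), dtype=np.int16)
        b = np.zeros_like(a)
        a[0, 0:4, 0:4] = 1
        b[0, 1:5, 1:5] = 1
        rep = consistency_report(_lv(a), _lv(b))
        assert rep.dice == pytest.approx(0.5625)
        assert rep.passed

    def test_cohort_report_pearson(self):
        rng = np.random.default_rng(7)
        pairs = [(_random_label(rng), _random_label(rng)) for _ in range(6)]
        table, pearson = cohort_consistency(pairs)
        assert len(table) == 6
        assert -1.0 <= pearson <= 1.0
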