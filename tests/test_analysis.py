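"""Threshold derivation and agreement statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qperf import (
    bland_altman,
    dice,
    mann_whitney,
    patient_summary,
    roc_youden,
    segment_burden,
    segment_mbf,
    segment_positive,
    territory_summary,
    threshold_map,
)
from qperf.analysis import TERRITORIES


class TestRocYouden:
    def test_perfectly_separated_classes(self):
        v = np.array([1.0] * 10 + [3.0] * 10)
        y = np.array([True] * 10 + [False] * 10)
        res = roc_youden(v, y)
        assert res.auc == pytest.approx(1.0)
        assert res.cutoff == pytest.approx(2.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert res.accuracy == pytest.approx(1.0)

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(1234)
        v = rng.normal(2.0, 0.6, size=2000)
        y = rng.permutation(np.arange(2000) < 1000)
        res = roc_youden(v, y)
        assert res.auc == pytest.approx(0.5, abs=0.03)

    def test_two_gaussian_cutoff_matches_grid_search_oracle(self):
        rng = np.random.default_rng(99)
        pos = rng.normal(1.1, 0.4, size=5000)
        neg = rng.normal(2.35, 0.55, size=5000)
        v = np.concatenate([pos, neg])
        y = np.concatenate([np.ones(5000, bool), np.zeros(5000, bool)])
        res = roc_youden(v, y)
        # independent brute-force: scan a dense cutoff grid, maximise J
        grid = np.linspace(0.0, 4.0, 4001)
        sens = (pos[None, :] < grid[:, None]).mean(axis=1)
        spec = (neg[None, :] >= grid[:, None]).mean(axis=1)
        oracle = grid[np.argmax(sens + spec - 1.0)]
        assert res.cutoff == pytest.approx(oracle, abs=0.05)

    def test_auc_invariant_under_monotone_transform_with_flipped_polarity(self):
        rng = np.random.default_rng(5)
        v = rng.gamma(4.0, 0.5, size=400)
        y = rng.random(400) < 1.0 / (1.0 + np.exp(3 * (v - 2.0)))
        base = roc_youden(v, y)
        # strictly decreasing transform + flipped polarity == negated input
        transformed = roc_youden(-np.exp(-v), y)
        assert transformed.auc == pytest.approx(base.auc, abs=1e-12)
        assert transformed.youden_j == pytest.approx(base.youden_j, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden(np.arange(5.0), np.ones(5, bool))


def _random_slice(rng, n_sect, offset, shape=(24, 24)):
    labels = np.zeros(shape, int)
    myo = rng.random(shape) < 0.4
    labels[myo] = offset + rng.integers(0, n_sect, size=int(myo.sum())) + 1
    return labels


class _FakeMap:
    def __init__(self, mbf, valid):
        self.mbf = mbf
        self.valid_mask = valid
        self.myo_mask = valid

    @property
    def values(self):
        return self.mbf[self.valid_mask]


class TestSegmentSummaries:
    def test_constant_map_gives_constant_segments(self):
        rng = np.random.default_rng(0)
        labels = [_random_slice(rng, 6, 0), _random_slice(rng, 6, 6),
                  _random_slice(rng, 4, 12)]
        maps = [_FakeMap(np.full((24, 24), 1.9), lab > 0) for lab in labels]
        seg = segment_mbf(maps, labels)
        present = ~np.isnan(seg)
        np.testing.assert_allclose(seg[present], 1.9)

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(8)
        labels = [_random_slice(rng, 6, 0), _random_slice(rng, 6, 6),
                  _random_slice(rng, 4, 12)]
        maps = [_FakeMap(rng.uniform(0.5, 4.0, (24, 24)), lab > 0) for lab in labels]
        seg = segment_mbf(maps, labels)
        for sid in range(1, 17):
            vals = np.concatenate([
                m.mbf[lab == sid] for m, lab in zip(maps, labels)
            ])
            if vals.size:
                assert seg[sid - 1] == pytest.approx(vals.mean())
            else:
                assert np.isnan(seg[sid - 1])

    def test_positivity_is_strictly_more_than_half(self):
        labels = np.zeros((4, 4), int)
        labels[:2, :2] = 1  # 4 pixels in segment 1
        mask = np.zeros((4, 4), bool)
        mask[0, :2] = True  # exactly half covered
        assert not segment_positive(mask, labels)[0]
        mask[1, 0] = True  # 3 of 4 covered
        assert segment_positive(mask, labels)[0]

    def test_fully_covered_segment_positive(self):
        labels = np.zeros((4, 4), int)
        labels[:, :] = 5
        assert segment_positive(np.ones((4, 4), bool), labels)[4]

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(4)
        labels = [_random_slice(rng, 6, 0), _random_slice(rng, 6, 6),
                  _random_slice(rng, 4, 12)]
        masks = [(lab > 0) & (rng.random(lab.shape) < 0.5) for lab in labels]
        flags = segment_positive(masks, labels)
        for sid in range(1, 17):
            total = sum(int((lab == sid).sum()) for lab in labels)
            inside = sum(int((m & (lab == sid)).sum())
                         for m, lab in zip(masks, labels))
            expected = total > 0 and inside > total / 2
            assert flags[sid - 1] == expected


class TestTerritoryAndPatient:
    def test_mean_of_two_lowest_segments(self):
        seg = np.full(16, np.nan)
        lad = np.array(TERRITORIES["LAD"]) - 1
        seg[lad] = [2.0, 1.0, 3.0, 4.0, 2.5, 0.5]
        values, flags = territory_summary(seg, np.zeros(16, bool))
        assert values[0] == pytest.approx((0.5 + 1.0) / 2)
        assert not flags.any()

    def test_one_positive_segment_flags_territory_and_patient(self):
        seg_v = np.full(16, 2.0)
        seg_f = np.zeros(16, bool)
        seg_f[8] = True  # segment 9 is RCA territory
        values, flags = territory_summary(seg_v, seg_f)
        assert list(flags) == [False, True, False]
        pmap = _FakeMap(np.full((5, 5), 2.0), np.ones((5, 5), bool))
        mbf, positive = patient_summary([pmap], flags)
        assert mbf == pytest.approx(2.0)
        assert positive

    def test_matches_sort_and_average_oracle(self):
        rng = np.random.default_rng(10)
        seg_v = rng.uniform(0.5, 4.0, 16)
        seg_f = rng.random(16) < 0.3
        values, flags = territory_summary(seg_v, seg_f)
        for i, name in enumerate(("LAD", "RCA", "LCX")):
            idx = np.array(TERRITORIES[name]) - 1
            assert values[i] == pytest.approx(np.sort(seg_v[idx])[:2].mean())
            assert flags[i] == seg_f[idx].any()

    def test_patient_mean_pools_all_valid_pixels(self):
        rng = np.random.default_rng(2)
        maps = []
        pooled = []
        for _ in range(3):
            mbf = rng.uniform(0.5, 4, (10, 10))
            valid = rng.random((10, 10)) < 0.5
            mbf[~valid] = np.nan
            maps.append(_FakeMap(mbf, valid))
            pooled.append(mbf[valid])
        mbf, _ = patient_summary(maps, np.zeros(3, bool))
        assert mbf == pytest.approx(np.concatenate(pooled).mean())


class TestDice:
    def test_identical_disjoint_and_partial(self):
        a = np.zeros(200, bool)
        a[:100] = True
        assert dice(a, a) == 1.0
        b = np.zeros(200, bool)
        b[100:200] = True
        assert dice(a, b) == 0.0
        c = np.zeros(200, bool)
        c[32:132] = True  # |A|=|B|=100, overlap 68
        assert dice(a, c) == pytest.approx(0.68)

    def test_both_empty_is_perfect_agreement(self):
        assert dice(np.zeros(10, bool), np.zeros(10, bool)) == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(50) < 0.3
        b = rng.random(50) < 0.3
        assert dice(a, b) == dice(b, a)
        if a.any():
            assert dice(a, a) == 1.0


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([5.0, 10.0, 20.0, 40.0])
        ba = bland_altman(x, x)
        assert ba.mean_bias == 0.0
        assert ba.loa_low == 0.0 and ba.loa_high == 0.0
        assert ba.prop_beta == 0.0

    def test_constant_offset(self):
        m = np.array([5.0, 10.0, 20.0, 40.0])
        ba = bland_altman(m, m + 5.0)
        assert ba.mean_bias == pytest.approx(-5.0)
        assert ba.prop_beta == pytest.approx(0.0, abs=1e-12)

    def test_proportional_bias_recovered(self):
        rng = np.random.default_rng(21)
        mean_burden = rng.uniform(0, 60, 200)
        d = 0.5 * mean_burden + rng.normal(0, 1.0, 200)
        manual = mean_burden + d / 2
        quant = mean_burden - d / 2
        ba = bland_altman(manual, quant)
        assert ba.prop_beta == pytest.approx(0.5, abs=0.03)
        assert ba.prop_p < 0.001

    def test_equal_masks_imply_zero_bias_and_unit_dice(self):
        rng = np.random.default_rng(3)
        masks = [rng.random((12, 12)) < 0.2 for _ in range(4)]
        myo = [np.ones((12, 12), bool)] * 4
        from qperf import burden

        burdens = [burden(m, y) for m, y in zip(masks, myo)]
        ba = bland_altman(burdens, burdens)
        assert ba.mean_bias == 0.0
        assert all(dice(m, m) == 1.0 for m in masks)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestMannWhitney:
    def test_exact_small_sample_matches_enumeration(self):
        a = np.array([1.3, 2.6, 0.7])
        b = np.array([2.1, 3.4, 1.9])
        u, p = mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1.0
        u_obs = ranks[:3].sum() - 3 * 4 / 2
        u_obs = min(u_obs, 9 - u_obs)
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            r = ranks[list(combo)].sum() - 3 * 4 / 2
            stat = min(r, 9 - r)
            total += 1
            if stat <= u_obs:
                count += 1
        assert p == pytest.approx(count / total)

    def test_complete_separation(self):
        a = np.arange(10.0)
        b = np.arange(100.0, 110.0)
        u, p = mann_whitney(a, b)
        assert u == 0.0
        u2, _ = mann_whitney(b, a)
        assert u2 == 100.0


class TestThresholdMap:
    def test_cutoff_outside_value_range(self):
        grid = np.array([[1.0, 2.0], [3.0, np.nan]])
        none = threshold_map(grid, 0.5)
        assert np.nansum(none) == 0
        allpos = threshold_map(grid, 10.0)
        assert np.nansum(allpos) == 3
        assert np.isnan(allpos[1, 1])


class TestSegmentBurden:
    def test_moves_in_steps_of_6_25_percent(self):
        values = sorted(
            {segment_burden([i < k for i in range(16)]) for k in range(17)}
        )
        steps = np.diff(values)
        np.testing.assert_allclose(steps, 6.25)
        assert values[0] == 0.0 and values[-1] == 100.0
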