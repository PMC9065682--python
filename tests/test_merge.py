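import numpy as np
import pytest

from polyreco.errors import LogicError, ParameterError
from polyreco.merge import (
    MergeParams,
    compute_gap,
    interval_gap,
    merge_unit,
    should_merge,
)

from conftest import make_box


class TestIntervalGap:
    @pytest.mark.parametrize("a,b,expected", [
        ((446, 1089), (1155, 1267), 66),   # adjacent regions on one chromosome
        ((0, 10), (5, 20), -5),            # overlap depth
        ((0, 10), (10, 20), 0),            # touching
        ((100, 200), (0, 40), 60),         # order-independent
    ])
    def test_signed_distance(self, a, b, expected):
        assert interval_gap(*a, *b) == expected
        assert interval_gap(*b, *a) == expected

    def test_bad_interval_rejected(self):
        with pytest.raises(ParameterError):
            interval_gap(5, 1, 0, 10)


class TestComputeGap:
    def test_mean_of_positive_gaps(self):
        boxes = [make_box(id=1, y=(100, 200)), make_box(id=2, y=(60, 90)),
                 make_box(id=3, y=(10, 40))]
        assert compute_gap(boxes) == pytest.approx(15.0)  # mean(10, 20)

    def test_single_box_gives_zero(self):
        assert compute_gap([make_box()]) == 0.0

    def test_overlapping_neighbours_excluded(self):
        boxes = [make_box(id=1, y=(50, 200)), make_box(id=2, y=(0, 100))]
        assert compute_gap(boxes) == 0.0

    def test_empty_unit_rejected(self):
        with pytest.raises(ParameterError):
            compute_gap([])

    def test_matches_sort_and_scan_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            boxes = []
            for i in range(5):
                lo = int(rng.integers(0, 900))
                boxes.append(make_box(id=i + 1,
                                      y=(lo, lo + int(rng.integers(5, 120)))))
            ordered = sorted(boxes, key=lambda b: -b.l_y)
            gaps = [a.r_y - b.l_y for a, b in zip(ordered, ordered[1:])
                    if a.r_y - b.l_y > 0]
            expected = sum(gaps) / len(gaps) if gaps else 0.0
            assert compute_gap(boxes) == pytest.approx(expected)


class TestShouldMerge:
    P = MergeParams(gap=15.0, slen=100.0)

    def test_disjoint_within_both_thresholds(self):
        a = make_box(id=1, y=(100, 200), x=(0, 50))
        b = make_box(id=2, y=(80, 95), x=(60, 90))   # y_gap=5, x_gap=10
        assert should_merge(a, b, self.P)

    def test_y_gap_at_threshold_is_inclusive(self):
        a = make_box(id=1, y=(100, 200), x=(0, 50))
        b = make_box(id=2, y=(0, 85), x=(50, 90))    # y_gap=15=gap, x_gap=0
        assert should_merge(a, b, self.P)

    def test_y_overlap_x_gap_at_slen_is_exclusive(self):
        a = make_box(id=1, y=(0, 100), x=(0, 50))
        b = make_box(id=2, y=(50, 150), x=(150, 200))  # x_gap=100=slen
        assert not should_merge(a, b, self.P)
        b_closer = make_box(id=2, y=(50, 150), x=(149, 200))
        assert should_merge(a, b_closer, self.P)

    def test_x_overlap_uses_gap_bound(self):
        a = make_box(id=1, y=(100, 200), x=(0, 50))
        near = make_box(id=2, y=(0, 90), x=(40, 80))    # y_gap=10 <= gap
        far = make_box(id=3, y=(0, 80), x=(40, 80))     # y_gap=20 > gap
        assert should_merge(a, near, self.P)
        assert not should_merge(a, far, self.P)

    def test_nested_boxes_merge(self):
        outer = make_box(id=1, y=(0, 100), x=(0, 100))
        inner = make_box(id=2, y=(20, 40), x=(20, 40))
        assert should_merge(outer, inner, self.P)

    def test_y_gap_beyond_gap_blocks_disjoint_merge(self):
        a = make_box(id=1, y=(100, 200), x=(0, 50))
        b = make_box(id=2, y=(0, 80), x=(0, 50))     # y_gap=20 > gap
        assert not should_merge(a, b, self.P)

    def test_cross_unit_pair_is_a_logic_error(self):
        a = make_box(chr1="1")
        b = make_box(chr1="2")
        with pytest.raises(LogicError):
            should_merge(a, b, self.P)


class TestMergeUnit:
    def test_single_box_unchanged(self):
        b = make_box(num=10)
        out = merge_unit([b], MergeParams(gap=10, slen=50))
        assert len(out) == 1 and out[0].num == 10

    def test_min_num_filter_applies_before_merging(self):
        big = make_box(id=1, y=(0, 100), num=10)
        small = make_box(id=2, y=(105, 200), num=2)
        out = merge_unit([big, small], MergeParams(gap=10, slen=50, min_num=5))
        assert len(out) == 1 and out[0].num == 10

    def test_chain_merges_transitively(self):
        # A-B and B-C mergeable, A-C too far apart directly
        a = make_box(id=1, y=(200, 300), x=(0, 30), num=10)
        b = make_box(id=2, y=(140, 190), x=(35, 60), num=10)
        c = make_box(id=3, y=(80, 130), x=(65, 90), num=10)
        p = MergeParams(gap=10.0, slen=40.0)
        assert should_merge(a, b, p) and should_merge(b, c, p)
        assert not should_merge(a, c, p)
        out = merge_unit([a, b, c], p)
        assert len(out) == 1
        merged = out[0]
        assert (merged.l_y, merged.r_y, merged.l_x, merged.r_x) == (300, 80, 0, 90)
        assert merged.num == 30

    def test_far_regions_stay_separate(self):
        top = make_box(id=1, y=(1155, 1267), x=(592, 671), num=56)
        mid = make_box(id=2, y=(446, 1089), x=(78, 605), num=239)
        out = merge_unit([top, mid], MergeParams(gap=60.0, slen=213.5))
        assert len(out) == 2  # y_gap=66 exceeds the unit's mean gap
        assert [b.id for b in out] == [1, 2]
        assert out[0].l_y == 1267 and out[1].delta_y == 643

    def test_ids_reassigned_top_to_bottom(self):
        lo = make_box(id=1, y=(0, 50), x=(0, 10), num=10)
        hi = make_box(id=2, y=(500, 600), x=(500, 510), num=10)
        out = merge_unit([lo, hi], MergeParams(gap=5, slen=20))
        assert [(b.id, b.l_y) for b in out] == [(1, 600), (2, 50)]

    @pytest.mark.parametrize("trial", range(15))
    def test_total_num_conserved_and_boxes_tight(self, trial):
        rng = np.random.default_rng(500 + trial)
        boxes = []
        for i in range(int(rng.integers(2, 10))):
            y0, x0 = int(rng.integers(0, 800)), int(rng.integers(0, 800))
            boxes.append(make_box(
                id=i + 1, y=(y0, y0 + int(rng.integers(10, 150))),
                x=(x0, x0 + int(rng.integers(10, 150))),
                num=int(rng.integers(5, 40))))
        from polyreco.merge import compute_gap
        p = MergeParams(gap=compute_gap(boxes), slen=150.0)
        out = merge_unit(boxes, p)
        assert sum(b.num for b in out) == sum(b.num for b in boxes)
        # no remaining pair is mergeable (fixpoint reached)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert not should_merge(out[i], out[j], p)

    @pytest.mark.parametrize("trial", range(10))
    def test_result_independent_of_input_order(self, trial):
        rng = np.random.default_rng(900 + trial)
        boxes = []
        for i in range(6):
            y0, x0 = int(rng.integers(0, 500)), int(rng.integers(0, 500))
            boxes.append(make_box(
                id=i + 1, y=(y0, y0 + int(rng.integers(10, 120))),
                x=(x0, x0 + int(rng.integers(10, 120))), num=10))
        p = MergeParams(gap=compute_gap(boxes), slen=120.0)
        baseline = {(b.l_x, b.l_y, b.r_x, b.r_y, b.num)
                    for b in merge_unit(boxes, p)}
        perm = list(boxes)
        rng.shuffle(perm)
        perm = [b.with_id(i + 1) for i, b in enumerate(perm)]
        assert {(b.l_x, b.l_y, b.r_x, b.r_y, b.num)
                for b in merge_unit(perm, p)} == baseline
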