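"""Pair enumeration combinatorics, FAR/FRR, ROC sweep, EER, separation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainprint import (
    DatasetIndex,
    count_genuine_pairs,
    count_genuine_pairs_dataset,
    enumerate_genuine_pairs,
    enumerate_imposter_pairs,
    eer,
    far_frr_at_threshold,
    roc_curve,
    score_histogram,
    separation_gap,
)

from conftest import make_volume


def structure_index(scans_per_visit_by_subject):
    """Index of 1-voxel volumes realizing the given visit structures."""
    idx = DatasetIndex()
    for subject, visits in scans_per_visit_by_subject.items():
        for v, m in enumerate(visits, start=1):
            for s in range(1, m + 1):
                idx.add(make_volume(np.zeros((1, 1, 1)), subject=subject,
                                    visit=v, scan=s))
    return idx


class TestGenuinePairs:
    @pytest.mark.parametrize(
        "visits, mode, expected",
        [
            ([3, 3], "different_visit", 9),
            ([3], "different_visit", 0),
            ([7], "different_visit", 0),
            ([3], "same_visit", 3),
            ([4, 3, 3], "different_visit", 33),
            ([4, 3, 3], "same_visit", 6 + 3 + 3),
            ([2, 2], "different_visit", 4),  # C(V,2)*m^2 with V=2, m=2
        ],
    )
    def test_counts_and_enumeration_agree(self, visits, mode, expected):
        assert count_genuine_pairs(visits, mode) == expected
        idx = structure_index({"A": visits})
        pairs = enumerate_genuine_pairs(idx, mode)
        assert len(pairs) == expected
        assert len(set(map(frozenset, map(lambda p: (p[0], p[1]), pairs)))) == len(pairs)

    def test_pair_identity_constraints(self):
        idx = structure_index({"A": [3, 2], "B": [2, 2]})
        for a, b in enumerate_genuine_pairs(idx, "same_visit"):
            assert a[0] == b[0] and a[1] == b[1] and a[2] != b[2]
        for a, b in enumerate_genuine_pairs(idx, "different_visit"):
            assert a[0] == b[0] and a[1] != b[1]

    def test_dataset_total(self):
        idx = structure_index({"A": [3, 3], "B": [2], "C": [4, 3, 3]})
        for mode in ("same_visit", "different_visit"):
            assert count_genuine_pairs_dataset(idx, mode) == len(
                enumerate_genuine_pairs(idx, mode)
            )

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            count_genuine_pairs([], "same_visit")

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 4), min_size=1, max_size=4),
           st.sampled_from(["same_visit", "different_visit"]))
    def test_closed_form_equals_enumeration(self, visits, mode):
        """Closed-form pair count vs brute-force enumeration, random
        visit structures."""
        idx = structure_index({"A": visits})
        assert count_genuine_pairs(visits, mode) == len(
            enumerate_genuine_pairs(idx, mode)
        )


class TestImposterPairs:
    @pytest.mark.parametrize("n, expected", [(2, 1), (10, 45), (150, 11175)])
    def test_one_volume_per_subject_counts(self, n, expected):
        idx = structure_index({f"S{i:04d}": [2] for i in range(n)})
        pairs = enumerate_imposter_pairs(idx)
        assert len(pairs) == expected
        assert all(a[0] != b[0] for a, b in pairs)
        assert all(a[1:] == (1, 2) and b[1:] == (1, 2) for a, b in pairs)

    def test_missing_selected_scan(self):
        idx = structure_index({"A": [2], "B": [1]})  # B lacks scan 2
        with pytest.raises(KeyError):
            enumerate_imposter_pairs(idx)
        assert len(enumerate_imposter_pairs(idx, selector=(1, 1))) == 1

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            enumerate_imposter_pairs(structure_index({"A": [3]}))


class TestFarFrr:
    def test_direct_count(self):
        far, frr = far_frr_at_threshold([80, 90], [60, 85], 85)
        assert (far, frr) == (0.0, 50.0)

    def test_extreme_thresholds(self):
        g, i = [50, 60], [10, 20]
        assert far_frr_at_threshold(g, i, 0) == (100.0, 0.0)
        assert far_frr_at_threshold(g, i, 99) == (0.0, 100.0)

    def test_score_equal_to_threshold_accepted(self):
        # a genuine score at t is not rejected; an imposter at t not accepted
        far, frr = far_frr_at_threshold([70], [70], 70)
        assert (far, frr) == (0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            far_frr_at_threshold([], [1], 0)


class TestRoc:
    def test_separable_scores_reach_origin(self):
        curve = roc_curve([90, 95], [10, 20])
        assert any(far == 0.0 and frr == 0.0 for _, far, frr in curve.points)

    def test_interleaved_scores_contain_midpoint(self):
        curve = roc_curve([1, 3], [2, 4])
        assert any(far == 50.0 and frr == 50.0 for _, far, frr in curve.points)

    def test_endpoints(self):
        curve = roc_curve([30, 60], [20, 70])
        _, far0, frr0 = curve.points[0]
        _, far1, frr1 = curve.points[-1]
        assert (far0, frr0) == (100.0, 0.0)
        assert (far1, frr1) == (0.0, 100.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_rates(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(70, 15, 25).clip(0, 100)
        i = rng.normal(40, 15, 30).clip(0, 100)
        curve = roc_curve(g, i)
        fars = [far for _, far, _ in curve.points]
        frrs = [frr for _, _, frr in curve.points]
        assert (np.diff(fars) <= 0).all()
        assert (np.diff(frrs) >= 0).all()


def eer_fine_grid_oracle(genuine, imposter, step=0.01):
    """Exhaustive fine-grid threshold search for the equal-error point:
    (FAR + FRR)/2 at the grid threshold minimizing |FAR - FRR|."""
    g = np.sort(np.asarray(genuine, dtype=float))
    i = np.sort(np.asarray(imposter, dtype=float))
    lo = min(g[0], i[0]) - 1.0
    hi = max(g[-1], i[-1]) + 1.0
    ts = np.arange(lo, hi + step, step)
    frr = 100.0 * np.searchsorted(g, ts, side="left") / g.size
    far = 100.0 * (i.size - np.searchsorted(i, ts, side="right")) / i.size
    k = np.argmin(np.abs(far - frr))
    return (far[k] + frr[k]) / 2.0


class TestEer:
    def test_fully_separated(self):
        res = eer(roc_curve([90, 95], [10, 20]))
        assert res.eer == 0.0
        assert res.exact_crossing

    def test_interleaved(self):
        res = eer(roc_curve([1, 3], [2, 4]))
        assert res.eer == 50.0

    def test_fully_inverted(self):
        res = eer(roc_curve([10, 20], [90, 95]))
        assert res.eer == 100.0

    def test_eer_within_bounds(self):
        res = eer(roc_curve([50, 55, 60], [45, 52, 58]))
        assert 0.0 <= res.eer <= 100.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_fine_grid_search(self, seed):
        # score sets large enough that the per-pair rate quantum (100/n)
        # is well below the 0.5 pp agreement bound
        rng = np.random.default_rng(seed)
        g = rng.normal(65, 18, 300).clip(0, 100)
        i = rng.normal(40, 18, 400).clip(0, 100)
        res = eer(roc_curve(g, i))
        assert res.eer == pytest.approx(eer_fine_grid_oracle(g, i), abs=0.5)


class TestSeparationGap:
    def test_reference_gap_values(self):
        # a separable experiment: highest imposter 83.46 < lowest genuine 86.03
        assert separation_gap([86.03], [83.46]) == (83.46, 86.03, True)

    def test_overlapping(self):
        assert separation_gap([50], [60]) == (60.0, 50.0, False)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_separable_iff_zero_eer(self, seed):
        rng = np.random.default_rng(seed)
        shift = rng.uniform(-30, 60)
        g = rng.normal(50 + shift, 10, 20).clip(0, 100)
        i = rng.normal(40, 10, 20).clip(0, 100)
        *_, separable = separation_gap(g, i)
        res = eer(roc_curve(g, i))
        assert separable == (res.eer == 0.0)


class TestScoreHistogram:
    def test_single_score(self):
        bins = score_histogram([95], 5)
        assert sum(p for _, p in bins) == pytest.approx(100.0)
        assert [(c, p) for c, p in bins if p > 0] == [(97.5, 100.0)]

    def test_uniform_scores(self):
        bins = score_histogram([10, 30, 50, 70], 20)
        nonzero = [(c, p) for c, p in bins if p > 0]
        assert nonzero == [(10.0, 25.0), (30.0, 25.0), (50.0, 25.0), (70.0, 25.0)]

    def test_score_100_counted(self):
        bins = score_histogram([100.0], 2.5)
        assert sum(p for _, p in bins) == pytest.approx(100.0)

    def test_empty_and_bad_width_rejected(self):
        with pytest.raises(ValueError):
            score_histogram([], 5)
        with pytest.raises(ValueError):
            score_histogram([50], 0)
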