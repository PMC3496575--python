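import numpy as np
import pytest

from twostagefdr.mtp import bh_stepup
from twostagefdr.selection import (
    SelectionRule,
    select,
    select_fdrs,
    select_fixed_threshold,
    select_top_k,
)


class TestFixedThreshold:
    def test_direct_comparison(self):
        sel = select_fixed_threshold([0.5, 0.05, 0.2], 0.1)
        assert list(sel.selected) == [False, True, False]
        assert sel.m2 == 1 and sel.gamma1_effective == 0.1 and not sel.stopped

    def test_nothing_passes(self):
        sel = select_fixed_threshold([0.5, 0.4], 0.01)
        assert sel.m2 == 0 and not sel.stopped

    def test_everything_passes(self):
        sel = select_fixed_threshold([0.1, 0.5, 0.9], 0.999)
        assert sel.m2 == 3


class TestTopK:
    def test_smallest_two_selected(self):
        sel = select_top_k([0.5, 0.01, 0.2, 0.9], 2)
        assert list(sel.selected) == [False, True, True, False]
        assert sel.gamma1_effective == 0.2

    def test_select_all(self):
        sel = select_top_k([0.3, 0.7, 0.1], 3)
        assert sel.m2 == 3 and sel.gamma1_effective == 0.7

    def test_boundary_ties_broken_by_stable_order(self):
        sel = select_top_k([0.1, 0.2, 0.2, 0.9], 2)
        assert list(sel.selected) == [True, True, False, False]
        assert sel.gamma1_effective == 0.2
        assert sel.m2 == 2  # exactly m2_target despite the tie

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            select_top_k([0.1, 0.2], 0)
        with pytest.raises(ValueError):
            select_top_k([0.1, 0.2], 3)


class TestFDRS:
    def test_stepup_enumeration(self):
        sel = select_fdrs([0.01, 0.02, 0.9], 0.1)
        assert list(sel.selected) == [True, True, False]
        assert sel.m2 == 2
        assert sel.gamma1_effective == pytest.approx(2 * 0.1 / 3)

    def test_global_null_extreme_stops(self):
        sel = select_fdrs([1.0, 1.0, 1.0], 0.1)
        assert sel.stopped and sel.m2 == 0
        assert np.isnan(sel.gamma1_effective)

    def test_ms_floor_raises_threshold_only(self):
        p1 = [0.001, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95]
        sel = select_fdrs(p1, 0.2, ms=3)
        assert sel.m2 == 1  # only p_(1) survives BH at 0.2
        assert list(sel.selected) == [True] + [False] * 9  # mask not enlarged
        assert sel.gamma1_effective == pytest.approx(0.3)  # p_(3) floor active

    def test_gamma1_dominates_selected_pvalues(self, rng):
        for _ in range(50):
            p1 = rng.uniform(size=40)
            p1[:5] *= 0.01
            sel = select_fdrs(p1, 0.25, ms=6)
            if sel.stopped:
                continue
            assert np.all(p1[sel.selected] <= sel.m2 * 0.25 / 40 + 1e-12)
            assert np.all(p1[sel.selected] <= sel.gamma1_effective + 1e-12)

    def test_m2_monotone_in_alpha1(self, rng):
        p1 = rng.uniform(size=60)
        p1[:8] *= 0.02
        m2s = [select_fdrs(p1, a).m2 for a in (0.05, 0.1, 0.2, 0.4)]
        assert m2s == sorted(m2s)

    def test_global_null_stop_rate(self):
        # stop probability is 1 - alpha1 under the global null
        alpha1, reps, m = 0.2, 5000, 100
        rng = np.random.default_rng(7)
        stops = sum(select_fdrs(rng.uniform(size=m), alpha1).stopped
                    for _ in range(reps))
        est = stops / reps
        se = np.sqrt(alpha1 * (1 - alpha1) / reps)
        assert abs(est - (1 - alpha1)) <= 3 * se


def test_topk_threshold_consistency(rng):
    # selecting at gamma1 = p_(k) re-selects a superset of the top-k set
    for _ in range(30):
        p1 = rng.uniform(size=25)
        k = int(rng.integers(1, 25))
        top = select_top_k(p1, k)
        thr = select_fixed_threshold(p1, top.gamma1_effective) \
            if top.gamma1_effective < 1 else None
        if thr is not None:
            assert np.all(thr.selected[top.selected])


def test_dispatcher_matches_direct_calls(rng):
    p1 = rng.uniform(size=30)
    assert np.array_equal(select(p1, SelectionRule.fixed(0.1)).selected,
                          select_fixed_threshold(p1, 0.1).selected)
    assert np.array_equal(select(p1, SelectionRule.fns(5)).selected,
                          select_top_k(p1, 5).selected)
    assert np.array_equal(select(p1, SelectionRule.fdrs(0.2)).selected,
                          select_fdrs(p1, 0.2, ms=6).selected)


def test_fdrs_selection_is_bh_rejection_set(rng):
    p1 = rng.uniform(size=50) ** 2
    sel = select_fdrs(p1, 0.3)
    assert np.array_equal(sel.selected, bh_stepup(p1, 0.3).rejected)


def test_rule_validation():
    with pytest.raises(ValueError):
        SelectionRule(kind="unknown")
    with pytest.raises(ValueError):
        SelectionRule.fixed(1.5)
    with pytest.raises(ValueError):
        SelectionRule.fns(0)
    with pytest.raises(ValueError):
        SelectionRule.fdrs(0.0)
    with pytest.raises(ValueError):
        SelectionRule(kind="fns", m2=5, alpha1=0.2)
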