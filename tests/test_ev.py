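"""EV bead-panel correction, rank statistics, ROC and NTA summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from liquidmet.ev import (
    ISOTYPES,
    MARKERS_37,
    BeadPanel,
    EvPanelError,
    background_correct,
    marker_group_compare,
    nta_summary,
    rank_auc,
    roc_analysis,
)


def make_panel(sample_id="s1", blank=50.0, group="AML", **overrides):
    mfi = {m: 150.0 for m in MARKERS_37}
    mfi.update(overrides)
    iso = {i: 55.0 for i in ISOTYPES}
    return BeadPanel(sample_id=sample_id, marker_mfi=mfi, isotype_mfi=iso,
                     blank_mfi=blank, group=group)


class TestBackgroundCorrect:
    def test_marker_equal_to_blank_gives_zero(self):
        c = background_correct(make_panel(blank=150.0))
        assert c.corrected_mfi["CD44"] == pytest.approx(0.0)

    def test_simple_subtraction(self):
        c = background_correct(make_panel(blank=50.0))
        assert c.corrected_mfi["CD9"] == pytest.approx(100.0)

    def test_clamp_on_and_off(self):
        panel = make_panel(blank=50.0, CD44=30.0)
        on = background_correct(panel, clamp=True)
        assert on.corrected_mfi["CD44"] == 0.0
        assert on.clamped["CD44"]
        off = background_correct(panel, clamp=False)
        assert off.corrected_mfi["CD44"] == pytest.approx(-20.0)

    @given(c=st.floats(-100, 100))
    def test_translation_consistency(self, c):
        """Adding a constant to marker and blank leaves corrected values unchanged."""
        base = background_correct(make_panel(blank=60.0), clamp=False)
        shifted_panel = BeadPanel(
            sample_id="s1",
            marker_mfi={m: 150.0 + c for m in MARKERS_37},
            isotype_mfi={i: 55.0 for i in ISOTYPES},
            blank_mfi=60.0 + c)
        shifted = background_correct(shifted_panel, clamp=False)
        for m in MARKERS_37:
            assert shifted.corrected_mfi[m] == pytest.approx(base.corrected_mfi[m], abs=1e-9)

    def test_vocabulary_enforced(self):
        mfi = {m: 1.0 for m in MARKERS_37[:-1]}
        mfi["NOT_A_MARKER"] = 1.0
        with pytest.raises(EvPanelError, match="vocabulary"):
            BeadPanel(sample_id="bad", marker_mfi=mfi,
                      isotype_mfi={i: 1.0 for i in ISOTYPES}, blank_mfi=0.0)


class TestRoc:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=50)
        assert r.auc == pytest.approx(1.0)
        assert r.sensitivity == pytest.approx(1.0)
        assert r.specificity == pytest.approx(1.0)

    @pytest.mark.parametrize("scores,expected", [
        ([1, 2, 3, 4], 1.0),
        ([1, 3, 2, 4], 0.75),
    ])
    def test_all_pairs_counting_examples(self, scores, expected):
        assert rank_auc(np.array(scores, float), np.array([0, 0, 1, 1])) == pytest.approx(expected)

    def test_matches_brute_force_and_sklearn_on_random_fixtures(self, rng):
        """Rank-formulation AUC equals all-pairs counting (ties half) and the
        sklearn trapezoid AUC on every random fixture."""
        for _ in range(300):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            pos, neg = scores[labels == 1], scores[labels == 0]
            gt = (pos[:, None] > neg[None, :]).sum()
            eq = (pos[:, None] == neg[None, :]).sum()
            brute = (gt + 0.5 * eq) / (pos.size * neg.size)
            assert rank_auc(scores, labels) == pytest.approx(brute, abs=1e-12)
            assert rank_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_permuted_labels_near_half(self, rng):
        scores = rng.normal(size=1000)
        labels = np.array([0] * 500 + [1] * 500)
        rng.shuffle(labels)
        assert rank_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_raises(self):
        with pytest.raises(EvPanelError, match="both classes"):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_bootstrap_ci_seeded(self):
        scores, labels = [1, 4, 2, 8, 9, 3], [0, 1, 0, 1, 1, 0]
        r1 = roc_analysis(scores, labels, n_boot=200, seed=5)
        r2 = roc_analysis(scores, labels, n_boot=200, seed=5)
        assert r1.ci == r2.ci


class TestGroupCompare:
    def make_panels(self, a_values, b_values, marker="CD44"):
        panels = []
        for i, v in enumerate(a_values):
            panels.append(background_correct(make_panel(f"a{i}", group="AML",
                                                        **{marker: 50.0 + v})))
        for i, v in enumerate(b_values):
            panels.append(background_correct(make_panel(f"b{i}", group="HD",
                                                        **{marker: 50.0 + v})))
        return panels

    def test_exact_small_sample_p_matches_enumeration(self):
        """3-vs-3 with complete separation: two-sided rank-sum p = 0.1 by full
        enumeration (2 extreme assignments of 20)."""
        panels = self.make_panels([1, 2, 3], [4, 5, 6])
        table = marker_group_compare(panels, adjust=False)
        p = table.loc[table["marker"] == "CD44", "p"].item()
        # independent enumeration over all C(6,3) rank splits
        ranks = np.arange(1, 7)
        sums = [sum(c) for c in itertools.combinations(ranks, 3)]
        observed = 1 + 2 + 3
        tail = np.mean([s <= observed for s in sums])
        assert p == pytest.approx(2 * tail, abs=1e-12)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_give_p_near_one(self, rng):
        vals = rng.normal(size=6)
        panels = self.make_panels(vals[:3] * 0, vals[:3] * 0)
        table = marker_group_compare(panels, adjust=False)
        assert (table["p"] > 0.9).all()

    def test_large_shift_detected(self, rng):
        a = rng.normal(100, 1, size=20)
        b = rng.normal(0, 1, size=20)
        table = marker_group_compare(self.make_panels(a, b), adjust=False)
        assert table.loc[table["marker"] == "CD44", "p"].item() < 0.001

    def test_holm_column_present_and_larger(self):
        panels = self.make_panels([1, 2, 3], [4, 5, 6])
        table = marker_group_compare(panels, adjust=True)
        assert (table["p_holm"] >= table["p"] - 1e-12).all()

    def test_too_small_group_raises(self):
        panels = self.make_panels([1], [2, 3])
        with pytest.raises(EvPanelError, match=">= 2"):
            marker_group_compare(panels)


class TestNta:
    def test_constant_sample(self):
        s = nta_summary([100.0] * 50, concentration=1e9)
        assert s.mean == s.mode == s.d10 == s.d50 == s.d90 == pytest.approx(100.0)

    def test_uniform_grid_median(self):
        s = nta_summary(np.arange(50, 150, dtype=float), concentration=1.0)
        assert s.d50 == pytest.approx(99.5)

    def test_permutation_invariance_and_ordering(self, rng):
        sizes = rng.lognormal(np.log(120), 0.3, size=500)
        s1 = nta_summary(sizes, 1.0)
        s2 = nta_summary(rng.permutation(sizes), 1.0)
        assert (s1.d10, s1.d50, s1.d90) == (s2.d10, s2.d50, s2.d90)
        assert s1.d10 <= s1.d50 <= s1.d90

    def test_duplication_leaves_percentiles_unchanged(self, rng):
        sizes = rng.lognormal(np.log(120), 0.3, size=200)
        s1 = nta_summary(sizes, 1.0)
        s2 = nta_summary(np.concatenate([sizes, sizes]), 1.0)
        assert s1.d50 == pytest.approx(s2.d50)
        assert s1.d10 == pytest.approx(s2.d10)

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(EvPanelError):
            nta_summary([], 1.0)
        with pytest.raises(EvPanelError):
            nta_summary([-1.0, 100.0], 1.0)
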