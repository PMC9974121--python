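"""Per-tree scoring: ED1, EDGE1, ED2 (against the oracle), PD loss, capture."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edge2 import (
    SimConfig,
    capture_curve,
    ed2_oracle,
    ed2_scores,
    edge1_score,
    edge2_score,
    expected_pd_loss,
    fair_proportion_ed1,
    simulate_tree,
)

from conftest import random_trees, tree_from_newick


class TestFairProportion:
    def test_star_tree_keeps_terminal_lengths(self, star_tree):
        assert fair_proportion_ed1(star_tree) == {"A": 1.0, "B": 1.0, "C": 1.0}

    def test_hand_computed_cherry(self):
        tree = tree_from_newick("((A:1,B:1):1,C:2);")
        ed1 = fair_proportion_ed1(tree)
        assert ed1["A"] == pytest.approx(1.5)
        assert ed1["B"] == pytest.approx(1.5)
        assert ed1["C"] == pytest.approx(2.0)
        assert sum(ed1.values()) == pytest.approx(tree.total_pd) == 5.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_conserves_total_pd_on_simulated_trees(self, seed):
        tree = simulate_tree(SimConfig(n_tips=40, seed=seed))
        ed1 = fair_proportion_ed1(tree)
        assert sum(ed1.values()) == pytest.approx(tree.total_pd, rel=1e-12)


class TestEdge1:
    @given(ed=st.floats(0, 1e6), ge=st.integers(0, 4))
    @settings(max_examples=50, derandomize=True)
    def test_formula(self, ed, ge):
        assert edge1_score(ed, ge) == pytest.approx(
            math.log(1 + ed) + ge * math.log(2)
        )

    def test_known_values(self):
        assert edge1_score(0, 0) == 0
        assert edge1_score(math.e - 1, 0) == pytest.approx(1.0)
        assert edge1_score(1, 4) == pytest.approx(5 * math.log(2))


class TestEd2:
    def test_star_tree_ed2_is_tbl(self, star_tree):
        p = {"A": 0.9, "B": 0.1, "C": 0.5}
        for taxon, score in ed2_scores(star_tree, p).items():
            assert score.ed2 == pytest.approx(1.0)
            assert score.terminal_share == pytest.approx(1.0)

    def test_cherry_hand_computation(self, cherry_tree):
        p = {"A": 0.3, "B": 0.5, "C": 0.2}
        scores = ed2_scores(cherry_tree, p)
        assert scores["A"].ed2 == pytest.approx(2 + 4 * 0.5)  # = 4
        assert scores["B"].ed2 == pytest.approx(2 + 4 * 0.3)
        assert scores["C"].ed2 == pytest.approx(10.0)
        assert scores["A"].terminal_share == pytest.approx(2 / 4)

    def test_missing_p_names_the_tip(self, cherry_tree):
        with pytest.raises(KeyError, match="B"):
            ed2_scores(cherry_tree, {"A": 0.5, "C": 0.5})

    def test_limit_low_p_gives_tbl(self, cherry_tree):
        p = {t: 0.0001 for t in cherry_tree.tip_labels}
        scores = ed2_scores(cherry_tree, p)
        assert scores["A"].ed2 == pytest.approx(2.0, abs=1e-3)

    def test_limit_high_p_gives_root_path(self, cherry_tree):
        p = {t: 0.9999 for t in cherry_tree.tip_labels}
        scores = ed2_scores(cherry_tree, p)
        for t in cherry_tree.tip_labels:
            assert scores[t].ed2 == pytest.approx(
                cherry_tree.root_to_tip_length(t), rel=1e-3
            )

    def test_monotone_in_relatives_p(self, cherry_tree):
        lo = ed2_scores(cherry_tree, {"A": 0.5, "B": 0.2, "C": 0.2})["A"].ed2
        hi = ed2_scores(cherry_tree, {"A": 0.5, "B": 0.8, "C": 0.2})["A"].ed2
        assert hi > lo

    def test_own_p_does_not_change_ed2(self, cherry_tree):
        a = ed2_scores(cherry_tree, {"A": 0.1, "B": 0.4, "C": 0.2})["A"].ed2
        b = ed2_scores(cherry_tree, {"A": 0.9, "B": 0.4, "C": 0.2})["A"].ed2
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_oracle_on_random_trees(self):
        for tree, p in random_trees(n_trees=15, max_tips=10, seed=31):
            fast = ed2_scores(tree, p)
            for taxon in tree.tip_labels:
                assert fast[taxon].ed2 == pytest.approx(
                    ed2_oracle(tree, p, taxon), abs=1e-10
                )

    def test_mc_oracle_agrees_with_exhaustive(self, cherry_tree):
        p = {"A": 0.3, "B": 0.5, "C": 0.2}
        exact = ed2_oracle(cherry_tree, p, "A")
        mc = ed2_oracle(
            cherry_tree,
            p,
            "A",
            method="mc",
            n_replicates=200_000,
            rng=np.random.default_rng(0),
        )
        assert mc == pytest.approx(exact, rel=0.02)

    def test_oracle_refuses_large_trees(self):
        tree = simulate_tree(SimConfig(n_tips=25, seed=1))
        p = {t: 0.5 for t in tree.tip_labels}
        with pytest.raises(ValueError, match="mc"):
            ed2_oracle(tree, p, tree.tip_labels[0])

    def test_clade_insensitivity_via_deep_secure_graft(self):
        """Grafting the clade deep inside a large secure group moves ED2 by
        less than the grafted branch times the product of the new p's."""
        small = tree_from_newick("((A:2,B:2):4,C:10);")
        # study clade joins 4 secure species; a 50 MY branch sits above them
        grafted = tree_from_newick(
            "(((((A:2,B:2):4,C:10):0,(D1:1,D2:1,D3:1,D4:1):5):50),E:60);"
        )
        p = {"A": 0.5, "B": 0.5, "C": 0.5}
        p_big = dict(p, E=0.5, **{f"D{i}": 0.01 for i in range(1, 5)})
        s_small = ed2_scores(small, p)
        s_big = ed2_scores(grafted, p_big)
        bound = 50 * 0.01 ** 4  # grafted length x product of the secure p's
        for t in ("A", "B", "C"):
            assert abs(s_big[t].ed2 - s_small[t].ed2) < bound

    def test_ed2_equals_ed1_on_star_tree(self, star_tree):
        p = {t: 0.37 for t in star_tree.tip_labels}
        ed1 = fair_proportion_ed1(star_tree)
        for t, s in ed2_scores(star_tree, p).items():
            assert s.ed2 == pytest.approx(ed1[t])

    def test_rank_correlation_with_ed1_under_random_p(self):
        tree = simulate_tree(SimConfig(n_tips=50, seed=11))
        rng = np.random.default_rng(3)
        p = {t: float(rng.uniform(0.05, 0.97)) for t in tree.tip_labels}
        ed1 = fair_proportion_ed1(tree)
        ed2 = {t: s.ed2 for t, s in ed2_scores(tree, p).items()}
        taxa = list(tree.tip_labels)
        r1 = np.argsort(np.argsort([ed1[t] for t in taxa]))
        r2 = np.argsort(np.argsort([ed2[t] for t in taxa]))
        rho = np.corrcoef(r1, r2)[0, 1]
        assert rho > 0.5


class TestEdge2Score:
    def test_product(self):
        assert edge2_score(4, 0.5) == 2
        assert edge2_score(0, 0.5) == 0

    def test_anchor_ratio_cr_vs_lc(self):
        assert edge2_score(3.7, 0.97) / edge2_score(3.7, 0.060625) == pytest.approx(16)

    def test_rejects_degenerate_probabilities(self):
        with pytest.raises(ValueError):
            edge2_score(1.0, 0.0)
        with pytest.raises(ValueError):
            edge2_score(1.0, 1.0)


class TestExpectedPdLoss:
    def test_single_tip(self):
        tree = tree_from_newick("(A:3);")
        assert expected_pd_loss(tree, {"A": 0.5}) == pytest.approx(1.5)

    def test_cherry_hand_expansion(self):
        tree = tree_from_newick("((A:2,B:2):4,C:10);")
        p = {"A": 0.5, "B": 0.5, "C": 0.0001}
        expected = 2 * 0.5 + 2 * 0.5 + 4 * 0.25 + 10 * 0.0001
        assert expected_pd_loss(tree, p) == pytest.approx(expected)

    def test_vanishes_at_lower_clip_bound(self, cherry_tree):
        p = {t: 0.0001 for t in cherry_tree.tip_labels}
        assert expected_pd_loss(cherry_tree, p) < cherry_tree.total_pd * 1e-3


class TestCaptureCurve:
    def test_full_set_captures_everything(self):
        scores = {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}
        assert capture_curve(scores, 4) == pytest.approx(1.0)

    def test_equal_scores_capture_proportionally(self):
        scores = {f"s{i}": 2.0 for i in range(10)}
        assert capture_curve(scores, 5) == pytest.approx(0.5)

    def test_top_two_of_descending(self):
        assert capture_curve({"a": 4, "b": 3, "c": 2, "d": 1}, 2) == pytest.approx(0.7)

    def test_tie_break_is_deterministic(self):
        scores = {"b": 5.0, "a": 5.0, "c": 2.0}
        # ties by label: top-1 is 'a', still 5/12 of the total either way
        assert capture_curve(scores, 1) == pytest.approx(5 / 12)
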