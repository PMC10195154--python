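"""Dollo loss mapping, survival decay, PIC, loss-pattern statistics."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from ohnolog.loss_dynamics import (
    ancestral_states,
    classify_loss_pattern,
    count_loss_patterns,
    expression_biased_loss,
    fit_decay,
    parallel_trend,
    pic_contrasts,
    proportion_test_half,
    retention_vs_divergence,
    survival_curve,
)
from ohnolog.models import BOTH, ONE, NA


def cherry_tree():
    t = dendropy.Tree.get(data="(x:1,y:1);", schema="newick", preserve_underscores=True)
    t.is_rooted = True
    t.seed_node.label = "wgd"
    return t


@pytest.mark.parametrize(
    "cx,cy,expected",
    [
        (NA, BOTH, BOTH),
        (NA, ONE, NA),
        (NA, NA, NA),
        (BOTH, ONE, BOTH),
        (BOTH, BOTH, BOTH),
        (ONE, ONE, ONE),
    ],
)
def test_na_rule_table_on_cherries(cx, cy, expected):
    m = pd.DataFrame({"x": [cx], "y": [cy]}, index=["p"])
    anc = ancestral_states(cherry_tree(), m, "wgd")
    assert anc.states.loc["wgd", "p"] == expected


def test_missing_leaf_is_an_error():
    m = pd.DataFrame({"x": [BOTH]}, index=["p"])
    with pytest.raises(ValueError):
        ancestral_states(cherry_tree(), m, "wgd")


def brute_force_dollo(tree, leaf_states: dict[str, str]):
    """Minimum-loss placement by exhaustive search over branch subsets
    (no-gain model: a pair starts BOTH at the root; a loss on a branch
    makes the whole subtree ONE)."""
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            lab = node.taxon.label if node.is_leaf() else node.label
            edges.append((lab, node))
    best = None
    for r in range(len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            chosen = {lab for lab, _ in combo}
            # a loss branch must not be nested under another loss branch
            ok = True
            for lab, node in combo:
                anc = node.parent_node
                while anc is not None and ok:
                    anc_lab = anc.taxon.label if anc.is_leaf() else anc.label
                    if anc_lab in chosen:
                        ok = False
                    anc = anc.parent_node
            if not ok:
                continue
            predicted = {}
            for leaf in tree.leaf_node_iter():
                state = BOTH
                node = leaf
                while node is not None:
                    lab = node.taxon.label if node.is_leaf() else node.label
                    if lab in chosen:
                        state = ONE
                        break
                    node = node.parent_node
                predicted[leaf.taxon.label] = state
            if predicted == leaf_states:
                if best is None or r < len(best):
                    best = chosen
        if best is not None:
            break  # combinations are enumerated in increasing size
    return best


def random_tree(n_leaves, seed):
    rng = np.random.default_rng(seed)
    nodes = [f"L{i}" for i in range(n_leaves)]
    parts = [f"{n}:1" for n in nodes]
    k = 0
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        merged = f"({parts[i]},{parts[j]})I{k}:1"
        k += 1
        parts = [p for idx, p in enumerate(parts) if idx not in (i, j)] + [merged]
    nwk = f"({parts[0]},{parts[1]})wgd;"
    t = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    t.is_rooted = True
    return t


@pytest.mark.parametrize("n_leaves,seed", [(4, 0), (5, 1), (6, 2)])
def test_dollo_equals_exhaustive_enumeration(n_leaves, seed):
    """On complete data the parsimony rule table places exactly the
    minimum-loss branch set found by brute force."""
    tree = random_tree(n_leaves, seed)
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    for assignment in itertools.product([BOTH, ONE], repeat=n_leaves):
        m = pd.DataFrame([dict(zip(leaves, assignment))], index=["p"])
        anc = ancestral_states(tree, m, "wgd")
        got = set(anc.losses["branch"])
        expected = brute_force_dollo(tree, dict(zip(leaves, assignment)))
        if all(s == ONE for s in assignment):
            assert got == set()  # loss precedes the root: no branch event
        else:
            assert got == expected


class TestSurvival:
    def test_root_survival_is_one_and_formula(self):
        tree = cherry_tree()
        m = pd.DataFrame(
            {"x": [BOTH, ONE, BOTH, ONE], "y": [BOTH, BOTH, ONE, ONE]},
            index=list("abcd"),
        )
        anc = ancestral_states(tree, m, "wgd")
        curve = survival_curve(anc, tree).set_index("node")
        assert curve.loc["wgd", "survival"] == 1.0  # 3 of 3 root pairs
        assert curve.loc["x", "survival"] == pytest.approx(2 / 3)
        assert curve.loc["x", "distance"] == 1.0

    def test_survival_non_increasing_to_leaves(self, loss_only_sim):
        from ohnolog.simulate import presence_matrix_from_truth

        _, tree, truth = loss_only_sim
        states, _ = presence_matrix_from_truth(truth)
        anc = ancestral_states(tree, states, "wgd")
        for leaf in truth.species:
            node = next(
                n for n in tree.preorder_node_iter()
                if n.is_leaf() and n.taxon.label == leaf
            )
            path = []
            while node is not None and node.label != "wgd":
                path.append(node.taxon.label if node.is_leaf() else node.label)
                node = node.parent_node
            path.append("wgd")
            surv = [anc.n_both(lab) for lab in reversed(path)]
            assert all(a >= b for a, b in zip(surv, surv[1:]))


class TestDecayFit:
    def test_noiseless_one_phase_recovery(self):
        d = np.linspace(0.0, 2.0, 12)
        pts = pd.DataFrame({"distance": d, "survival": np.exp(-0.5 * d)})
        fit = fit_decay(pts)
        assert fit.rate == pytest.approx(0.5, abs=1e-6)
        assert fit.model == "one_phase"

    def test_two_phase_detected(self):
        rng = np.random.default_rng(0)
        d = np.linspace(0.02, 1.5, 30)
        s = 0.5 * np.exp(-2.0 * d) + 0.5 * np.exp(-0.1 * d)
        pts = pd.DataFrame({"distance": d, "survival": rng.binomial(5000, s) / 5000})
        fit = fit_decay(pts)
        assert fit.model == "two_phase"
        assert fit.rates2[0] > fit.rates2[1]

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            fit_decay(pd.DataFrame({"distance": [0, 1], "survival": [1, 0.5]}))


class TestPIC:
    def test_contrasts_match_hand_computation(self):
        """Balanced 4-leaf tree with equal branch lengths: contrasts have
        the closed form (x_i - x_j)/sqrt(2v) at the cherries and the
        node-mean difference over sqrt(2(v + v/2)) at the root."""
        t = dendropy.Tree.get(
            data="((a:1,b:1)n1:1,(c:1,d:1)n2:1)wgd;", schema="newick",
            preserve_underscores=True,
        )
        t.is_rooted = True
        vals = {"a": 1.0, "b": 3.0, "c": 2.0, "d": 8.0}
        got = sorted(pic_contrasts(t, vals, "wgd"))
        u1 = (1.0 - 3.0) / np.sqrt(2)
        u2 = (2.0 - 8.0) / np.sqrt(2)
        u3 = (2.0 - 5.0) / np.sqrt(2 * 1.5)
        assert got == pytest.approx(sorted([u1, u2, u3]), rel=1e-6)

    def test_perfect_anticorrelation(self):
        t = dendropy.Tree.get(
            data="((a:1,b:1):1,(c:1,d:1):1)wgd;", schema="newick",
            preserve_underscores=True,
        )
        t.is_rooted = True
        ret = pd.Series({"a": 0.9, "b": 0.7, "c": 0.5, "d": 0.3})
        ks = pd.Series({"a": 0.1, "b": 0.3, "c": 0.5, "d": 0.7})
        rep = retention_vs_divergence(ret, ks, t, "wgd")
        assert rep.r == pytest.approx(-1.0)
        assert rep.pic_r == pytest.approx(-1.0)


class TestLossPatterns:
    def test_classification_rules(self):
        assert classify_loss_pattern(BOTH, "B", "B") == "parallel"  # both lost A
        assert classify_loss_pattern(BOTH, "B", "A") == "reciprocal"
        assert classify_loss_pattern(ONE, "B", "B") == "none"  # shared ancestral loss
        assert classify_loss_pattern(BOTH, "", "B") == "none"

    def test_counts_on_four_leaf_tree(self):
        """Losses in non-sister species count as independent only when the
        MRCA is reconstructed BOTH (some other descendant retains both)."""
        t = dendropy.Tree.get(
            data="((x:1,y:1)n1:1,(z:1,w:1)n2:1)wgd;", schema="newick",
            preserve_underscores=True,
        )
        t.is_rooted = True
        m = pd.DataFrame(
            {"x": [ONE, ONE], "y": [BOTH, BOTH], "z": [ONE, ONE], "w": [BOTH, BOTH]},
            index=["p", "q"],
        )
        c = pd.DataFrame(
            {"x": ["A", "A"], "y": ["", ""], "z": ["A", "B"], "w": ["", ""]},
            index=["p", "q"],
        )
        counts = count_loss_patterns(t, m, c, "wgd").set_index(["species_x", "species_y"])
        assert counts.loc[("x", "z"), "n_parallel"] == 1  # both kept copy A
        assert counts.loc[("x", "z"), "n_reciprocal"] == 1
        # sister species both ONE are a shared ancestral loss under parsimony
        m2 = pd.DataFrame({"x": [ONE], "y": [ONE], "z": [BOTH], "w": [BOTH]}, index=["p"])
        c2 = pd.DataFrame({"x": ["A"], "y": ["B"], "z": [""], "w": [""]}, index=["p"])
        counts2 = count_loss_patterns(t, m2, c2, "wgd").set_index(["species_x", "species_y"])
        assert counts2.loc[("x", "y")].n_parallel + counts2.loc[("x", "y")].n_reciprocal == 0

    def test_trend_degenerate_is_nan(self):
        df = pd.DataFrame(
            {"n_parallel": [5, 5, 5], "n_reciprocal": [5, 5, 5],
             "distance": [0.1, 0.2, 0.3]}
        )
        r, p = parallel_trend(df)
        assert np.isnan(r) and np.isnan(p)


class TestProportionTest:
    @pytest.mark.parametrize(
        "x,n,expected",  # reference values from R prop.test(..., correct=TRUE)
        [(41, 50, 1.164865737e-05), (25, 50, 1.0), (9, 10, 0.02685669551)],
    )
    def test_matches_r_continuity_corrected_values(self, x, n, expected):
        assert proportion_test_half(x, n) == pytest.approx(expected, rel=1e-6)


class TestExpressionBiasedLoss:
    def test_extreme_bias(self):
        n = 50
        tab = pd.DataFrame(
            {
                "expr_a": np.linspace(1, 2, n),
                "expr_b": np.linspace(2, 1, n),
                "state_b": ["A" if a >= b else "B"
                            for a, b in zip(np.linspace(1, 2, n), np.linspace(2, 1, n))],
            }
        )
        rep = expression_biased_loss(tab)
        assert rep.frac_low_expressed_lost == 1.0
        assert rep.prop_p < 0.001
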