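"""Parsimony trait mapping and the Fisher exact association test."""

from itertools import product
from math import comb

import numpy as np
import pytest

from larkmt.simulate import simulate_traits_on_tree
from larkmt.traits import fisher_exact, fitch_ancestral, parse_newick


def brute_force_min_changes(tree, tip_states):
    """Exhaustive minimum over all internal labelings (oracle)."""
    states = sorted(set(tip_states.values()))
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for combo in product(states, repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), combo))
        for leaf in tree.leaf_node_iter():
            assign[id(leaf)] = tip_states[leaf.taxon.label]
        changes = sum(
            assign[id(n)] != assign[id(n.parent_node)]
            for n in tree.preorder_node_iter()
            if n.parent_node is not None
        )
        best = changes if best is None else min(best, changes)
    return best


def random_tree_newick(rng, tips):
    nodes = [f"T{i+1}" for i in range(tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


class TestParseNewick:
    def test_topology_counts(self):
        t = parse_newick("((A,B),(C,D));")
        assert len(t.leaf_nodes()) == 4
        assert sum(1 for n in t.preorder_node_iter() if not n.is_leaf()) == 3

    def test_malformed_raises(self):
        with pytest.raises(ValueError):
            parse_newick("((A,B;")

    def test_simulated_tree_tip_set_matches_truth(self):
        nwk, tips, truth = simulate_traits_on_tree(8, [], seed=8)
        t = parse_newick(nwk)
        assert {lf.taxon.label for lf in t.leaf_node_iter()} == set(tips)


class TestFitch:
    def test_uniform_tips_need_no_changes(self):
        t = parse_newick("((A,B),(C,D));")
        res = fitch_ancestral(t, {x: "1" for x in "ABCD"})
        assert res.changes_min == 0 and res.changes == []

    def test_two_cherries_need_one_change(self):
        t = parse_newick("((A,B),(C,D));")
        states = {"A": "1", "B": "1", "C": "0", "D": "0"}
        res = fitch_ancestral(t, states)
        assert res.changes_min == 1
        assert res.changes_min == brute_force_min_changes(t, states)
        assert len(res.changes) == 1

    def test_single_origin_on_lark_parrotbill_clade(self):
        """Remnant-CR2 order C shared by larks and the parrotbill maps to
        one origin on their common stem."""
        nwk = (
            "(((((Alauda,Eremophila),(Melanocorypha,Alaudala))Alaudidae,"
            "Panurus)cladeX,(Hirundo,(Phylloscopus,Sylvia)))Sylvioidea,"
            "Outgroup);"
        )
        t = parse_newick(nwk)
        states = {
            "Alauda": "C", "Eremophila": "C", "Melanocorypha": "C",
            "Alaudala": "C", "Panurus": "C",
            "Hirundo": "B", "Phylloscopus": "B", "Sylvia": "B", "Outgroup": "B",
        }
        res = fitch_ancestral(t, states)
        assert res.changes_min == 1
        assert res.changes == [("cladeX", "B", "C")]

    def test_matches_exhaustive_minimum_on_random_trees(self):
        rng = np.random.default_rng(17)
        for _ in range(12):
            tips = int(rng.integers(4, 11))
            t = parse_newick(random_tree_newick(rng, tips))
            states = {
                f"T{i+1}": str(rng.integers(0, 3)) for i in range(tips)
            }
            res = fitch_ancestral(t, states)
            assert res.changes_min == brute_force_min_changes(t, states)
            # resolved labeling achieves the reported minimum
            assert len(res.changes) == res.changes_min

    def test_multifurcation_handled_exactly(self):
        t = parse_newick("((A,B,C),(D,E,F));")
        states = {"A": "1", "B": "1", "C": "0", "D": "0", "E": "0", "F": "0"}
        res = fitch_ancestral(t, states)
        assert res.changes_min == brute_force_min_changes(t, states) == 2

    def test_matching_sister_tip_never_increases_changes(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            tips = int(rng.integers(4, 9))
            base = random_tree_newick(rng, tips)
            states = {f"T{i+1}": str(rng.integers(0, 2)) for i in range(tips)}
            before = fitch_ancestral(parse_newick(base), states).changes_min
            # duplicate tip T1 as its own sister with the same state
            grown = base.replace("T1", "(T1,Tnew)", 1)
            grown_states = {**states, "Tnew": states["T1"]}
            after = fitch_ancestral(parse_newick(grown), grown_states).changes_min
            assert after == before

    def test_missing_tip_state_raises_unless_allowed(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            fitch_ancestral(t, {"A": "1", "B": "1", "C": "0"})
        res = fitch_ancestral(t, {"A": "1", "B": "1", "C": "0"}, allow_missing=True)
        assert res.changes_min == 1

    def test_planted_changes_recovered_from_simulation(self):
        nwk, tips, truth = simulate_traits_on_tree(10, ["N3"], seed=31)
        res = fitch_ancestral(parse_newick(nwk), tips)
        assert res.changes_min == 1

    def test_planted_count_bounds_fitch_count(self):
        rng = np.random.default_rng(23)
        for rep in range(10):
            nwk, tips, truth = simulate_traits_on_tree(
                8, [f"N{int(rng.integers(1, 7))}"], seed=400 + rep
            )
            res = fitch_ancestral(parse_newick(nwk), tips)
            assert res.changes_min <= truth["planted_changes"]


def fisher_oracle(a, b, c, d):
    """Exhaustive enumeration with exact rational hypergeometric masses."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(n - r1, c1 - a) / denom
    total = 0.0
    for k in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        pk = comb(r1, k) * comb(n - r1, c1 - k) / denom
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


class TestFisher:
    def test_perfect_association_table(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_degenerate_row_gives_one(self):
        assert fisher_exact([[3, 3], [0, 0]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-6
            )

    def test_matches_scipy_reference(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(37)
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                scipy_fisher([[a, b], [c, d]]).pvalue, rel=1e-6
            )

    def test_symmetry_invariances(self):
        table = [[6, 2], [1, 7]]
        p = fisher_exact(table)
        assert fisher_exact([[6, 1], [2, 7]]) == pytest.approx(p)  # transpose
        assert fisher_exact([[7, 1], [2, 6]]) == pytest.approx(p)  # swap both
        assert 0 < p <= 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [0, 0]])
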