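"""Parsimony trait mapping on a supplied phylogeny, and the repeat
association test.

Discrete characters (gene-order type, presence of control-region tandem
repeats) are mapped onto a rooted tree by unweighted parsimony.  The
up-pass uses Hartigan's generalization of the Fitch algorithm — for
each node keep the states attained by the maximal number of children
and add (number of children - that maximum) changes — which gives the
exact minimum change count on binary *and* multifurcating trees.  The
down-pass resolves ambiguity deterministically: a node takes its
parent's state when that state is in its optimal set, otherwise the
lexicographically smallest member.

``fisher_exact`` computes the two-sided Fisher exact test for a 2x2
table (species counts of repeat presence in CR1 x CR2) by summing the
hypergeometric probabilities of all tables with the observed margins
that are no more probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
from scipy.stats import hypergeom

__all__ = [
    "TraitTree",
    "FitchResult",
    "parse_newick",
    "fitch_ancestral",
    "fisher_exact",
]

_TIE_SLACK = 1e-7


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string; malformed input raises with detail."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed newick: {exc}") from exc
    return tree


@dataclass
class FitchResult:
    changes_min: int
    node_sets: dict[int, frozenset[str]]  # node id -> optimal state set
    node_states: dict[int, str]  # resolved state per node
    changes: list[tuple[str, str, str]]  # (child node label, from, to)


@dataclass
class TraitTree:
    """A tree plus tip states and (after mapping) inferred node states."""

    tree: dendropy.Tree
    tip_states: dict[str, str]
    result: FitchResult | None = None


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{id(node) % 100000}"


def fitch_ancestral(
    tree: dendropy.Tree,
    tip_states: dict[str, str],
    allow_missing: bool = False,
) -> FitchResult:
    """Minimum-change ancestral states by two-pass (Hartigan/Fitch) parsimony.

    ``tip_states`` maps leaf taxon labels to discrete states.  Changes
    are placed on branches where the resolved child state differs from
    the resolved parent state; their number equals the parsimony
    minimum.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    missing = [
        _node_label(lf) for lf in leaves if _node_label(lf) not in tip_states
    ]
    if missing and not allow_missing:
        raise ValueError(f"missing tip states for {missing}")

    node_sets: dict[int, frozenset[str]] = {}
    changes_min = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = _node_label(node)
            if label in tip_states:
                node_sets[id(node)] = frozenset({tip_states[label]})
            continue
        child_sets = [
            node_sets[id(c)] for c in node.child_nodes() if id(c) in node_sets
        ]
        if not child_sets:
            continue
        counts: dict[str, int] = {}
        for cs in child_sets:
            for s in cs:
                counts[s] = counts.get(s, 0) + 1
        top = max(counts.values())
        node_sets[id(node)] = frozenset(s for s, c in counts.items() if c == top)
        changes_min += len(child_sets) - top

    node_states: dict[int, str] = {}
    changes: list[tuple[str, str, str]] = []
    for node in tree.preorder_node_iter():
        if id(node) not in node_sets:
            continue
        sset = node_sets[id(node)]
        parent = node.parent_node
        if parent is None or id(parent) not in node_states:
            node_states[id(node)] = min(sset)
            continue
        pstate = node_states[id(parent)]
        state = pstate if pstate in sset else min(sset)
        node_states[id(node)] = state
        if state != pstate:
            changes.append((_node_label(node), pstate, state))
    return FitchResult(
        changes_min=changes_min,
        node_sets=node_sets,
        node_states=node_states,
        changes=changes,
    )


def fisher_exact(table: list[list[int]] | tuple[tuple[int, int], tuple[int, int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Sums hypergeometric probabilities of tables (with the observed
    margins) whose probability does not exceed the observed table's,
    with a small relative slack for floating-point ties.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1, c1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, r1, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1.0 + _TIE_SLACK):
            total += pk
    return min(total, 1.0)
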