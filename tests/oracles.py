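"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities from first principles (exhaustive
enumeration, closed forms) without reusing the package's optimized code
paths.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import product

import numpy as np

from medhier.nlp import ParseTree


# -- subset-tree fragment enumeration ---------------------------------------

def fragments_rooted_at(node: ParseTree) -> set:
    """All subset-tree fragments rooted at ``node``.

    A fragment includes the node's full production; each non-leaf child is
    either left as a frontier nonterminal or expanded by one of its own
    fragments.  Leaf children (tokens) are always included.  Fragments are
    canonicalized as nested tuples.
    """
    if node.is_leaf:
        raise ValueError("fragments are rooted at internal nodes")
    child_options: list[list] = []
    for child in node.children:
        if child.is_leaf:
            child_options.append([("tok", child.label)])
        else:
            opts = [("frontier", child.label)]
            opts.extend(("sub", f) for f in fragments_rooted_at(child))
            child_options.append(opts)
    out = set()
    for combo in product(*child_options):
        out.add((node.label, tuple(combo)))
    return out


def stkn_bruteforce(t1: ParseTree, t2: ParseTree) -> int:
    """STKN by exhaustive fragment enumeration: sum over fragments f of
    (#nodes of t1 rooting f) * (#nodes of t2 rooting f)."""
    c1: Counter = Counter()
    for n in t1.internal_nodes():
        for f in fragments_rooted_at(n):
            c1[f] += 1
    c2: Counter = Counter()
    for n in t2.internal_nodes():
        for f in fragments_rooted_at(n):
            c2[f] += 1
    return sum(c1[f] * c2[f] for f in c1 if f in c2)


def random_tree(rng, max_nodes: int, labels=("A", "B", "C"), tokens=("x", "y")) -> ParseTree:
    """Random labeled tree with at most ``max_nodes`` nodes, leaves carrying
    tokens and internal nodes carrying nonterminal labels."""

    def build(budget: int) -> tuple[ParseTree, int]:
        if budget <= 2 or rng.random() < 0.3:
            # preterminal with one token leaf
            return (
                ParseTree(rng.choice(labels), (ParseTree(rng.choice(tokens)),)),
                2,
            )
        n_children = rng.randint(1, 3)
        children = []
        used = 1
        for _ in range(n_children):
            if budget - used < 2:
                break
            sub, c = build(budget - used)
            children.append(sub)
            used += c
        if not children:
            return (
                ParseTree(rng.choice(labels), (ParseTree(rng.choice(tokens)),)),
                2,
            )
        return ParseTree(rng.choice(labels), tuple(children)), used

    tree, _ = build(max_nodes)
    return tree


# -- Jensen-Shannon by explicit loops ---------------------------------------

def js_divergence_bruteforce(p, q) -> float:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    m = 0.5 * (p + q)
    total = 0.0
    for pi, qi, mi in zip(p, q, m):
        if pi > 0:
            total += 0.5 * pi * math.log(pi / mi)
        if qi > 0:
            total += 0.5 * qi * math.log(qi / mi)
    return total


# -- leading-node best-cut search -------------------------------------------

def leading_nodes_bruteforce(posterior) -> list[int]:
    """Best cut by explicit search over all adjacent gaps of the sorted
    posterior; first maximal gap wins."""
    p = np.asarray(posterior, dtype=float)
    if p.size == 1:
        return [0]
    order = np.argsort(-p, kind="stable")
    sp = p[order]
    best_gap, best_cut = -1.0, 1
    for cut in range(1, p.size):
        gap = sp[cut - 1] - sp[cut]
        if gap > best_gap:
            best_gap, best_cut = gap, cut
    return sorted(int(i) for i in order[:best_cut])


# -- direct double-loop average relation ------------------------------------

def avg_relation_bruteforce(set_a, set_b, sim) -> float:
    total = 0.0
    for i in set_a:
        for j in set_b:
            total += 1.0 if i == j else sim(i, j)
    return total / (len(set_a) * len(set_b))
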