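"""Brute-force oracles, independent of the pruning/Sankoff implementations."""

import itertools
import math

import numpy as np

from qsevo.phylo_ancestral import er_transition_matrix


def brute_force_log_likelihood(tree, tips, k, q):
    """Sum over every internal-node state assignment (flat root prior)."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip((id(n) for n in internals), assign))
        p = 1.0 / k
        for parent, child in tree.edges():
            ps = amap[id(parent)]
            cs = tips.get(child.name) if child.is_leaf else amap[id(child)]
            if cs is None:
                continue
            p *= er_transition_matrix(k, q, child.length)[ps, cs]
        total += p
    return math.log(total) if total > 0 else -math.inf


def brute_force_marginals(tree, tips, k, q):
    """Exhaustive marginal posteriors at internal nodes."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    margs = {id(n): np.zeros(k) for n in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip((id(n) for n in internals), assign))
        p = 1.0 / k
        for parent, child in tree.edges():
            ps = amap[id(parent)]
            cs = tips.get(child.name) if child.is_leaf else amap[id(child)]
            if cs is None:
                continue
            p *= er_transition_matrix(k, q, child.length)[ps, cs]
        for n in internals:
            margs[id(n)][amap[id(n)]] += p
    return {i: v / v.sum() for i, v in margs.items()}


def brute_force_parsimony_score(tree, tips, k):
    """Minimum change count over every internal-node labeling."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    best = math.inf
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip((id(n) for n in internals), assign))
        changes = 0
        for parent, child in tree.edges():
            ps = amap[id(parent)]
            cs = tips.get(child.name) if child.is_leaf else amap[id(child)]
            if cs is None:
                continue
            changes += ps != cs
        best = min(best, changes)
    return int(best)
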