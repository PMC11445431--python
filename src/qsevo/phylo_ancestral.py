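"""Rooted trees, equal-rates Markov likelihoods, and ancestral reconstruction.

Discrete quaternary-structure states evolve along a rooted tree under the
equal-rates (ER) continuous-time Markov model: every transition between
the k states shares one rate q, giving the closed-form transition
probabilities

    P(stay, t)   = 1/k + (1 - 1/k) exp(-k q t)
    P(switch, t) = 1/k - (1/k)     exp(-k q t)   (per target state)

The likelihood is computed by Felsenstein pruning with a flat root prior
1/k; the rate is fitted by bounded scalar maximisation; marginal ancestral
state probabilities combine the downward partials with upward (outside)
messages. Maximum parsimony uses a unit-cost Sankoff pass with ACCTRAN
(accelerated-transformation) resolution of ambiguity, and the root-state
confidence filter keeps trees whose most likely root state reaches 51%.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "TreeNode",
    "RootedTree",
    "AncestralResult",
    "PhyloError",
    "midpoint_root",
    "er_transition_matrix",
    "er_log_likelihood",
    "fit_er_rate",
    "marginal_ancestral",
    "acctran_parsimony",
    "root_confidence_filter",
]


class PhyloError(ValueError):
    """Raised for degenerate trees or invalid model input."""


class TreeNode:
    """A node of a rooted tree (children list, branch length to parent)."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, length={self.length})"


class RootedTree:
    """A rooted phylogenetic tree with branch lengths and unique leaf labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None for n in names):
            raise PhyloError("every leaf must be labeled")
        if len(set(names)) != len(names):
            raise PhyloError("leaf labels must be unique")
        for node in self.preorder():
            if not math.isfinite(node.length) or node.length < 0:
                raise PhyloError(f"invalid branch length {node.length} at {node.name!r}")

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs."""
        return [(n.parent, n) for n in self.preorder() if n.parent is not None]

    # -- distances ----------------------------------------------------------

    def root_distances(self) -> dict[TreeNode, float]:
        dist: dict[TreeNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                dist[node] = dist[node.parent] + node.length
        return dist

    def leaf_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """All pairwise leaf-to-leaf path lengths."""
        leaves = self.leaves()
        depth = self.root_distances()
        # ancestor chains for LCA by set intersection; trees here are small
        chains: dict[TreeNode, list[TreeNode]] = {}
        for leaf in leaves:
            chain = []
            node: TreeNode | None = leaf
            while node is not None:
                chain.append(node)
                node = node.parent
            chains[leaf] = chain
        n = len(leaves)
        mat = np.zeros((n, n))
        for i in range(n):
            anc_i = {id(x): d for d, x in enumerate(chains[leaves[i]])}
            for j in range(i + 1, n):
                lca = next(x for x in chains[leaves[j]] if id(x) in anc_i)
                d = depth[leaves[i]] + depth[leaves[j]] - 2 * depth[lca]
                mat[i, j] = mat[j, i] = d
        return [l.name for l in leaves], mat

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, rooting: str = "force-rooted") -> "RootedTree":
        """Parse a Newick string or file path (via dendropy)."""
        import dendropy

        if "(" not in source:
            with open(source) as fh:
                source = fh.read()
        try:
            dtree = dendropy.Tree.get(
                data=source, schema="newick", rooting=rooting, preserve_underscores=True
            )
        except Exception as exc:  # noqa: BLE001 - normalise parser errors
            raise PhyloError(f"cannot parse Newick input: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree) -> "RootedTree":
        def convert(dnode) -> TreeNode:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(name=label, length=dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:g}"
            inner = ",".join(fmt(c) for c in node.children)
            name = node.name or ""
            return f"({inner}){name}:{node.length:g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        if not self.root.children:
            return f"{self.root.name};"
        return f"({inner}){self.root.name or ''};"


def midpoint_root(source: str | RootedTree) -> RootedTree:
    """Root a tree at the midpoint of the longest leaf-to-leaf path.

    The input (Newick string, file path, or tree) is treated as unrooted:
    any degree-2 junction left by a previous rooting is contracted before
    the longest path is found.
    """
    tree = source if isinstance(source, RootedTree) else RootedTree.from_newick(source)
    if len(tree.leaves()) < 2:
        raise PhyloError("midpoint rooting needs at least 2 leaves")

    # undirected adjacency; contract the old degree-2 root if present
    adjacency: dict[int, list[tuple[TreeNode, float]]] = {}
    node_of: dict[int, TreeNode] = {}

    def link(a: TreeNode, b: TreeNode, w: float) -> None:
        adjacency.setdefault(id(a), []).append((b, w))
        adjacency.setdefault(id(b), []).append((a, w))
        node_of[id(a)] = a
        node_of[id(b)] = b

    for parent, child in tree.edges():
        link(parent, child, child.length)
    if not tree.root.is_leaf and len(tree.root.children) == 2:
        (a, wa), (b, wb) = adjacency[id(tree.root)]
        adjacency[id(a)] = [(n, w) for n, w in adjacency[id(a)] if n is not tree.root]
        adjacency[id(b)] = [(n, w) for n, w in adjacency[id(b)] if n is not tree.root]
        del adjacency[id(tree.root)]
        link(a, b, wa + wb)

    if sum(w for edges in adjacency.values() for _, w in edges) <= 0:
        raise PhyloError("cannot midpoint-root a zero-length tree")

    def paths_from(start: TreeNode) -> dict[int, tuple[float, list[TreeNode]]]:
        out = {id(start): (0.0, [start])}
        stack = [start]
        while stack:
            node = stack.pop()
            d, path = out[id(node)]
            for other, w in adjacency[id(node)]:
                if id(other) not in out:
                    out[id(other)] = (d + w, path + [other])
                    stack.append(other)
        return out

    leaves = [node_of[i] for i in adjacency if len(adjacency[i]) == 1]
    best = (-1.0, None)
    for leaf in leaves:
        reach = paths_from(leaf)
        for other in leaves:
            d, path = reach[id(other)]
            if d > best[0]:
                best = (d, path)
    longest, path = best
    half = longest / 2.0

    # locate the midpoint along the path
    acc = 0.0
    for a, b in zip(path, path[1:]):
        w = next(wt for n, wt in adjacency[id(a)] if n is b)
        if acc + w >= half - 1e-12:
            d_from_a = half - acc
            break
        acc += w

    def orient(node: TreeNode, come_from: TreeNode | None, length: float) -> TreeNode:
        new = TreeNode(name=node.name, length=length)
        for other, w in adjacency[id(node)]:
            if come_from is None or other is not come_from:
                new.add_child(orient(other, node, w))
        return new

    eps = 1e-12
    if d_from_a <= eps:  # midpoint falls exactly on node a
        return RootedTree(orient(a, None, 0.0))
    if d_from_a >= w - eps:  # midpoint falls exactly on node b
        return RootedTree(orient(b, None, 0.0))
    root = TreeNode(name=None, length=0.0)
    root.add_child(orient(a, b, d_from_a))
    root.add_child(orient(b, a, w - d_from_a))
    return RootedTree(root)


# ---------------------------------------------------------------------------
# Equal-rates likelihood


@dataclass
class AncestralResult:
    """Fitted rate, per-node state probabilities, and the root filter flag."""

    state_space: list
    node_probs: dict[TreeNode, np.ndarray]
    rate_q: float
    log_likelihood: float
    root_passed: bool


def er_transition_matrix(k: int, q: float, t: float) -> np.ndarray:
    """Closed-form ER transition matrix over a branch of length ``t``."""
    decay = math.exp(-k * q * t)
    stay = 1.0 / k + (1.0 - 1.0 / k) * decay
    switch = 1.0 / k - decay / k
    P = np.full((k, k), switch)
    np.fill_diagonal(P, stay)
    return P


def _tip_partial(k: int, state: int | None) -> np.ndarray:
    if state is None:
        return np.ones(k)
    if not 0 <= state < k:
        raise PhyloError(f"tip state {state} outside 0..{k - 1}")
    partial = np.zeros(k)
    partial[state] = 1.0
    return partial


def _pruning_partials(
    tree: RootedTree, tip_states: Mapping[str, int | None], k: int, q: float
) -> tuple[dict[TreeNode, np.ndarray], float]:
    """Scaled downward partials; returns (partials, summed log scale)."""
    partials: dict[TreeNode, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            partials[node] = _tip_partial(k, tip_states.get(node.name))
            continue
        partial = np.ones(k)
        for child in node.children:
            P = er_transition_matrix(k, q, child.length)
            partial = partial * (P @ partials[child])
        norm = partial.max()
        if norm <= 0:
            # impossible history (e.g. q = 0 with conflicting tips)
            partials[node] = partial
            log_scale = -math.inf
            continue
        partials[node] = partial / norm
        log_scale += math.log(norm)
    return partials, log_scale


def er_log_likelihood(
    tree: RootedTree, tip_states: Mapping[str, int | None], k: int, q: float
) -> float:
    """Felsenstein-pruning log-likelihood under ER with a flat root prior."""
    if q < 0:
        raise PhyloError("rate q must be non-negative")
    if k < 2:
        raise PhyloError("state space must have k >= 2")
    partials, log_scale = _pruning_partials(tree, tip_states, k, q)
    if not math.isfinite(log_scale):
        return -math.inf
    root_lik = partials[tree.root].sum() / k
    if root_lik <= 0:
        return -math.inf
    return math.log(root_lik) + log_scale


Q_MIN = 1e-8
Q_MAX = 100.0


def fit_er_rate(
    tree: RootedTree,
    tip_states: Mapping[str, int | None],
    k: int,
    q_max: float = Q_MAX,
) -> tuple[float, float]:
    """Maximum-likelihood ER rate by bounded scalar optimisation.

    A coarse log-grid scan brackets the optimum before Brent refinement;
    with fewer than two distinct observed tip states the likelihood is
    monotone decreasing in q and the rate pins to the lower bound.
    """
    observed = {s for s in tip_states.values() if s is not None}
    if len(observed) < 2:
        q = Q_MIN
        return q, er_log_likelihood(tree, tip_states, k, q)

    grid = np.concatenate([[Q_MIN], np.geomspace(1e-6, q_max, 60)])
    values = [er_log_likelihood(tree, tip_states, k, q) for q in grid]
    best = int(np.argmax(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    result = minimize_scalar(
        lambda q: -er_log_likelihood(tree, tip_states, k, q),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not result.success:
        raise PhyloError(f"ER rate optimisation failed: {result.message}")
    q_hat = float(result.x)
    ll = -float(result.fun)
    if values[best] > ll:  # grid point beat the refinement (flat likelihood)
        q_hat, ll = float(grid[best]), float(values[best])
    return q_hat, ll


def marginal_ancestral(
    tree: RootedTree,
    tip_states: Mapping[str, int | None],
    k: int,
    q: float,
) -> dict[TreeNode, np.ndarray]:
    """Marginal posterior state probabilities at every node.

    Downward partials are combined with upward (outside) messages; each
    returned vector is normalised to sum to 1. An observed leaf gets
    probability 1 on its observed state.
    """
    ll = er_log_likelihood(tree, tip_states, k, q)
    if not math.isfinite(ll):
        raise PhyloError("likelihood is zero at the supplied rate; marginals undefined")
    partials, _ = _pruning_partials(tree, tip_states, k, q)

    outside: dict[TreeNode, np.ndarray] = {tree.root: np.full(k, 1.0 / k)}
    for node in tree.preorder():
        for child in node.children:
            msg = outside[node].copy()
            for sib in node.children:
                if sib is not child:
                    P = er_transition_matrix(k, q, sib.length)
                    msg = msg * (P @ partials[sib])
            P_child = er_transition_matrix(k, q, child.length)
            out = msg @ P_child  # ER matrix is symmetric; P^T = P
            norm = out.max()
            outside[child] = out / norm if norm > 0 else out

    probs: dict[TreeNode, np.ndarray] = {}
    for node in tree.preorder():
        vec = partials[node] * outside[node]
        total = vec.sum()
        if total <= 0:
            raise PhyloError("underflow in marginal reconstruction")
        probs[node] = vec / total
    return probs


# ---------------------------------------------------------------------------
# Parsimony (ACCTRAN)


def acctran_parsimony(
    tree: RootedTree,
    tip_states: Mapping[str, int | None],
    k: int,
) -> tuple[dict[TreeNode, int], int]:
    """Unit-cost Sankoff parsimony with ACCTRAN ambiguity resolution.

    Works on arbitrary out-degree (multifurcations). Leaves with missing
    states contribute nothing to the score. Among equally parsimonious
    choices at a node, a state change on the current edge is preferred
    (accelerating changes toward the root), then the lowest state index.
    Returns the full node-state assignment and the minimum change count.
    """
    INF = float("inf")
    cost: dict[TreeNode, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state = tip_states.get(node.name)
            if state is None:
                cost[node] = np.zeros(k)
            else:
                vec = np.full(k, INF)
                vec[state] = 0.0
                cost[node] = vec
            continue
        total = np.zeros(k)
        for child in node.children:
            child_cost = cost[child]
            best = child_cost.min()
            # unit cost: stay free, any switch costs 1
            total += np.minimum(child_cost, best + 1.0)
        cost[node] = total

    root_cost = cost[tree.root]
    score = int(root_cost.min())
    assignment: dict[TreeNode, int] = {}
    root_state = int(np.argmin(root_cost))  # ties -> lowest index
    assignment[tree.root] = root_state
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = assignment[node.parent]
        child_cost = cost[node]
        options = child_cost + (np.arange(k) != parent_state)
        best = options.min()
        candidates = np.flatnonzero(options == best)
        changed = candidates[candidates != parent_state]
        if parent_state in candidates and changed.size:
            assignment[node] = int(changed[0])  # accelerate: change now
        elif parent_state in candidates:
            assignment[node] = parent_state
        else:
            assignment[node] = int(candidates[0])
    return assignment, score


def root_confidence_filter(root_probs: Sequence[float], threshold: float = 0.51) -> bool:
    """Keep a tree iff the most likely root state reaches the threshold."""
    probs = np.asarray(root_probs, dtype=float)
    if not math.isclose(float(probs.sum()), 1.0, rel_tol=0, abs_tol=1e-6):
        raise PhyloError("root probabilities must sum to 1")
    return bool(probs.max() >= threshold)
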