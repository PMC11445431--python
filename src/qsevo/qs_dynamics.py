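"""Ratchet statistics over annotated trees.

The frequency of quaternary-structure change is the number of parent-child
node pairs whose states differ, divided by the number of pairs where both
states could be determined. Subunit gains and losses compare subunit
counts along each determined edge (a homology-group switch at constant
stoichiometry is a change but neither a gain nor a loss). Per-orthogroup
summaries add tree shape (mean root distance, mean pairwise distance) and
cellular-location tallies (extracellular fraction, modal extracellular
quaternary structure and its agreement with the root state).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np

from .phylo_ancestral import PhyloError, RootedTree, TreeNode

__all__ = [
    "OrthogroupReport",
    "determined_states",
    "change_frequency",
    "gain_loss_counts",
    "tree_summaries",
]

State = Hashable  # any hashable state id (QSState, int, str)


@dataclass
class OrthogroupReport:
    """Per-tree summary of the reconstructed quaternary-structure history."""

    root_state: State | None
    root_probability: float | None
    change_frequency: float | None
    n_gains: int | None
    n_losses: int | None
    n_determined_pairs: int | None
    mean_interface_area: float | None
    mean_root_distance: float
    mean_pairwise_distance: float
    n_leaves: int
    n_located: int
    extracellular_fraction: float | None
    modal_extracellular_qs: State | None
    root_vs_extracellular_match: bool | None


def determined_states(
    tree: RootedTree,
    node_probs: Mapping[TreeNode, np.ndarray],
    state_space: list,
    leaf_states: Mapping[str, State | None],
    threshold: float = 0.5,
) -> dict[TreeNode, State | None]:
    """Resolve each node to a determined state or None.

    Leaves take their observed annotation (always determined when known).
    Internal nodes take the argmax of the marginal posterior when it
    strictly exceeds ``threshold`` and is unique; otherwise undetermined.
    """
    out: dict[TreeNode, State | None] = {}
    for node in tree.preorder():
        if node.is_leaf:
            out[node] = leaf_states.get(node.name)
            continue
        probs = node_probs.get(node)
        if probs is None:
            out[node] = None
            continue
        best = float(np.max(probs))
        if best > threshold and int(np.sum(probs == best)) == 1:
            out[node] = state_space[int(np.argmax(probs))]
        else:
            out[node] = None
    return out


def _determined_edges(
    tree: RootedTree, node_states: Mapping[TreeNode, State | None]
) -> list[tuple[State, State]]:
    edges = []
    for parent, child in tree.edges():
        ps = node_states.get(parent)
        cs = node_states.get(child)
        if ps is not None and cs is not None:
            edges.append((ps, cs))
    return edges


def change_frequency(
    tree: RootedTree, node_states: Mapping[TreeNode, State | None]
) -> float:
    """Fraction of determined parent-child pairs with differing states."""
    edges = _determined_edges(tree, node_states)
    if not edges:
        raise PhyloError("no parent-child pair has both states determined")
    changed = sum(1 for ps, cs in edges if ps != cs)
    return changed / len(edges)


def gain_loss_counts(
    tree: RootedTree,
    node_states: Mapping[TreeNode, State | None],
    subunit_count_of: Mapping[State, int] | None = None,
) -> tuple[int, int]:
    """(gains, losses) of subunits over determined parent-child pairs.

    ``subunit_count_of`` maps each state to its subunit count; by default
    states expose an ``n_subunits`` attribute (QSState) or are themselves
    integers. A multi-step jump on one edge counts as a single event.
    """

    def count_of(state: State) -> int:
        if subunit_count_of is not None:
            return subunit_count_of[state]
        if hasattr(state, "n_subunits"):
            return state.n_subunits
        return int(state)

    edges = _determined_edges(tree, node_states)
    if not edges:
        raise PhyloError("no parent-child pair has both states determined")
    gains = sum(1 for ps, cs in edges if count_of(cs) > count_of(ps))
    losses = sum(1 for ps, cs in edges if count_of(cs) < count_of(ps))
    return gains, losses


def tree_summaries(
    tree: RootedTree,
    leaf_states: Mapping[str, State | None],
    node_states: Mapping[TreeNode, State | None] | None = None,
    root_probs: np.ndarray | None = None,
    state_space: list | None = None,
    locations: Mapping[str, str] | None = None,
    interface_areas: Mapping[str, float] | None = None,
    subunit_count_of: Mapping[State, int] | None = None,
    min_located: int = 5,
) -> OrthogroupReport:
    """Assemble the per-orthogroup report.

    Location-dependent fields require at least ``min_located`` leaves with
    a known location; otherwise they are None while the shape and change
    statistics are still produced. Ties for the modal extracellular
    quaternary structure yield a missing mode and match flag.
    """
    leaves = tree.leaves()
    depth = tree.root_distances()
    mean_root_dist = float(np.mean([depth[l] for l in leaves]))
    if len(leaves) > 1:
        _, dmat = tree.leaf_distance_matrix()
        iu = np.triu_indices(len(leaves), k=1)
        mean_pair_dist = float(dmat[iu].mean())
    else:
        mean_pair_dist = 0.0

    root_state: State | None = None
    root_prob: float | None = None
    if root_probs is not None and state_space is not None:
        root_state = state_space[int(np.argmax(root_probs))]
        root_prob = float(np.max(root_probs))
    elif node_states is not None:
        root_state = node_states.get(tree.root)

    change_freq = n_gains = n_losses = n_pairs = None
    if node_states is not None:
        edges = _determined_edges(tree, node_states)
        n_pairs = len(edges)
        if edges:
            change_freq = change_frequency(tree, node_states)
            n_gains, n_losses = gain_loss_counts(tree, node_states, subunit_count_of)

    mean_area = None
    if interface_areas:
        vals = [v for v in interface_areas.values() if v is not None and not np.isnan(v)]
        if vals:
            mean_area = float(np.mean(vals))

    located = {
        l.name: locations[l.name]
        for l in leaves
        if locations and locations.get(l.name) not in (None, "", "unknown")
    }
    extracellular_fraction = modal_qs = match = None
    if len(located) >= min_located:
        extra = [name for name, loc in located.items() if loc == "extracellular"]
        extracellular_fraction = len(extra) / len(located)
        extra_states = [leaf_states[n] for n in extra if leaf_states.get(n) is not None]
        if extra_states:
            counts = Counter(extra_states).most_common()
            if len(counts) == 1 or counts[0][1] > counts[1][1]:
                modal_qs = counts[0][0]
                if root_state is not None:
                    match = modal_qs == root_state

    return OrthogroupReport(
        root_state=root_state,
        root_probability=root_prob,
        change_frequency=change_freq,
        n_gains=n_gains,
        n_losses=n_losses,
        n_determined_pairs=n_pairs,
        mean_interface_area=mean_area,
        mean_root_distance=mean_root_dist,
        mean_pairwise_distance=mean_pair_dist,
        n_leaves=len(leaves),
        n_located=len(located),
        extracellular_fraction=extracellular_fraction,
        modal_extracellular_qs=modal_qs,
        root_vs_extracellular_match=match,
    )
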