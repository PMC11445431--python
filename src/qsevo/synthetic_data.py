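"""Synthetic inputs with known ground truth.

Every stage of the pipeline can be exercised without downloads:

* ``gen_cn_complex`` builds Cn-symmetric toy complexes from compact
  pseudo-atom chains (one 1.9 Å sphere per residue on a jittered 3.8 Å
  lattice) placed so that adjacent subunits touch, with the contacting
  residues recorded as the ground-truth buried set;
* ``gen_birth_tree`` simulates pure-birth (Yule) trees;
* ``sim_trait_history`` runs an exact continuous-time Markov simulation of
  discrete states along the tree, recording every event;
* ``gen_conservation_scores`` and ``gen_abundance`` emit conservation and
  abundance tables with configurable interface enrichment and homomer
  abundance shift.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation_scores import AbundanceRecord, ConservationTable
from .interface_geometry import InterfaceProfile
from .phylo_ancestral import PhyloError, RootedTree, TreeNode
from .structure_sasa import AssemblyModel, AtomRecord, ResidueKey

__all__ = [
    "ToyComplexTruth",
    "SimulatedHistory",
    "PSEUDO_ATOM_RADIUS",
    "gen_cn_complex",
    "gen_birth_tree",
    "sim_trait_history",
    "gen_conservation_scores",
    "gen_abundance",
    "write_pdb",
]

#: One sphere per residue at roughly a side-chain-averaged radius.
PSEUDO_ATOM_RADIUS = 1.9
#: Lattice spacing between consecutive pseudo-atoms (CA-CA distance).
CHAIN_SPACING = 3.8
#: Random jitter amplitude applied to lattice positions (Å, uniform).
JITTER = 0.3
#: Target nearest-atom gap between adjacent subunits (Å, centre-to-centre).
CONTACT_GAP = 4.0
#: Atoms of different subunits closer than this are ground-truth contacts.
CONTACT_CUTOFF = 5.0

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class ToyComplexTruth:
    """A generated Cn toy complex plus its ground truth."""

    assembly: AssemblyModel
    buried_truth: set[ResidueKey]
    applied_transform: np.ndarray  # the Cn rotation matrix (about z)
    reference_areas: dict[str, float]  # isolated pseudo-atom sphere areas


@dataclass
class SimulatedHistory:
    """A simulated discrete-trait history with its full event log."""

    tree: RootedTree
    node_states: dict[TreeNode, int]
    event_log: list[tuple[TreeNode, float, int, int]]  # (child node, time, from, to)
    rates: np.ndarray

    @property
    def tip_states(self) -> dict[str, int]:
        return {leaf.name: self.node_states[leaf] for leaf in self.tree.leaves()}

    def replay(self) -> dict[TreeNode, int]:
        """Re-derive node states from the event log (consistency oracle)."""
        states: dict[TreeNode, int] = {self.tree.root: self.node_states[self.tree.root]}
        events_by_node: dict[int, list[tuple[float, int, int]]] = {}
        for node, t, s_from, s_to in self.event_log:
            events_by_node.setdefault(id(node), []).append((t, s_from, s_to))
        for node in self.tree.preorder():
            if node is self.tree.root:
                continue
            state = states[node.parent]
            for t, s_from, s_to in sorted(events_by_node.get(id(node), [])):
                if s_from != state:
                    raise ValueError("event log inconsistent with replay")
                state = s_to
            states[node] = state
        return states


# ---------------------------------------------------------------------------
# Toy complexes


_STEPS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _lattice_chain(n_residues: int, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding random walk on a cubic lattice, with jitter.

    The walk is confined to a bounding box with ~50% slack so distinct
    seeds yield genuinely different folds; a depth-first search with
    backtracking (neighbour order drawn from the seeded stream) guarantees
    completion inside the box.
    """
    side = 2
    while side**3 < 1.5 * n_residues:
        side += 1

    def in_box(cell):
        return all(0 <= c < side for c in cell)

    for _ in range(20):  # fresh starts are cheap; backtracking rarely fails
        start = tuple(int(v) for v in rng.integers(0, side, size=3))
        path = [start]
        occupied = {start}
        # stack of per-node untried neighbour lists (seeded random order)
        options = [list(rng.permutation(6))]
        while 0 < len(path) < n_residues:
            advanced = False
            while options[-1]:
                step = _STEPS[options[-1].pop()]
                cell = tuple(p + s for p, s in zip(path[-1], step))
                if in_box(cell) and cell not in occupied:
                    path.append(cell)
                    occupied.add(cell)
                    options.append(list(rng.permutation(6)))
                    advanced = True
                    break
            if not advanced:  # dead end: backtrack
                occupied.discard(path.pop())
                options.pop()
        if len(path) == n_residues:
            pts = np.array(path, dtype=float) * CHAIN_SPACING
            pts += rng.uniform(-JITTER, JITTER, size=pts.shape)
            return pts - pts.mean(axis=0)
    raise RuntimeError(f"could not pack a {n_residues}-residue chain (infeasible geometry)")


def _rotation_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _min_intersubunit_distance(chain: np.ndarray, offset: float, angle: float) -> float:
    a = chain + np.array([offset, 0.0, 0.0])
    b = a @ _rotation_z(angle).T
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def gen_cn_complex(
    n_subunits: int,
    n_residues: int = 30,
    seed: int = 0,
    sequence: str | None = None,
) -> ToyComplexTruth:
    """Generate a Cn-symmetric pseudo-atom complex with known buried residues.

    A compact chain is replicated by rotation about the z axis, radially
    placed so the nearest atoms of adjacent subunits sit ``CONTACT_GAP``
    apart; residues with a neighbouring-subunit atom within
    ``CONTACT_CUTOFF`` form the ground-truth buried set (empty for
    monomers). The same ``sequence`` can be supplied to make complexes
    from one orthogroup alignable; otherwise a seeded random sequence is
    drawn. Deterministic per (seed, parameters).
    """
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    if n_residues < 20:
        raise ValueError("n_residues must be >= 20")
    rng = np.random.default_rng(seed)
    chain = _lattice_chain(n_residues, rng)
    if sequence is None:
        sequence = "".join(rng.choice(list(_AA20), size=n_residues))
    elif len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")

    angle = 2.0 * math.pi / n_subunits if n_subunits > 1 else 0.0
    transform = _rotation_z(angle)

    if n_subunits == 1:
        placed = [chain]
    else:
        # bisection on the radial offset for the target inter-subunit gap
        lo, hi = 0.0, 4.0 * float(np.abs(chain).max()) + 10.0 * CONTACT_GAP
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            d = _min_intersubunit_distance(chain, mid, angle)
            if d < CONTACT_GAP:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-9:
                break
        offset = hi
        base = chain + np.array([offset, 0.0, 0.0])
        placed = [base @ _rotation_z(angle * j).T for j in range(n_subunits)]

    chains = [chr(ord("A") + j) for j in range(n_subunits)]
    atoms: list[AtomRecord] = []
    for cid, coords in zip(chains, placed):
        for i in range(n_residues):
            atoms.append(
                AtomRecord(
                    element="C",
                    coords=coords[i],
                    radius=PSEUDO_ATOM_RADIUS,
                    residue_key=(cid, i + 1, ""),
                    residue_name=_ONE_TO_THREE[sequence[i]],
                )
            )
    assembly = AssemblyModel(
        atoms=atoms,
        chains=chains,
        sequences={cid: sequence for cid in chains},
        n_subunits=n_subunits,
    )

    buried: set[ResidueKey] = set()
    if n_subunits > 1:
        all_coords = np.array([np.asarray(p) for p in placed])
        for j, coords in enumerate(placed):
            others = np.concatenate([all_coords[m] for m in range(n_subunits) if m != j])
            d2 = ((coords[:, None, :] - others[None, :, :]) ** 2).sum(axis=2)
            close = np.sqrt(d2.min(axis=1)) < CONTACT_CUTOFF
            for i in np.flatnonzero(close):
                buried.add((chains[j], int(i) + 1, ""))

    sphere_area = 4.0 * math.pi * (PSEUDO_ATOM_RADIUS + 1.4) ** 2
    reference_areas = {three: sphere_area for three in _ONE_TO_THREE.values()}
    return ToyComplexTruth(
        assembly=assembly,
        buried_truth=buried,
        applied_transform=transform,
        reference_areas=reference_areas,
    )


def write_pdb(assembly: AssemblyModel, path: str | Path) -> None:
    """Write an assembly as a minimal fixed-column PDB file (CA records)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(assembly.atoms)
    array = struc.AtomArray(n)
    for i, atom in enumerate(assembly.atoms):
        array.coord[i] = atom.coords
        array.chain_id[i] = atom.residue_key[0]
        array.res_id[i] = atom.residue_key[1]
        array.ins_code[i] = atom.residue_key[2]
        array.res_name[i] = atom.residue_name
        array.atom_name[i] = "CA"
        array.element[i] = atom.element
        array.hetero[i] = atom.is_hetero
    pdb = PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Trees and trait histories


def gen_birth_tree(
    n_leaves: int | None = None,
    seed: int = 0,
    birth_rate: float = 1.0,
    max_time: float | None = None,
) -> RootedTree:
    """Pure-birth (Yule) tree, unit birth rate by default.

    Exactly one of ``n_leaves`` (stop at that many extant lineages, then
    extend all tips by one further waiting time) or ``max_time`` (grow to
    a fixed height) must be given. Deterministic per seed.
    """
    if (n_leaves is None) == (max_time is None):
        raise ValueError("specify exactly one of n_leaves or max_time")
    if n_leaves is not None and n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = np.random.default_rng(seed)

    root = TreeNode(name=None, length=0.0)
    active: list[TreeNode] = [root]
    pending: dict[int, float] = {id(root): 0.0}  # birth time of each active branch
    t = 0.0
    counter = 0
    while True:
        k = len(active)
        wait = rng.exponential(1.0 / (birth_rate * k))
        if max_time is not None and t + wait >= max_time:
            for node in active:
                node.length = max_time - pending[id(node)]
            break
        t += wait
        idx = int(rng.integers(k))
        node = active.pop(idx)
        node.length = t - pending.pop(id(node))
        for _ in range(2):
            child = TreeNode(name=None, length=0.0)
            node.add_child(child)
            active.append(child)
            pending[id(child)] = t
        if n_leaves is not None and len(active) == n_leaves:
            final_wait = rng.exponential(1.0 / (birth_rate * len(active)))
            for leaf in active:
                leaf.length = t + final_wait - pending[id(leaf)]
            break

    for i, leaf in enumerate(n for n in _preorder(root) if not n.children):
        leaf.name = f"t{i + 1}"
    return RootedTree(root)


def _preorder(node: TreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def sim_trait_history(
    tree: RootedTree,
    rates: np.ndarray,
    root_state: int,
    seed: int = 0,
) -> SimulatedHistory:
    """Exact stochastic simulation of a CTMC along every branch.

    ``rates`` is a k x k generator matrix (rows sum to zero, off-diagonal
    rates non-negative). Waiting times are exponential with the current
    state's total exit rate; every change is logged as
    (child node, time along branch, from, to).
    """
    Q = np.asarray(rates, dtype=float)
    k = Q.shape[0]
    if Q.shape != (k, k) or not np.allclose(Q.sum(axis=1), 0.0, atol=1e-9):
        raise ValueError("rates must be a square generator matrix with zero row sums")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < 0).any():
        raise ValueError("off-diagonal rates must be non-negative")
    if not 0 <= root_state < k:
        raise ValueError("root_state outside the state space")

    rng = np.random.default_rng(seed)
    node_states: dict[TreeNode, int] = {tree.root: root_state}
    event_log: list[tuple[TreeNode, float, int, int]] = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        state = node_states[node.parent]
        t = 0.0
        while True:
            exit_rate = -Q[state, state]
            if exit_rate <= 0:
                break
            t += rng.exponential(1.0 / exit_rate)
            if t >= node.length:
                break
            probs = off[state] / exit_rate
            new_state = int(rng.choice(k, p=probs))
            event_log.append((node, t, state, new_state))
            state = new_state
        node_states[node] = state
    return SimulatedHistory(tree=tree, node_states=node_states, event_log=event_log, rates=Q)


# ---------------------------------------------------------------------------
# Annotation tables


def gen_conservation_scores(
    profile: InterfaceProfile | Mapping[ResidueKey, str],
    interface_shift: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ConservationTable:
    """Conservation scores with configurable interface enrichment.

    Non-interface residues draw from Normal(0, noise_sd); interface
    residues from Normal(-interface_shift, noise_sd) — lower scores mean
    more conserved, so a positive shift makes interfaces more conserved.
    """
    region_of = profile.region_of if isinstance(profile, InterfaceProfile) else dict(profile)
    if not region_of:
        raise ValueError("profile has no residues")
    rng = np.random.default_rng(seed)
    scores: dict[ResidueKey, float] = {}
    for key in sorted(region_of):
        mean = -interface_shift if region_of[key] == "interface" else 0.0
        scores[key] = float(rng.normal(mean, noise_sd))
    return ConservationTable(scores=scores)


def gen_abundance(
    n_monomers: int,
    n_homomers: int,
    log_mean: float = 3.0,
    log_sd: float = 1.0,
    homomer_log_shift: float = math.log(2.0),
    subunit_dist: Mapping[int, float] | None = None,
    seed: int = 0,
) -> list[AbundanceRecord]:
    """Lognormal abundance tables (ppm) with a homomer shift.

    Monomer abundances are LogNormal(log_mean, log_sd) (natural-log
    parameters); homomers are shifted up by ``homomer_log_shift`` and
    their subunit counts drawn from ``subunit_dist`` (default: dimers 60%,
    tetramers 30%, octamers 10% — the dominant PDB homomer stoichiometries).
    """
    if subunit_dist is None:
        subunit_dist = {2: 0.6, 4: 0.3, 8: 0.1}
    counts = sorted(subunit_dist)
    probs = np.array([subunit_dist[c] for c in counts], dtype=float)
    if not math.isclose(float(probs.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("subunit_dist probabilities must sum to 1")

    rng = np.random.default_rng(seed)
    records: list[AbundanceRecord] = []
    for i in range(n_monomers):
        ab = float(rng.lognormal(log_mean, log_sd))
        records.append(AbundanceRecord(f"mono{i + 1}", ab, 1, ab))
    for i in range(n_homomers):
        ab = float(rng.lognormal(log_mean + homomer_log_shift, log_sd))
        n_sub = int(rng.choice(counts, p=probs))
        records.append(AbundanceRecord(f"homo{i + 1}", ab, n_sub, ab / n_sub))
    return records
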