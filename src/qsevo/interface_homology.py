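"""Interface overlap, interface-homology grouping, and quaternary-structure states.

Two homologous complexes share a homologous interface when at least half of
the smaller interface's residues are structurally corresponded with the
other interface's residues. Connected components of the resulting graph
define interface-homology groups; a multi-state quaternary-structure (QS)
state is the pair (subunit count, homology group), so complexes with the
same stoichiometry but independent interfaces occupy distinct states.
Homomers with interfaces below 1000 Å² are treated as probable QS errors
and reclassified as monomers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .interface_geometry import InterfaceProfile
from .structural_superposition import Correspondence
from .structure_sasa import ResidueKey

__all__ = [
    "OverlapMatrix",
    "QSState",
    "MONOMER_STATE",
    "interface_overlap",
    "build_overlap_matrix",
    "homology_groups",
    "assign_states",
    "qs_error_filter",
]


@dataclass(frozen=True, eq=False)
class QSState:
    """A quaternary-structure state, binary or multi-state.

    All monomers share a single state. In multi-state mode the identity is
    the pair (subunit count, interface-homology group); in binary mode it
    collapses to monomer vs homomer (the recorded subunit count is kept
    for bookkeeping but does not enter state identity).
    """

    kind: str  # "binary" | "multi"
    is_homomer: bool
    n_subunits: int = 1
    homology_group: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if not self.is_homomer and (self.n_subunits != 1 or self.homology_group != 0):
            raise ValueError("monomer state must have n_subunits=1 and homology_group=0")

    def _identity(self) -> tuple:
        if self.kind == "binary":
            return (self.kind, self.is_homomer)
        return (self.kind, self.is_homomer, self.n_subunits, self.homology_group)

    def __eq__(self, other) -> bool:
        if not isinstance(other, QSState):
            return NotImplemented
        return self._identity() == other._identity()

    def __hash__(self) -> int:
        return hash(self._identity())

    @property
    def label(self) -> str:
        if not self.is_homomer:
            return "monomer"
        if self.kind == "binary":
            return "homomer"
        return f"{self.n_subunits}mer-g{self.homology_group}"


MONOMER_STATE_BINARY = QSState(kind="binary", is_homomer=False)
MONOMER_STATE = QSState(kind="multi", is_homomer=False)


@dataclass
class OverlapMatrix:
    """Pairwise interface overlaps and TM-scores over an ordered protein set.

    Undefined comparisons (a protein with an empty interface) are NaN and
    are skipped when averaging.
    """

    proteins: list[str]
    overlap: np.ndarray
    tm: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.proteins)
        self.overlap = np.asarray(self.overlap, dtype=float)
        if self.overlap.shape != (n, n):
            raise ValueError("overlap matrix shape must match protein list")
        if not np.allclose(
            np.nan_to_num(self.overlap), np.nan_to_num(self.overlap.T), atol=1e-12
        ):
            raise ValueError("overlap matrix must be symmetric")

    def mean_overlap(self) -> float:
        iu = np.triu_indices(len(self.proteins), k=1)
        vals = self.overlap[iu]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    def mean_tm(self) -> float:
        if self.tm is None:
            return float("nan")
        iu = np.triu_indices(len(self.proteins), k=1)
        vals = self.tm[iu]
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def interface_overlap(
    pairsAB: Correspondence,
    interfaceA: Iterable[ResidueKey],
    interfaceB: Iterable[ResidueKey],
) -> float | None:
    """Fraction of corresponded pairs that are interface on both sides.

    Normalised by the smaller interface; returns None (undefined) when
    either interface is empty, so callers can exclude it from averages.
    """
    setA = set(interfaceA)
    setB = set(interfaceB)
    if not setA or not setB:
        return None
    shared = sum(1 for a, b in pairsAB.pairs if a in setA and b in setB)
    return shared / min(len(setA), len(setB))


def build_overlap_matrix(
    proteins: list[str],
    interfaces: Mapping[str, set[ResidueKey]],
    correspondences: Mapping[tuple[str, str], Correspondence],
    tm_scores: Mapping[tuple[str, str], float] | None = None,
) -> OverlapMatrix:
    """Assemble the symmetric overlap (and TM-score) matrix for an orthogroup."""
    n = len(proteins)
    overlap = np.full((n, n), np.nan)
    tm = np.full((n, n), np.nan) if tm_scores is not None else None
    for i, a in enumerate(proteins):
        overlap[i, i] = 1.0 if interfaces.get(a) else np.nan
        if tm is not None:
            tm[i, i] = 1.0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = proteins[i], proteins[j]
            corr = correspondences.get((a, b))
            if corr is None:
                corr = correspondences.get((b, a))
                if corr is not None:
                    corr = Correspondence(
                        pairs=[(x, y) for y, x in corr.pairs], method=corr.method
                    )
            if corr is None:
                continue
            val = interface_overlap(corr, interfaces.get(a, set()), interfaces.get(b, set()))
            overlap[i, j] = overlap[j, i] = np.nan if val is None else val
            if tm is not None:
                score = tm_scores.get((a, b), tm_scores.get((b, a), np.nan))
                tm[i, j] = tm[j, i] = score
    return OverlapMatrix(proteins=list(proteins), overlap=overlap, tm=tm)


def homology_groups(matrix: OverlapMatrix, threshold: float = 0.5) -> dict[str, int]:
    """Connected components of the overlap-above-threshold graph.

    Group ids are dense integers starting at 1, numbered by each
    component's lexicographically smallest member, so the output is
    independent of input order.
    """
    graph = nx.Graph()
    graph.add_nodes_from(matrix.proteins)
    n = len(matrix.proteins)
    for i in range(n):
        for j in range(i + 1, n):
            val = matrix.overlap[i, j]
            if not np.isnan(val) and val >= threshold:
                graph.add_edge(matrix.proteins[i], matrix.proteins[j])
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    groups: dict[str, int] = {}
    for gid, comp in enumerate(components, start=1):
        for protein in comp:
            groups[protein] = gid
    return groups


def assign_states(
    n_subunits: Mapping[str, int | None],
    groups: Mapping[str, int] | None = None,
    mode: str = "multi",
) -> dict[str, QSState | None]:
    """Map proteins to QS states; unknown subunit counts map to None."""
    if mode not in {"binary", "multi"}:
        raise ValueError(f"unknown state mode {mode!r}")
    states: dict[str, QSState | None] = {}
    for protein, count in n_subunits.items():
        if count is None:
            states[protein] = None
        elif count == 1:
            states[protein] = MONOMER_STATE_BINARY if mode == "binary" else MONOMER_STATE
        elif mode == "binary":
            states[protein] = QSState(kind="binary", is_homomer=True, n_subunits=count)
        else:
            gid = (groups or {}).get(protein, 1)
            states[protein] = QSState(
                kind="multi", is_homomer=True, n_subunits=count, homology_group=gid
            )
    return states


def qs_error_filter(
    profile: InterfaceProfile | float,
    state: QSState | None,
    min_area: float = 1000.0,
) -> QSState | None:
    """Reclassify small-interface homomers (< ``min_area`` Å²) as monomers.

    ``profile`` may be an :class:`InterfaceProfile` or a bare interface
    area in Å².
    """
    if state is None or not state.is_homomer:
        return state
    area = profile.interface_area if isinstance(profile, InterfaceProfile) else float(profile)
    if area < min_area:
        return MONOMER_STATE_BINARY if state.kind == "binary" else MONOMER_STATE
    return state
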