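"""Residue correspondence, rigid superposition, and TM-score.

Homologous subunits are compared by (i) establishing a residue-level
correspondence from a global sequence alignment (the subunits being
orthologs, sequence alignment is reliable), (ii) least-squares rigid
superposition of the corresponded representative atoms with iterative
rejection of far pairs, and (iii) a TM-score normalised by the smaller
chain. An externally produced correspondence (e.g. from a structural
aligner) can be injected in place of step (i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structure_sasa import AssemblyModel, ResidueKey

__all__ = [
    "Correspondence",
    "SuperpositionResult",
    "SuperpositionError",
    "sequence_guided_correspondence",
    "kabsch",
    "tm_score",
    "tm_d0",
    "iterative_superpose",
]


class SuperpositionError(ValueError):
    """Raised for degenerate geometry or unusable correspondences."""


@dataclass
class Correspondence:
    """Ordered, colinear residue pairs between two structures."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    method: str = "sequence-guided"

    def __post_init__(self) -> None:
        a_seen: set[ResidueKey] = set()
        b_seen: set[ResidueKey] = set()
        for a, b in self.pairs:
            if a in a_seen or b in b_seen:
                raise SuperpositionError("residue appears in more than one pair")
            a_seen.add(a)
            b_seen.add(b)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1; maps B frame onto A
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    tm_score: float | None = None
    n_aligned: int = 0

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def sequence_guided_correspondence(
    seqA: str,
    seqB: str,
    keysA: Sequence[ResidueKey] | None = None,
    keysB: Sequence[ResidueKey] | None = None,
    substitution_table: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Correspondence:
    """Global affine-gap alignment; matched columns become residue pairs.

    Ties in the alignment are resolved deterministically (first optimal
    alignment of the dynamic program).
    """
    if len(seqA) < 10 or len(seqB) < 10:
        raise SuperpositionError("sequences must be at least 10 residues long")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_table)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    alignment = aligner.align(seqA.upper(), seqB.upper())[0]

    if keysA is None:
        keysA = [("A", i + 1, "") for i in range(len(seqA))]
    if keysB is None:
        keysB = [("B", i + 1, "") for i in range(len(seqB))]
    if len(keysA) != len(seqA) or len(keysB) != len(seqB):
        raise SuperpositionError("residue key lists must match sequence lengths")

    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    blocks_a, blocks_b = alignment.aligned
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for off in range(a1 - a0):
            pairs.append((keysA[a0 + off], keysB[b0 + off]))
    return Correspondence(pairs=pairs, method="sequence-guided")


def kabsch(coordsA: np.ndarray, coordsB: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of B onto A (reflections excluded)."""
    A = np.asarray(coordsA, dtype=float)
    B = np.asarray(coordsB, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise SuperpositionError("paired coordinate arrays of shape (n, 3) required")
    n = A.shape[0]
    if n < 3:
        raise SuperpositionError("at least 3 pairs required")
    centA = A.mean(axis=0)
    centB = B.mean(axis=0)
    A0 = A - centA
    B0 = B - centB
    if np.linalg.matrix_rank(A0, tol=1e-8) < 2 or np.linalg.matrix_rank(B0, tol=1e-8) < 2:
        raise SuperpositionError("collinear or degenerate point configuration")

    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = centA - R @ centB
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_aligned=n)


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale d0 for a normalising length, floored at 0.5 Å."""
    if l_norm <= 15:
        return 0.5
    return max(0.5, 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8)


def tm_score(distances: Sequence[float], l_norm: int) -> float:
    """TM-score of superposed residue-pair distances, normalised by ``l_norm``."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise SuperpositionError("TM-score undefined for an empty correspondence")
    if l_norm < 1:
        raise SuperpositionError("normalising length must be positive")
    d0 = tm_d0(l_norm)
    return float(np.sum(1.0 / (1.0 + (distances / d0) ** 2)) / l_norm)


def iterative_superpose(
    structA: AssemblyModel,
    structB: AssemblyModel,
    chainA: str | None = None,
    chainB: str | None = None,
    correspondence: Correspondence | None = None,
    reject_cutoff: float = 5.0,
    max_iter: int = 20,
) -> tuple[Correspondence, SuperpositionResult]:
    """Superpose two chains: alternate Kabsch fit and far-pair rejection.

    The fit is repeated on the retained pairs until the retained set is
    stable or ``max_iter`` is reached. The returned RMSD is over the final
    retained pairs; the TM-score is over *all* corresponded pairs, with
    the normalising length the smaller chain's residue count.
    """
    chainA = chainA or structA.chains[0]
    chainB = chainB or structB.chains[0]
    keysA, coordsA = structA.representative_coords(chainA)
    keysB, coordsB = structB.representative_coords(chainB)
    if len(keysA) < 10 or len(keysB) < 10:
        raise SuperpositionError("chains must have representative atoms for >= 10 residues")

    if correspondence is None:
        correspondence = sequence_guided_correspondence(
            structA.sequences[chainA],
            structB.sequences[chainB],
            keysA=keysA,
            keysB=keysB,
        )

    idxA = {k: i for i, k in enumerate(keysA)}
    idxB = {k: i for i, k in enumerate(keysB)}
    pair_idx = [
        (idxA[a], idxB[b]) for a, b in correspondence.pairs if a in idxA and b in idxB
    ]
    if len(pair_idx) < 3:
        raise SuperpositionError("fewer than 3 corresponded residues with coordinates")
    ia = np.array([p[0] for p in pair_idx])
    ib = np.array([p[1] for p in pair_idx])
    allA = coordsA[ia]
    allB = coordsB[ib]

    # rejection is monotone: a pair once rejected never re-enters, so the
    # retained set shrinks and the retained-pair RMSD does not increase
    retained = np.ones(len(pair_idx), dtype=bool)
    result = kabsch(allA, allB)
    for _ in range(max_iter):
        d = np.linalg.norm(allA - result.transform(allB), axis=1)
        new_retained = retained & (d <= reject_cutoff)
        if new_retained.sum() < 3:
            raise SuperpositionError("fewer than 3 pairs survive distance rejection")
        if np.array_equal(new_retained, retained):
            break
        retained = new_retained
        result = kabsch(allA[retained], allB[retained])

    d_all = np.linalg.norm(allA - result.transform(allB), axis=1)
    l_norm = min(len(keysA), len(keysB))
    score = tm_score(d_all, l_norm)
    final = SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        tm_score=score,
        n_aligned=int(retained.sum()),
    )
    return correspondence, final
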