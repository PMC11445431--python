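"""Conservation differentials, synthesis costs, and subunit-scaled abundance.

Interface conservation is judged against the solvent-accessible surface of
the same protein: the statistic is the difference of mean normalised
conservation scores (interface minus surface; by the ConSurf convention
lower means more conserved) with a two-sided Wilcoxon rank-sum test.
Synthesis cost is the mean number of high-energy phosphate bonds required
per residue. Scaled abundance divides a protein's abundance (ppm) by its
complex's subunit count, approximating the particle concentration; a
predicted homomer without a known stoichiometry can be assumed dimeric.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .structure_sasa import ResidueKey

__all__ = [
    "ConservationTable",
    "AbundanceRecord",
    "load_cost_table",
    "conservation_differential",
    "region_cost",
    "scaled_abundance",
    "read_conservation_tsv",
    "write_conservation_tsv",
]


@dataclass
class ConservationTable:
    """Per-residue normalised conservation scores (lower = more conserved)."""

    scores: dict[ResidueKey, float]

    def __post_init__(self) -> None:
        for key, score in self.scores.items():
            if not np.isfinite(score):
                raise ValueError(f"non-finite conservation score at {key}")

    def region_scores(self, residues: Sequence[ResidueKey]) -> list[float]:
        return [self.scores[k] for k in residues if k in self.scores]


@dataclass
class AbundanceRecord:
    protein_id: str
    abundance: float  # ppm
    n_subunits: int
    scaled_abundance: float

    def __post_init__(self) -> None:
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")


_COST_ANCHORS = {"A": 11.0, "G": 11.0, "S": 11.0, "W": 74.0}


def load_cost_table(path: str | Path | None = None) -> dict[str, float]:
    """Amino-acid synthesis costs in phosphate bonds (~P).

    The shipped table is checked against its anchor values at load time
    (Ala/Gly/Ser = 11, Trp = 74).
    """
    if path is None:
        fh = resources.files("qsevo.data").joinpath("aa_synthesis_cost.csv").open()
    else:
        fh = open(path)
    with fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    table = {aa: float(cost) for aa, cost in rows[1:]}
    if len(table) != 20 or any(v <= 0 for v in table.values()):
        raise ValueError("cost table must have 20 positive entries")
    for aa, expected in _COST_ANCHORS.items():
        if table[aa] != expected:
            raise ValueError(f"cost table anchor violated: {aa} = {table[aa]}, expected {expected}")
    return table


def conservation_differential(
    iface_scores: Sequence[float],
    surf_scores: Sequence[float],
    alpha: float = 0.05,
    lower_is_conserved: bool = True,
) -> tuple[float, float, bool]:
    """(mean difference, p-value, significantly-more-conserved flag).

    The mean difference is interface minus surface. The flag is true only
    when the interface is more conserved *and* the two-sided rank-sum test
    rejects at ``alpha``.
    """
    if len(iface_scores) < 3 or len(surf_scores) < 3:
        raise ValueError("need at least 3 residues in each region")
    iface = np.asarray(iface_scores, dtype=float)
    surf = np.asarray(surf_scores, dtype=float)
    diff = float(iface.mean() - surf.mean())
    stat = stats.ranksums(iface, surf)
    p = float(stat.pvalue)
    conserved_direction = diff < 0 if lower_is_conserved else diff > 0
    return diff, p, bool(conserved_direction and p < alpha)


def region_cost(residues: Sequence[str], table: Mapping[str, float] | None = None) -> float:
    """Mean synthesis cost (phosphate bonds per residue) of a region."""
    if not residues:
        raise ValueError("empty region has no synthesis cost")
    if table is None:
        table = load_cost_table()
    try:
        return float(np.mean([table[r.upper()] for r in residues]))
    except KeyError as exc:
        raise KeyError(f"unknown amino acid letter {exc.args[0]!r}") from exc


def scaled_abundance(
    protein_id: str,
    abundance: float,
    n_subunits: int | None,
    is_homomer: bool = False,
    assume_dimer: bool = True,
) -> AbundanceRecord:
    """Scale an abundance (ppm) by subunit count (~particle concentration).

    A homomer with an unknown subunit count is assumed dimeric when
    ``assume_dimer`` is set; otherwise the missing count is an error.
    """
    if abundance < 0:
        raise ValueError("abundance must be non-negative")
    if n_subunits is None:
        if is_homomer and assume_dimer:
            n_subunits = 2
        elif not is_homomer:
            n_subunits = 1
        else:
            raise ValueError(f"unknown subunit count for homomer {protein_id!r}")
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    return AbundanceRecord(
        protein_id=protein_id,
        abundance=float(abundance),
        n_subunits=int(n_subunits),
        scaled_abundance=float(abundance) / int(n_subunits),
    )


def read_conservation_tsv(path: str | Path) -> ConservationTable:
    """Read a (chain, resnum, icode, score) TSV into a ConservationTable."""
    scores: dict[ResidueKey, float] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        for row in reader:
            chain, resnum, icode, score = row[:4]
            scores[(chain, int(resnum), icode)] = float(score)
    return ConservationTable(scores=scores)


def write_conservation_tsv(path: str | Path, table: ConservationTable) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["chain", "resnum", "icode", "score"])
        for (chain, resnum, icode), score in table.scores.items():
            writer.writerow([chain, resnum, icode, f"{score:.6f}"])
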