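"""Interface, surface and core calling, interface area, and related descriptors.

A residue is an interface residue when assembly buries more than
``delta_frac`` (default 10%) of its isolated-subunit SASA *and* its
isolated-subunit RSA exceeds ``rsa_min`` (default 20%); non-interface
residues above the RSA threshold are surface; everything else is core.
Per-complex interface area is the total SASA lost on assembly divided by
the number of subunits; relative buried surface is the same loss divided
by the summed subunit SASA.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .structure_sasa import (
    ComplexPartition,
    ResidueKey,
    SasaResult,
    StructureError,
    miller_reference_areas,
    relative_accessibility,
    shrake_rupley,
)

__all__ = [
    "InterfaceProfile",
    "HYDROPHOBIC_RESIDUES",
    "compute_assembly_sasa",
    "call_regions",
    "interface_area",
    "relative_buried_surface",
    "hydrophobic_fraction",
    "molecular_weight",
    "residue_masses",
]

#: Residues counted as hydrophobic in interface/surface composition.
HYDROPHOBIC_RESIDUES = frozenset("CFILMVW")

_ONE_FROM_THREE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class InterfaceProfile:
    """Region labels plus the per-complex interface summary statistics."""

    region_of: dict[ResidueKey, str]  # interface | surface | core
    interface_area: float  # Å² per subunit
    relative_buried: float  # fraction of subunit surface buried on assembly
    hydrophobic_fraction_interface: float | None = None
    hydrophobic_fraction_surface: float | None = None
    n_subunits: int = 1
    residue_names: dict[ResidueKey, str] = field(default_factory=dict)

    def residues_in(self, region: str, chain: str | None = None) -> list[ResidueKey]:
        return [
            k
            for k, r in self.region_of.items()
            if r == region and (chain is None or k[0] == chain)
        ]


def compute_assembly_sasa(
    partition: ComplexPartition,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> tuple[SasaResult, SasaResult]:
    """SASA of the assembled complex and of the isolated subunits (merged)."""
    sasa_complex = shrake_rupley(partition.complex.atoms, probe_radius, n_points)
    sasa_subunits = SasaResult.merge(
        shrake_rupley(sub.atoms, probe_radius, n_points) for sub in partition.subunits
    )
    return sasa_complex, sasa_subunits


def call_regions(
    partition: ComplexPartition,
    sasa_complex: SasaResult,
    sasa_subunits: SasaResult,
    delta_frac: float = 0.10,
    rsa_min: float = 0.20,
    reference_areas: Mapping[str, float] | None = None,
    hydrophobicity_chain: str | None = "first",
) -> InterfaceProfile:
    """Partition residues into interface / surface / core and summarise.

    Both inequalities are strict: buried fraction must exceed ``delta_frac``
    of the subunit SASA, and subunit RSA must exceed ``rsa_min``. Residues
    with zero subunit SASA cannot satisfy either rule and fall to core.
    Hydrophobic fractions are computed on the first subunit's residues by
    default (``hydrophobicity_chain``: a chain id, "first", or None for all
    chains).
    """
    residue_names = partition.complex.residue_names
    missing = sasa_complex.per_residue.keys() - sasa_subunits.per_residue.keys()
    if missing:
        raise StructureError(
            f"residues present in complex but not subunits: {sorted(missing)[:3]}"
        )
    rsa = relative_accessibility(
        sasa_subunits, residue_names, reference_areas=reference_areas
    )

    region_of: dict[ResidueKey, str] = {}
    for key, sub_area in sasa_subunits.per_residue.items():
        cx_area = sasa_complex.per_residue.get(key, 0.0)
        delta = sub_area - cx_area
        if sub_area > 0 and delta > delta_frac * sub_area and rsa[key] > rsa_min:
            region_of[key] = "interface"
        elif rsa[key] > rsa_min:
            region_of[key] = "surface"
        else:
            region_of[key] = "core"

    n_sub = len(partition.subunits)
    area = interface_area(sasa_subunits.total, sasa_complex.total, n_sub)
    rel_buried = relative_buried_surface(sasa_subunits.total, sasa_complex.total)

    if hydrophobicity_chain == "first":
        hydro_chain: str | None = partition.complex.chains[0]
    else:
        hydro_chain = hydrophobicity_chain

    def _hydro(region: str) -> float | None:
        keys = [
            k for k, r in region_of.items() if r == region and (hydro_chain is None or k[0] == hydro_chain)
        ]
        if not keys:
            return None
        return hydrophobic_fraction(
            [_ONE_FROM_THREE.get(residue_names[k], "X") for k in keys]
        )

    return InterfaceProfile(
        region_of=region_of,
        interface_area=area,
        relative_buried=rel_buried,
        hydrophobic_fraction_interface=_hydro("interface"),
        hydrophobic_fraction_surface=_hydro("surface"),
        n_subunits=n_sub,
        residue_names=dict(residue_names),
    )


def interface_area(
    sasa_subunits_total: float,
    sasa_complex_total: float,
    n_subunits: int,
    tolerance: float = 1e-6,
) -> float:
    """Interface size: total SASA buried on assembly per subunit (Å²)."""
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    if sasa_subunits_total < 0 or sasa_complex_total < 0:
        raise ValueError("SASA totals must be non-negative")
    diff = sasa_subunits_total - sasa_complex_total
    if diff < -tolerance * max(sasa_subunits_total, 1.0):
        raise StructureError(
            "complex SASA exceeds summed subunit SASA: "
            f"{sasa_complex_total:.3f} > {sasa_subunits_total:.3f}"
        )
    return max(diff, 0.0) / n_subunits


def relative_buried_surface(
    sasa_subunits_total: float, sasa_complex_total: float
) -> float:
    """Fraction of the summed subunit SASA buried in the assembly, in [0, 1]."""
    if sasa_subunits_total <= 0:
        raise ZeroDivisionError("summed subunit SASA must be positive")
    if sasa_complex_total == 0:
        warnings.warn("complex SASA is zero; relative buried surface pinned to 1", stacklevel=2)
        return 1.0
    frac = (sasa_subunits_total - sasa_complex_total) / sasa_subunits_total
    return min(max(frac, 0.0), 1.0)


def hydrophobic_fraction(residues: Sequence[str]) -> float:
    """Fraction of C, F, I, L, M, V, W residues in a region (1-letter codes)."""
    if not residues:
        raise ValueError("empty region has no hydrophobic fraction")
    hydro = sum(1 for r in residues if r.upper() in HYDROPHOBIC_RESIDUES)
    return hydro / len(residues)


def residue_masses() -> dict[str, float]:
    """Water-subtracted average residue masses (Da) keyed by 1-letter code."""
    with resources.files("qsevo.data").joinpath("residue_masses.csv").open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    return {aa: float(mass) for aa, mass in rows[1:]}


def molecular_weight(
    sequence: str,
    n_subunits: int = 1,
    exclude_ranges: Iterable[tuple[int, int]] = (),
    masses: Mapping[str, float] | None = None,
) -> float:
    """Complex molecular weight: summed residue masses times subunit count.

    ``exclude_ranges`` are 1-based inclusive position ranges (signal or
    transit peptides) removed before summing.
    """
    if masses is None:
        masses = residue_masses()
    excluded: set[int] = set()
    for start, end in exclude_ranges:
        excluded.update(range(start, end + 1))
    kept = [aa for pos, aa in enumerate(sequence, start=1) if pos not in excluded]
    if not kept:
        raise ValueError("sequence is empty after exclusions")
    try:
        mass = sum(masses[aa.upper()] for aa in kept)
    except KeyError as exc:
        raise KeyError(f"unknown amino acid letter {exc.args[0]!r}") from exc
    return mass * n_subunits
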