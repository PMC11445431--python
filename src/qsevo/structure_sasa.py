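"""Structure parsing, complex partitioning, and solvent-accessible surface area.

Quaternary-structure analysis starts from the solvent-accessible surface
area (SASA) of every residue, computed three ways: in the assembled complex,
in each isolated subunit, and (for monomers) in the single chain. The SASA
implementation is a deterministic Shrake–Rupley quadrature: each atom is
inflated by the probe radius (water, 1.4 Å), sampled with a golden-section
spiral point set, and points falling inside any neighbouring inflated atom
are counted as buried. Relative solvent accessibility (RSA) divides a
residue's SASA by its maximal reference area (Miller et al. tripeptide
values by default).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "AssemblyModel",
    "ComplexPartition",
    "SasaResult",
    "DEFAULT_RADII",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_N_POINTS",
    "StructureError",
    "read_structure",
    "partition_complex",
    "shrake_rupley",
    "relative_accessibility",
    "miller_reference_areas",
    "sphere_points",
    "write_rsa_table",
]

# NACCESS/Chothia-style van der Waals radii (Å) keyed by element symbol.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.00,
    "D": 1.00,
}
DEFAULT_RADIUS_FALLBACK = 1.80

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "SOL"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

ResidueKey = tuple[str, int, str]


class StructureError(ValueError):
    """Raised for unparseable, empty, or inconsistent structural input."""


@dataclass
class AtomRecord:
    """One (heavy) atom: element, coordinates, radius, and residue identity."""

    element: str
    coords: np.ndarray
    radius: float
    residue_key: ResidueKey  # (chain id, author residue number, insertion code)
    residue_name: str
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom coordinates must be a finite 3-vector, got {self.coords!r}")
        if not self.radius > 0:
            raise StructureError(f"atom radius must be positive, got {self.radius}")


@dataclass
class AssemblyModel:
    """A multi-chain structure: atoms, chain order, and per-chain sequences."""

    atoms: list[AtomRecord]
    chains: list[str]
    sequences: dict[str, str]
    n_subunits: int = 1

    def __post_init__(self) -> None:
        chain_set = set(self.chains)
        for atom in self.atoms:
            if atom.residue_key[0] not in chain_set:
                raise StructureError(f"atom chain {atom.residue_key[0]!r} not in declared chains")
        if self.n_subunits < 1:
            raise StructureError("n_subunits must be >= 1")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def residue_keys(self) -> list[ResidueKey]:
        """Residue keys in first-occurrence order."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    @property
    def residue_names(self) -> dict[ResidueKey, str]:
        return {a.residue_key: a.residue_name for a in self.atoms}

    def chain_atoms(self, chain: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.residue_key[0] == chain]

    def select_chain(self, chain: str) -> "AssemblyModel":
        if chain not in self.chains:
            raise StructureError(f"chain {chain!r} not present")
        return AssemblyModel(
            atoms=self.chain_atoms(chain),
            chains=[chain],
            sequences={chain: self.sequences.get(chain, "")},
            n_subunits=1,
        )

    def representative_coords(self, chain: str | None = None) -> tuple[list[ResidueKey], np.ndarray]:
        """One coordinate per residue (CA-equivalent: the first atom of the residue)."""
        atoms = self.atoms if chain is None else self.chain_atoms(chain)
        keys: list[ResidueKey] = []
        coords: list[np.ndarray] = []
        seen: set[ResidueKey] = set()
        for a in atoms:
            if a.residue_key not in seen:
                seen.add(a.residue_key)
                keys.append(a.residue_key)
                coords.append(a.coords)
        return keys, np.array(coords, dtype=float)


@dataclass
class ComplexPartition:
    """An assembled complex together with its isolated single-chain subunits."""

    complex: AssemblyModel
    subunits: list[AssemblyModel]

    def __post_init__(self) -> None:
        n_complex = len(self.complex.atoms)
        n_sub = sum(len(s.atoms) for s in self.subunits)
        if n_complex != n_sub:
            raise StructureError(
                f"subunit atoms ({n_sub}) do not partition complex atoms ({n_complex})"
            )


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible areas (Å²)."""

    per_atom: np.ndarray
    per_residue: dict[ResidueKey, float]
    total: float

    def __post_init__(self) -> None:
        if np.any(self.per_atom < 0):
            raise ValueError("negative per-atom SASA")

    @classmethod
    def merge(cls, results: Iterable["SasaResult"]) -> "SasaResult":
        """Concatenate disjoint results (e.g. per-subunit SASAs)."""
        results = list(results)
        per_atom = np.concatenate([r.per_atom for r in results]) if results else np.zeros(0)
        per_residue: dict[ResidueKey, float] = {}
        for r in results:
            overlap = per_residue.keys() & r.per_residue.keys()
            if overlap:
                raise ValueError(f"cannot merge SASA results sharing residues: {sorted(overlap)[:3]}")
            per_residue.update(r.per_residue)
        return cls(per_atom=per_atom, per_residue=per_residue, total=float(per_atom.sum()))


# ---------------------------------------------------------------------------
# Parsing


def _sequence_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


def read_structure(
    path: str | Path,
    format: str | None = None,
    exclude_waters: bool = True,
    include_hetero: bool = False,
    radii: Mapping[str, float] | None = None,
    identity_threshold: float = 0.95,
) -> AssemblyModel:
    """Parse a PDB or mmCIF file into an :class:`AssemblyModel`.

    Coordinates are taken as deposited (first model); the caller is
    responsible for supplying biological-assembly coordinates. Only the
    highest-occupancy alternate conformer is kept; hydrogens, waters
    (when ``exclude_waters``) and hetero records (unless
    ``include_hetero``) are dropped before SASA computation.

    ``n_subunits`` counts the chains whose sequence is >= ``identity_threshold``
    identical to the first chain.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if format is None:
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"

    try:
        if format == "pdb":
            from biotite.structure.io.pdb import PDBFile

            source = PDBFile.read(str(path))
            array = source.get_structure(model=1, altloc="occupancy")
        elif format == "mmcif":
            from biotite.structure.io.pdbx import CIFFile, get_structure

            source = CIFFile.read(str(path))
            array = get_structure(source, model=1, altloc="occupancy")
        else:
            raise StructureError(f"unknown structure format {format!r}")
    except StructureError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise StructureError(f"cannot parse {path} as {format}: {exc}") from exc

    radius_table = dict(DEFAULT_RADII)
    if radii:
        radius_table.update({k.upper(): v for k, v in radii.items()})

    atoms: list[AtomRecord] = []
    chains: list[str] = []
    residues_by_chain: dict[str, list[str]] = {}
    seen_res: set[ResidueKey] = set()
    for i in range(array.array_length()):
        element = str(array.element[i]).upper()
        if element in {"H", "D"}:
            continue
        res_name = str(array.res_name[i]).upper()
        hetero = bool(array.hetero[i])
        if exclude_waters and res_name in WATER_NAMES:
            continue
        if hetero and not include_hetero and res_name not in THREE_TO_ONE:
            continue
        chain_id = str(array.chain_id[i])
        ins_code = str(array.ins_code[i]) if "ins_code" in array.get_annotation_categories() else ""
        key: ResidueKey = (chain_id, int(array.res_id[i]), ins_code.strip())
        radius = radius_table.get(element, DEFAULT_RADIUS_FALLBACK)
        atoms.append(
            AtomRecord(
                element=element,
                coords=np.array(array.coord[i], dtype=float),
                radius=radius,
                residue_key=key,
                residue_name=res_name,
                is_hetero=hetero,
            )
        )
        if chain_id not in residues_by_chain:
            chains.append(chain_id)
            residues_by_chain[chain_id] = []
        if key not in seen_res:
            seen_res.add(key)
            residues_by_chain[chain_id].append(res_name)

    if not atoms:
        raise StructureError(f"{path} contains no protein atoms after filtering")

    sequences = {
        ch: "".join(THREE_TO_ONE.get(rn, "X") for rn in res_names)
        for ch, res_names in residues_by_chain.items()
    }
    ref_seq = sequences[chains[0]]
    n_subunits = sum(
        1 for ch in chains if _sequence_identity(ref_seq, sequences[ch]) >= identity_threshold
    )
    return AssemblyModel(atoms=atoms, chains=chains, sequences=sequences, n_subunits=n_subunits)


def partition_complex(assembly: AssemblyModel) -> ComplexPartition:
    """Split an assembly into single-chain subunit models (coordinates unchanged)."""
    if not assembly.chains:
        raise StructureError("assembly has no chains")
    subunits = [assembly.select_chain(ch) for ch in assembly.chains]
    return ComplexPartition(complex=assembly, subunits=subunits)


# ---------------------------------------------------------------------------
# Shrake-Rupley quadrature


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral point set on the unit sphere."""
    k = np.arange(n)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * math.pi * k / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley(
    atoms: Sequence[AtomRecord],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Shrake–Rupley SASA over a set of atoms.

    Per-atom area is ``(accessible points / n_points) * 4 pi (r + probe)^2``.
    Atoms with exactly coincident centres occlude each other symmetrically
    (both report zero accessible area) with a warning.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a usable quadrature")
    if not probe_radius > 0:
        raise ValueError("probe_radius must be positive")
    atoms = list(atoms)
    n = len(atoms)
    if n == 0:
        return SasaResult(per_atom=np.zeros(0), per_residue={}, total=0.0)

    coords = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array([a.radius for a in atoms], dtype=float)
    inflated = radii + probe_radius
    unit = sphere_points(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * inflated.max()
    pairs = tree.query_pairs(r=max_reach, output_type="ndarray")

    neighbours: list[list[int]] = [[] for _ in range(n)]
    coincident = np.zeros(n, dtype=bool)
    for i, j in pairs:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < 1e-6:
            coincident[i] = coincident[j] = True
            continue
        if d < inflated[i] + inflated[j]:
            neighbours[i].append(j)
            neighbours[j].append(i)
    if coincident.any():
        warnings.warn(
            f"{int(coincident.sum())} atoms have coincident centres; "
            "treating them as mutually occluded",
            stacklevel=2,
        )

    per_atom = np.zeros(n)
    for i in range(n):
        if coincident[i]:
            continue
        points = coords[i] + inflated[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours[i]:
            d2 = np.einsum("ij,ij->i", points - coords[j], points - coords[j])
            accessible &= d2 >= inflated[j] ** 2
            if not accessible.any():
                break
        per_atom[i] = accessible.sum() / n_points * 4.0 * math.pi * inflated[i] ** 2

    per_residue: dict[ResidueKey, float] = {}
    for atom, area in zip(atoms, per_atom):
        per_residue[atom.residue_key] = per_residue.get(atom.residue_key, 0.0) + float(area)
    return SasaResult(per_atom=per_atom, per_residue=per_residue, total=float(per_atom.sum()))


# ---------------------------------------------------------------------------
# Relative accessibility


def miller_reference_areas() -> dict[str, float]:
    """Reference maximal residue areas (Å², tripeptide standard state)."""
    with resources.files("qsevo.data").joinpath("miller_areas.csv").open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    table = {name.upper(): float(area) for name, area in rows[1:]}
    return table


def relative_accessibility(
    per_residue: SasaResult,
    residue_names: Mapping[ResidueKey, str],
    reference_areas: Mapping[str, float] | None = None,
    fallback_area: float | None = None,
) -> dict[ResidueKey, float]:
    """RSA per residue: SASA divided by the reference maximal area.

    Values above 1 (extended termini) are not clipped. Unknown residue names
    use ``fallback_area`` when given, otherwise raise ``KeyError``.
    """
    if reference_areas is None:
        reference_areas = miller_reference_areas()
    rsa: dict[ResidueKey, float] = {}
    for key, area in per_residue.per_residue.items():
        name = residue_names[key].upper()
        ref = reference_areas.get(name)
        if ref is None:
            if fallback_area is None:
                raise KeyError(f"no reference area for residue {name!r} at {key}")
            ref = fallback_area
        rsa[key] = area / ref
    return rsa


def write_rsa_table(
    path: str | Path,
    residue_names: Mapping[ResidueKey, str],
    sasa_complex: SasaResult,
    sasa_subunits: SasaResult,
    rsa_subunit: Mapping[ResidueKey, float],
) -> None:
    """Per-residue SASA/RSA TSV: chain, resnum, icode, resname, areas, RSA."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["chain", "resnum", "icode", "resname", "sasa_complex", "sasa_subunit", "rsa_subunit"]
        )
        for key in sasa_subunits.per_residue:
            chain, resnum, icode = key
            writer.writerow(
                [
                    chain,
                    resnum,
                    icode,
                    residue_names[key],
                    f"{sasa_complex.per_residue.get(key, float('nan')):.3f}",
                    f"{sasa_subunits.per_residue[key]:.3f}",
                    f"{rsa_subunit[key]:.4f}",
                ]
            )
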