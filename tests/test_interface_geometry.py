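import numpy as np
import pytest

from qsevo.interface_geometry import (
    call_regions,
    compute_assembly_sasa,
    hydrophobic_fraction,
    interface_area,
    molecular_weight,
    relative_buried_surface,
)
from qsevo.structure_sasa import (
    AssemblyModel,
    AtomRecord,
    ComplexPartition,
    SasaResult,
    StructureError,
    partition_complex,
    relative_accessibility,
)
from qsevo.synthetic_data import gen_cn_complex


def _fake_partition(per_res_sub, per_res_cx, reference):
    """Build a minimal two-chain partition whose SASA we dictate directly."""
    atoms = []
    for key in per_res_sub:
        atoms.append(AtomRecord("C", np.array([0.0, 0.0, 3.8 * key[1]]), 1.9, key, "ALA"))
    chains = sorted({k[0] for k in per_res_sub})
    complex_model = AssemblyModel(
        atoms=atoms, chains=chains,
        sequences={c: "A" * sum(1 for k in per_res_sub if k[0] == c) for c in chains},
        n_subunits=len(chains),
    )
    partition = ComplexPartition(
        complex=complex_model,
        subunits=[complex_model.select_chain(c) for c in chains],
    )
    sub = SasaResult(np.zeros(len(atoms)), dict(per_res_sub), sum(per_res_sub.values()))
    cx = SasaResult(np.zeros(len(atoms)), dict(per_res_cx), sum(per_res_cx.values()))
    return partition, cx, sub


class TestCallRegions:
    def test_threshold_semantics(self):
        reference = {"ALA": 200.0}
        per_sub = {("A", 1, ""): 100.0, ("A", 2, ""): 100.0, ("A", 3, ""): 10.0,
                   ("B", 1, ""): 100.0, ("B", 2, ""): 100.0, ("B", 3, ""): 10.0}
        per_cx = {("A", 1, ""): 80.0, ("A", 2, ""): 96.0, ("A", 3, ""): 2.0,
                  ("B", 1, ""): 80.0, ("B", 2, ""): 96.0, ("B", 3, ""): 2.0}
        partition, cx, sub = _fake_partition(per_sub, per_cx, reference)
        profile = call_regions(partition, cx, sub, reference_areas=reference)
        # delta 20 > 10% of 100, RSA 0.5 > 0.2 -> interface
        assert profile.region_of[("A", 1, "")] == "interface"
        # delta 4 <= 10% of 100 -> surface (RSA above threshold)
        assert profile.region_of[("A", 2, "")] == "surface"
        # RSA 0.05 <= 0.2 -> core despite large relative delta
        assert profile.region_of[("A", 3, "")] == "core"

    def test_zero_subunit_sasa_is_core(self):
        reference = {"ALA": 200.0}
        per_sub = {("A", 1, ""): 0.0, ("A", 2, ""): 90.0,
                   ("B", 1, ""): 0.0, ("B", 2, ""): 90.0}
        per_cx = {("A", 1, ""): 0.0, ("A", 2, ""): 70.0,
                  ("B", 1, ""): 0.0, ("B", 2, ""): 70.0}
        partition, cx, sub = _fake_partition(per_sub, per_cx, reference)
        profile = call_regions(partition, cx, sub, reference_areas=reference)
        assert profile.region_of[("A", 1, "")] == "core"

    def test_missing_residue_raises(self):
        reference = {"ALA": 200.0}
        per_sub = {("A", 1, ""): 50.0, ("B", 1, ""): 50.0}
        per_cx = {("A", 1, ""): 40.0, ("B", 1, ""): 40.0}
        partition, cx, sub = _fake_partition(per_sub, per_cx, reference)
        cx.per_residue[("A", 9, "")] = 1.0
        with pytest.raises(StructureError):
            call_regions(partition, cx, sub, reference_areas=reference)

    def test_dimer_recovers_buried_truth(self):
        # generator ground truth: buried residues with RSA > 0.2 are called
        hits = total = 0
        for seed in range(10):
            truth = gen_cn_complex(2, 24, seed=seed)
            partition = partition_complex(truth.assembly)
            cx, sub = compute_assembly_sasa(partition)
            profile = call_regions(partition, cx, sub, reference_areas=truth.reference_areas)
            rsa = relative_accessibility(
                sub, truth.assembly.residue_names, truth.reference_areas
            )
            eligible = {k for k in truth.buried_truth if rsa[k] > 0.2}
            called = set(profile.residues_in("interface"))
            hits += len(eligible & called)
            total += len(eligible)
        assert total > 0
        assert hits / total >= 0.9

    def test_invariance_under_rigid_motion(self, dimer_truth):
        from scipy.spatial.transform import Rotation

        partition = partition_complex(dimer_truth.assembly)
        cx, sub = compute_assembly_sasa(partition)
        base = call_regions(partition, cx, sub, reference_areas=dimer_truth.reference_areas)

        R = Rotation.from_euler("zyx", [17, 123, -49], degrees=True).as_matrix()
        shift = np.array([3.0, -8.0, 2.0])
        moved_atoms = [
            AtomRecord(a.element, R @ a.coords + shift, a.radius, a.residue_key, a.residue_name)
            for a in dimer_truth.assembly.atoms
        ]
        moved = AssemblyModel(
            atoms=moved_atoms,
            chains=dimer_truth.assembly.chains,
            sequences=dimer_truth.assembly.sequences,
            n_subunits=2,
        )
        part2 = partition_complex(moved)
        cx2, sub2 = compute_assembly_sasa(part2)
        other = call_regions(part2, cx2, sub2, reference_areas=dimer_truth.reference_areas)
        assert base.region_of == other.region_of


class TestInterfaceArea:
    def test_direct_formula(self):
        assert interface_area(10000.0, 9000.0, 2) == pytest.approx(500.0)

    def test_monomer_zero(self):
        assert interface_area(5000.0, 5000.0, 1) == 0.0

    def test_inconsistent_raises(self):
        with pytest.raises(StructureError):
            interface_area(9000.0, 10000.0, 2)

    def test_matches_per_atom_accounting(self):
        # independent oracle: sum per-atom SASA differences on a C3 trimer
        truth = gen_cn_complex(3, 20, seed=7)
        partition = partition_complex(truth.assembly)
        cx, sub = compute_assembly_sasa(partition)
        per_atom_delta = float(sub.per_atom.sum() - cx.per_atom.sum())
        expected = per_atom_delta / 3
        assert interface_area(sub.total, cx.total, 3) == pytest.approx(expected, rel=1e-9)

    def test_monomer_profile_zero(self):
        truth = gen_cn_complex(1, 20, seed=3)
        partition = partition_complex(truth.assembly)
        cx, sub = compute_assembly_sasa(partition)
        profile = call_regions(partition, cx, sub, reference_areas=truth.reference_areas)
        assert profile.interface_area == 0.0
        assert profile.relative_buried == 0.0
        assert profile.residues_in("interface") == []


class TestRelativeBuried:
    def test_direct_formula(self):
        assert relative_buried_surface(10000.0, 9000.0) == pytest.approx(0.10)

    def test_monomer_zero(self):
        assert relative_buried_surface(5000.0, 5000.0) == 0.0

    def test_pathological_full_burial(self):
        with pytest.warns(UserWarning):
            assert relative_buried_surface(100.0, 0.0) == 1.0

    def test_zero_subunit_raises(self):
        with pytest.raises(ZeroDivisionError):
            relative_buried_surface(0.0, 0.0)


class TestHydrophobicFraction:
    @pytest.mark.parametrize(
        "residues, expected",
        [(["C", "A", "T"], 1 / 3), (["W"] * 5, 1.0), (["A", "G", "S", "T"], 0.0)],
    )
    def test_counts(self, residues, expected):
        assert hydrophobic_fraction(residues) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            hydrophobic_fraction([])


class TestMolecularWeight:
    def test_subunit_multiplication(self):
        seq = "ACDEFGHIKL"
        assert molecular_weight(seq, 2) == pytest.approx(2 * molecular_weight(seq, 1))

    def test_single_glycine(self):
        assert molecular_weight("G") == pytest.approx(57.05, abs=0.01)

    def test_full_exclusion_raises(self):
        with pytest.raises(ValueError):
            molecular_weight("ACD", exclude_ranges=[(1, 3)])

    def test_unknown_letter_raises(self):
        with pytest.raises(KeyError):
            molecular_weight("AZB")

    def test_signal_peptide_exclusion(self):
        assert molecular_weight("GGGAAA", exclude_ranges=[(1, 3)]) == pytest.approx(
            molecular_weight("AAA")
        )
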