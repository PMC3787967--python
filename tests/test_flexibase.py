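"""Ligand model, mol2 / db2-lite round trips, rigid component, hydroxyls, energy window."""

import gzip
import io
import math

import numpy as np
import pytest

from minidock import fixtures as fx
from minidock.errors import UndockableMoleculeError
from minidock.flexibase import (
    Atom,
    Bond,
    ConformerHierarchy,
    EnergyWindow,
    dihedral,
    energy_window_filter,
    find_rigid_component,
    read_db2lite,
    read_mol2,
    reset_hydroxyls,
    write_db2lite,
    write_mol2,
)


def ring_molecule(ring_type="C.ar", ring_order="ar", tail=0, hydroxyl=False):
    """Hexagonal ring with optional tail carbons and one hydroxyl (out-of-plane H)."""
    atoms = [Atom(i, f"C{i + 1}", "C", ring_type) for i in range(6)]
    bonds = [Bond(i, (i + 1) % 6, ring_order) for i in range(6)]
    coords = [[1.4 * math.cos(2 * math.pi * k / 6), 1.4 * math.sin(2 * math.pi * k / 6), 0.0]
              for k in range(6)]
    prev = 0
    for t in range(tail):
        idx = len(atoms)
        atoms.append(Atom(idx, f"C{idx + 1}", "C", "C.3"))
        bonds.append(Bond(prev, idx, "1"))
        coords.append([2.8 + 1.5 * (t + 1), 0.0, 0.3 * (t % 2)])
        prev = idx
    if hydroxyl:
        o = len(atoms)
        atoms.append(Atom(o, "O1", "O", "O.3"))
        bonds.append(Bond(3, o, "1"))
        coords.append([-2.76 * 0.5, -2.38, 0.0])
        atoms.append(Atom(o + 1, "H1", "H", "H"))
        bonds.append(Bond(o, o + 1, "1"))
        coords.append([coords[o][0] + 0.3, coords[o][1] - 0.5, 0.8])
    return ConformerHierarchy("ring", atoms, bonds, [np.array(coords)])


class TestMol2:
    def test_round_trip_preserves_fields(self):
        mol = fx.make_hierarchy(n_atoms=10, n_conformers=2, n_hydroxyls=1, seed=4)
        text = write_mol2(mol)
        back = read_mol2(text)
        assert len(back) == 1
        got = back[0]
        assert got.n_atoms == mol.n_atoms and got.n_conformers == 2
        for a, b in zip(mol.atoms, got.atoms):
            assert (a.name, a.mol2_type) == (b.name, b.mol2_type)
            assert b.partial_charge == pytest.approx(a.partial_charge, abs=1e-4)
        assert [(b.i, b.j, b.order) for b in got.bonds] == \
               [(b.i, b.j, b.order) for b in mol.bonds]
        for c1, c2 in zip(mol.conformers, got.conformers):
            np.testing.assert_allclose(c1, c2, atol=1e-4)

    def test_three_blocks_same_topology_group_to_one_hierarchy(self):
        mol = fx.make_hierarchy(n_atoms=9, n_conformers=3, seed=2)
        back = read_mol2(write_mol2(mol))
        assert len(back) == 1 and back[0].n_conformers == 3

    def test_different_molecules_stay_separate(self):
        a = fx.make_hierarchy(n_atoms=8, seed=1, name="A")
        b = fx.make_hierarchy(n_atoms=9, seed=2, name="B")
        back = read_mol2(write_mol2(a) + write_mol2(b))
        assert [h.name for h in back] == ["A", "B"]
        assert [h.n_conformers for h in back] == [3, 3]

    def test_aromatic_bonds_and_charges_survive(self):
        mol = ring_molecule(hydroxyl=True)
        got = read_mol2(write_mol2(mol))[0]
        assert {b.order for b in got.bonds[:6]} == {"ar"}
        for a, b in zip(mol.atoms, got.atoms):
            assert b.partial_charge == pytest.approx(a.partial_charge, abs=1e-4)

    def test_rdkit_reads_our_output(self):
        """Independent parser cross-check on a plain aromatic ring."""
        from rdkit import Chem

        mol = ring_molecule()
        rd = Chem.MolFromMol2Block(write_mol2(mol), sanitize=False, removeHs=False)
        assert rd is not None and rd.GetNumAtoms() == 6
        conf = rd.GetConformer()
        got = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                         conf.GetAtomPosition(i).z] for i in range(6)])
        np.testing.assert_allclose(got, mol.conformers[0], atol=1e-3)


class TestDb2Lite:
    def test_round_trip_equality(self):
        mol = fx.make_hierarchy(n_atoms=11, n_conformers=3, n_hydroxyls=2, seed=9)
        got = read_db2lite(write_db2lite(mol))[0]
        assert got.name == mol.name
        assert got.rigid_component == mol.rigid_component
        for a, b in zip(mol.atoms, got.atoms):
            assert (a.name, a.element, a.mol2_type, a.vdw_class) == \
                   (b.name, b.element, b.mol2_type, b.vdw_class)
            assert b.partial_charge == pytest.approx(a.partial_charge, abs=1e-6)
            assert b.desolvation_energy == pytest.approx(a.desolvation_energy, abs=1e-6)
        np.testing.assert_allclose(got.conformers, mol.conformers, atol=1e-6)
        np.testing.assert_allclose(got.conformer_energies, mol.conformer_energies,
                                   atol=1e-6)

    def test_hand_written_minimal_record(self):
        text = (
            "db2lite 1\n"
            "name tiny\n"
            "counts 2 1 1\n"
            "atom 0 C1 C C.3 -0.100000 C.3 0.200000\n"
            "atom 1 O1 O O.3 0.100000 O.3 0.300000\n"
            "bond 0 1 1\n"
            "rigid 0 1\n"
            "conf 0 1.500000\n"
            "coord 0.000000 0.000000 0.000000\n"
            "coord 1.400000 0.000000 0.000000\n"
            "end\n"
        )
        mol = read_db2lite(text)[0]
        assert mol.name == "tiny" and mol.n_atoms == 2
        assert mol.atoms[1].element == "O"
        assert mol.conformer_energies == [1.5]
        assert mol.conformers[0][1][0] == pytest.approx(1.4)

    def test_gzip_transparent(self, tmp_path):
        mol = fx.make_hierarchy(seed=3)
        plain = tmp_path / "m.db2"
        zipped = tmp_path / "m.db2.gz"
        write_db2lite(mol, plain)
        write_db2lite(mol, zipped)
        a, b = read_db2lite(plain)[0], read_db2lite(zipped)[0]
        np.testing.assert_allclose(a.conformers, b.conformers)
        assert [x.partial_charge for x in a.atoms] == [x.partial_charge for x in b.atoms]

    def test_inconsistent_rigid_coordinates_rejected(self):
        mol = fx.make_hierarchy(n_atoms=9, n_conformers=2, seed=5)
        text = write_db2lite(mol)
        # corrupt a rigid-component coordinate in the second conformer
        lines = text.splitlines()
        second = [i for i, l in enumerate(lines) if l.startswith("conf 1")][0]
        parts = lines[second + 1].split()
        parts[1] = str(float(parts[1]) + 0.5)
        lines[second + 1] = " ".join(parts)
        with pytest.raises(Exception):
            read_db2lite("\n".join(lines))


class TestRigidComponent:
    def test_benzene_with_tail_is_the_ring(self):
        mol = ring_molecule(tail=3)
        assert find_rigid_component(mol) == [0, 1, 2, 3, 4, 5]

    def test_naphthalene_is_both_rings(self):
        atoms = [Atom(i, f"C{i + 1}", "C", "C.ar") for i in range(10)]
        ring1 = [Bond(i, (i + 1) % 6, "ar") for i in range(5)] + [Bond(5, 0, "ar")]
        ring2 = [Bond(0, 6, "ar"), Bond(6, 7, "ar"), Bond(7, 8, "ar"),
                 Bond(8, 9, "ar"), Bond(9, 1, "ar")]
        coords = np.zeros((10, 3))
        mol = ConformerHierarchy("naph", atoms, ring1 + ring2, [coords],
                                 rigid_component=[])
        assert find_rigid_component(mol) == list(range(10))

    def test_biphenyl_rings_not_merged(self):
        atoms = [Atom(i, f"C{i + 1}", "C", "C.ar") for i in range(12)]
        bonds = [Bond(i, (i + 1) % 6, "ar") for i in range(6)]
        bonds += [Bond(6 + i, 6 + (i + 1) % 6, "ar") for i in range(6)]
        bonds.append(Bond(0, 6, "1"))  # rotatable inter-ring bond
        mol = ConformerHierarchy("biph", atoms, bonds, [np.zeros((12, 3))],
                                 rigid_component=[])
        assert find_rigid_component(mol) == [0, 1, 2, 3, 4, 5]  # tie -> lowest indices

    def test_n_butane_flagged_undockable(self):
        atoms = [Atom(i, f"C{i + 1}", "C", "C.3") for i in range(4)]
        bonds = [Bond(0, 1, "1"), Bond(1, 2, "1"), Bond(2, 3, "1")]
        mol = ConformerHierarchy("butane", atoms, bonds, [np.zeros((4, 3))],
                                 rigid_component=[])
        with pytest.raises(UndockableMoleculeError):
            find_rigid_component(mol)

    def test_amide_chain_is_rigid_fallback(self):
        # CH3-C(=O)-NH-CH3 backbone: amide + terminal bonds are non-rotatable
        atoms = [Atom(0, "C1", "C", "C.3"), Atom(1, "C2", "C", "C.2"),
                 Atom(2, "O1", "O", "O.2"), Atom(3, "N1", "N", "N.am"),
                 Atom(4, "C3", "C", "C.3")]
        bonds = [Bond(0, 1, "1"), Bond(1, 2, "2"), Bond(1, 3, "am"), Bond(3, 4, "1")]
        mol = ConformerHierarchy("acet", atoms, bonds, [np.zeros((5, 3))],
                                 rigid_component=[])
        assert len(find_rigid_component(mol)) >= 3


class TestHydroxyls:
    def test_phenol_reset_to_in_plane_pair(self):
        mol = ring_molecule(hydroxyl=True)
        o, h = 6, 7
        start = dihedral(mol.conformers[0][2], mol.conformers[0][3],
                         mol.conformers[0][o], mol.conformers[0][h])
        assert abs(start) > 0.3 and abs(abs(start) - math.pi) > 0.3  # out of plane
        rot = reset_hydroxyls(mol, mol.conformers[0])
        assert len(rot) == 2
        ds = sorted(abs(dihedral(r[2], r[3], r[o], r[h])) for r in rot)
        assert ds[0] == pytest.approx(0.0, abs=1e-6)
        assert ds[1] == pytest.approx(math.pi, abs=1e-6)

    def test_reset_is_idempotent_on_first_rotamer(self):
        mol = ring_molecule(hydroxyl=True)
        first = reset_hydroxyls(mol, mol.conformers[0])[0]
        again = reset_hydroxyls(mol, first)[0]
        np.testing.assert_allclose(first, again, atol=1e-9)

    def test_sp3_hydroxyl_three_equiangular_rotamers(self):
        mol = ring_molecule(ring_type="C.3", ring_order="1", hydroxyl=True)
        o, h = 6, 7
        rot = reset_hydroxyls(mol, mol.conformers[0])
        assert len(rot) == 3
        ds = sorted(dihedral(r[2], r[3], r[o], r[h]) for r in rot)
        gaps = [ds[1] - ds[0], ds[2] - ds[1], 2 * math.pi - (ds[2] - ds[0])]
        for g in gaps:
            assert g == pytest.approx(2 * math.pi / 3, abs=1e-6)

    def test_oxygen_without_hydrogen_skipped(self):
        mol = ring_molecule(hydroxyl=True)
        atoms = mol.atoms[:-1]  # drop the proton
        bonds = mol.bonds[:-1]
        bare = ConformerHierarchy("noH", atoms, bonds, [mol.conformers[0][:-1]],
                                  rigid_component=mol.rigid_component)
        rot = reset_hydroxyls(bare, bare.conformers[0])
        assert len(rot) == 1
        np.testing.assert_allclose(rot[0], bare.conformers[0])

    def test_rotamer_explosion_capped(self):
        mol = fx.make_hierarchy(n_atoms=9, n_conformers=1, n_hydroxyls=5, seed=8)
        rot = reset_hydroxyls(mol, mol.conformers[0], max_combinations=8)
        assert 1 <= len(rot) <= 8


class TestEnergyWindow:
    @pytest.mark.parametrize("width,expected", [
        (12.5, [0.0, 10.0]),
        (15.0, [0.0, 10.0, 14.0]),
        (30.0, [0.0, 10.0, 14.0]),
        (0.0, [0.0]),
        (math.inf, [0.0, 10.0, 14.0, 31.0]),
    ])
    def test_window_values(self, width, expected):
        mol = fx.make_hierarchy(n_atoms=8, n_conformers=4, seed=6)
        mol.conformer_energies = [0.0, 10.0, 14.0, 31.0]
        kept = energy_window_filter(mol, EnergyWindow(width))
        assert kept.conformer_energies == expected
        assert kept.n_conformers == len(expected)

    def test_wider_window_is_superset(self):
        mol = fx.make_hierarchy(n_atoms=8, n_conformers=4, seed=6)
        mol.conformer_energies = [3.0, 0.5, 9.0, 0.0]
        kept = [energy_window_filter(mol, EnergyWindow(w)).conformer_energies
                for w in (0.0, 1.0, 4.0, 10.0)]
        for small, big in zip(kept[:-1], kept[1:]):
            assert set(small) <= set(big)
        assert 0.0 in kept[0]  # minimum always kept
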