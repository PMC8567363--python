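"""Structure I/O and geometric kernels: distances, omega dihedrals, PDB round trips."""

import numpy as np
import pytest
import biotite.structure as struc

from vcss import (Conformer, interatomic_distance, omega_dihedral,
                  read_multimodel_pdb, write_multimodel_pdb, parse_selection)
from vcss.conformers import _dihedral
from vcss.exceptions import GeometryError, PDBParseError, RosterError, SelectionError

from conftest import rigid_transform


def _pdb_line(serial, name, res_name, res_id, xyz):
    # atom name occupies columns 13-16; names shorter than 4 chars start at 14
    field = name if len(name) == 4 else f" {name:<3s}"
    return (f"ATOM  {serial:5d} {field}{res_name:>4s} A{res_id:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00")


def _make_pdb(tmp_path, models, fname="toy.pdb"):
    """models: list of lists of (name, res_name, res_id, xyz_angstrom)."""
    lines = []
    multi = len(models) > 1
    for m, atoms in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for i, (name, rn, rid, xyz) in enumerate(atoms, start=1):
            lines.append(_pdb_line(i, name, rn, rid, xyz))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / fname
    path.write_text("\n".join(lines) + "\n")
    return str(path)


ATOMS_A = [("CA", "ALA", 1, (1.0, 0.0, 0.0)), ("CA", "GLY", 2, (4.0, 0.0, 0.0))]


class TestPDBReading:
    def test_three_models_default_times(self, tmp_path):
        path = _make_pdb(tmp_path, [ATOMS_A] * 3)
        traj = read_multimodel_pdb(path)
        assert len(traj) == 3
        assert traj.times.tolist() == [0.0, 10.0, 20.0]

    def test_angstrom_to_nm_conversion(self, tmp_path):
        path = _make_pdb(tmp_path, [ATOMS_A])
        traj = read_multimodel_pdb(path)
        assert len(traj) == 1
        assert traj[0].position(1, "CA")[0] == pytest.approx(0.1)

    def test_inconsistent_roster_raises(self, tmp_path):
        path = _make_pdb(tmp_path, [ATOMS_A, ATOMS_A[:1]])
        with pytest.raises(RosterError):
            read_multimodel_pdb(path)

    def test_garbled_atom_record_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(_pdb_line(1, "CA", "ALA", 1, (1, 2, 3)) + "\n"
                        + "ATOM      2  CA  ALA A   2      xx.xxx   0.000   0.000\n")
        with pytest.raises(PDBParseError, match="line 2"):
            read_multimodel_pdb(str(path))

    def test_hydrogen_name_normalization(self, tmp_path):
        atoms = [("1HH1", "ARG", 1, (0.0, 0.0, 0.0))]
        traj = read_multimodel_pdb(_make_pdb(tmp_path, [atoms]))
        assert traj[0].atom_index(1, "HH11") == 0

    def test_round_trip_preserves_coordinates(self, tmp_path, small_trans_traj):
        traj = small_trans_traj[0]
        sub = type(traj)(traj.conformers[:3])
        out = tmp_path / "rt.pdb"
        write_multimodel_pdb(sub, str(out))
        back = read_multimodel_pdb(str(out))
        for a, b in zip(sub, back):
            # PDB stores 3 decimals in Angstrom = 1e-4 nm
            np.testing.assert_allclose(a.coords, b.coords, atol=1.1e-4)


def _conformer(coords, names=None, res_ids=None):
    n = len(coords)
    return Conformer(0, 0.0,
                     np.array(names or [f"X{i}" for i in range(n)]),
                     np.array(res_ids or list(range(1, n + 1))),
                     np.array(["ALA"] * n), np.array(coords, float))


class TestDistance:
    def test_three_four_five_triangle(self):
        c = _conformer([(0, 0, 0), (0.3, 0, 0.4)], names=["A", "B"], res_ids=[1, 2])
        assert interatomic_distance(c, (1, "A"), (2, "B")) == pytest.approx(0.5)

    def test_identity_is_zero(self):
        c = _conformer([(0.7, -0.2, 1.0)], names=["A"], res_ids=[1])
        assert interatomic_distance(c, (1, "A"), (1, "A")) == 0.0

    def test_matches_brute_force_norm_and_symmetry(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = rng.normal(size=(2, 3))
            c = _conformer(p, names=["A", "B"], res_ids=[1, 2])
            expected = float(np.sqrt(((p[0] - p[1]) ** 2).sum()))
            d_ab = interatomic_distance(c, (1, "A"), (2, "B"))
            assert d_ab == pytest.approx(expected, abs=1e-12)
            assert d_ab == interatomic_distance(c, (2, "B"), (1, "A"))

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.normal(size=(2, 3))
        c = _conformer(p, names=["A", "B"], res_ids=[1, 2])
        d0 = interatomic_distance(c, (1, "A"), (2, "B"))
        rot, t = rigid_transform(p, seed=6)
        c2 = c.transformed(rot, t)
        assert interatomic_distance(c2, (1, "A"), (2, "B")) == pytest.approx(d0, abs=1e-12)

    def test_unresolved_selection_lists_candidates(self):
        c = _conformer([(0, 0, 0)], names=["CA"], res_ids=[1])
        with pytest.raises(SelectionError, match="CA"):
            interatomic_distance(c, (1, "CB"), (1, "CA"))


def _omega_conformer(ca_prev, c_prev, n, ca):
    return Conformer(0, 0.0,
                     np.array(["CA", "C", "N", "CA"]),
                     np.array([1, 1, 2, 2]),
                     np.array(["ALA"] * 4),
                     np.array([ca_prev, c_prev, n, ca], float))


class TestOmegaDihedral:
    def test_planar_cis_is_zero(self):
        c = _omega_conformer((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
        assert omega_dihedral(c, 2) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        c = _omega_conformer((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))
        assert omega_dihedral(c, 2) == pytest.approx(180.0, abs=1e-9)

    def test_rotation_invariance(self):
        pts = np.array([(0.1, 1, 0), (0, 0, 0), (1, 0, 0.2), (1, 1, -0.3)])
        c = _omega_conformer(*pts)
        before = omega_dihedral(c, 2)
        rot, t = rigid_transform(pts, seed=7)
        after = omega_dihedral(c.transformed(rot, t), 2)
        assert after == pytest.approx(before, abs=1e-9)

    def test_mirror_reflection_flips_sign(self):
        pts = np.array([(0.1, 1, 0), (0, 0, 0), (1, 0, 0.2), (1, 1, -0.3)])
        c = _omega_conformer(*pts)
        mirrored = _omega_conformer(*(pts * np.array([1, 1, -1])))
        assert omega_dihedral(mirrored, 2) == pytest.approx(-omega_dihedral(c, 2),
                                                            abs=1e-9)

    def test_agrees_with_reference_library(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            p = rng.normal(size=(4, 3))
            expected = float(np.degrees(struc.dihedral(*p.astype(np.float32))))
            assert _dihedral(*p) == pytest.approx(expected, abs=1e-3)

    def test_missing_backbone_atom_raises(self):
        c = _conformer([(0, 0, 0)], names=["CA"], res_ids=[2])
        with pytest.raises(GeometryError, match="1:CA"):
            omega_dihedral(c, 2)

    def test_requires_preceding_residue(self):
        c = _conformer([(0, 0, 0)], names=["CA"], res_ids=[1])
        with pytest.raises(GeometryError):
            omega_dihedral(c, 1)


def test_parse_selection():
    assert parse_selection("2:OH") == (2, "OH")
    with pytest.raises(SelectionError):
        parse_selection("nonsense")
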