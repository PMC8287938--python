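"""Structure I/O, SASA, buried interface area, contacts, symmetry
expansion, and anti-parallel stack building."""

import math

import numpy as np
import pytest

import biotite.structure as struc

from oligosaxs.geometry import (
    C2221_OPS,
    Structure,
    StructureError,
    build_antiparallel_stack,
    buried_interface_area,
    expand_symmetry,
    helix_axis,
    interface_residues,
    read_structure,
    sasa,
    structure_from_coords,
    write_structure,
)
from oligosaxs.synth import ideal_helix_coords

MINIMAL_PDB = """\
CRYST1   27.190   83.710  160.060  90.00  90.00  90.00 C 2 2 21
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.759   7.092  -4.973  1.00  0.00           C
END
"""


@pytest.fixture()
def minimal_structure(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return read_structure(p)


def helix_pair(separation=9.0, n_res=20, antiparallel=True):
    """Two poly-alanine Cα helices with parallel or anti-parallel axes."""
    a = ideal_helix_coords(n_res)
    b = ideal_helix_coords(n_res)
    if antiparallel:
        b = b @ np.diag([1.0, -1.0, -1.0])  # flip axis
        b = b - b.mean(axis=0) + a.mean(axis=0)
    b = b + np.array([separation, 0.0, 0.0])
    sa = structure_from_coords(a, chain_id="A")
    sb = structure_from_coords(b, chain_id="B")
    atoms = sa.atoms + sb.atoms
    return Structure(atoms=atoms)


class TestReadWrite:
    def test_minimal_fixture_atoms_and_coords(self, minimal_structure):
        st = minimal_structure
        assert len(st) == 3
        assert st.atoms.coord[1] == pytest.approx(
            [11.639, 6.071, -5.147]
        )

    def test_unit_cell_parsed(self, minimal_structure):
        assert minimal_structure.unit_cell[:3] == pytest.approx(
            (27.19, 83.71, 160.06)
        )
        assert minimal_structure.space_group == "C 2 2 21"

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(StructureError):
            read_structure(p)

    def test_roundtrip_preserves_coordinates(self, tmp_path):
        st = helix_pair()
        path = write_structure(st, tmp_path / "pair.pdb")
        back = read_structure(path)
        np.testing.assert_allclose(
            back.atoms.coord, st.atoms.coord, atol=1e-3
        )


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        st = structure_from_coords(np.zeros((1, 3)), element="C")
        area = sasa(st, probe=1.4, n_points=960)
        expected = 4.0 * math.pi * (1.70 + 1.4) ** 2
        assert area.sum() == pytest.approx(expected, rel=0.01)

    def test_far_atoms_keep_full_area(self):
        st = structure_from_coords(
            np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]), element="C"
        )
        areas = sasa(st)
        expected = 4.0 * math.pi * (1.70 + 1.4) ** 2
        np.testing.assert_allclose(areas, expected, rtol=0.01)

    def test_overlapping_atoms_bury_area_and_converge(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        st = structure_from_coords(coords, element="C")
        lo = sasa(st, n_points=960).sum()
        hi = sasa(st, n_points=3840).sum()
        isolated = 2 * 4.0 * math.pi * (1.70 + 1.4) ** 2
        assert lo < isolated
        assert abs(lo - hi) / hi < 0.01
        # analytic accessible area of two overlapping spheres of equal
        # radius R at distance d: each cap of height h = R - d/2 is buried
        R, d = 1.70 + 1.4, 2.0
        cap = 2.0 * math.pi * R * (R - d / 2.0)
        expected = isolated - 2.0 * cap
        assert hi == pytest.approx(expected, rel=0.01)

    def test_unknown_element_reported(self):
        st = structure_from_coords(np.zeros((1, 3)), element="XX")
        with pytest.raises(StructureError, match="XX"):
            sasa(st)

    def test_agrees_with_independent_implementation(self):
        # cross-check against biotite's Shrake-Rupley on a helix pair,
        # forcing the same single-radius table via per-atom radii
        st = helix_pair(separation=6.0)
        mine = sasa(st, probe=1.4, n_points=1000).sum()
        theirs = struc.sasa(
            st.atoms,
            probe_radius=1.4,
            point_number=1000,
            vdw_radii=np.full(len(st), 1.70),
        ).sum()
        assert mine == pytest.approx(theirs, rel=0.02)


class TestBuriedInterfaceArea:
    def test_far_apart_groups_have_zero_bsa(self):
        st = helix_pair(separation=60.0)
        rep = buried_interface_area(st, "A", "B")
        assert rep.bsa_total == pytest.approx(0.0, abs=1e-6)
        assert rep.residues_a == [] and rep.residues_b == []

    def test_internal_consistency_with_sasa_op(self):
        st = helix_pair(separation=9.0)
        rep = buried_interface_area(st, "A", "B")
        mask_a = st.select("A")
        total = (
            sasa(st.atoms[mask_a]).sum()
            + sasa(st.atoms[~mask_a]).sum()
            - sasa(st.atoms).sum()
        )
        assert rep.bsa_total == pytest.approx(total, rel=1e-6)
        assert rep.bsa_half == pytest.approx(rep.bsa_total / 2.0)

    def test_symmetric_in_groups_and_rigid_motion_invariant(self):
        st = helix_pair(separation=9.0)
        ab = buried_interface_area(st, "A", "B")
        ba = buried_interface_area(st, "B", "A")
        assert ab.bsa_total == pytest.approx(ba.bsa_total, rel=1e-9)
        # rotate + translate the whole complex rigidly
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True)
        atoms = st.atoms.copy()
        atoms.coord = rot.apply(atoms.coord) + np.array([5.0, -3.0, 11.0])
        # rotation invariance holds to the finite angular sampling of
        # the Shrake-Rupley point set
        moved = buried_interface_area(Structure(atoms=atoms), "A", "B")
        assert moved.bsa_total == pytest.approx(ab.bsa_total, rel=0.01)

    def test_overlapping_selections_rejected(self):
        st = helix_pair()
        with pytest.raises(StructureError):
            buried_interface_area(st, "A", ["A", "B"])


class TestContacts:
    def test_constructed_salt_bridge_detected(self):
        atoms = struc.AtomArray(2)
        atoms.coord = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        atoms.chain_id = np.array(["A", "B"])
        atoms.res_id = np.array([1, 2])
        atoms.res_name = np.array(["LYS", "GLU"])
        atoms.atom_name = np.array(["NZ", "OE1"])
        atoms.element = np.array(["N", "O"])
        st = Structure(atoms=atoms)
        rep = interface_residues(st, "A", "B")
        assert len(rep.contacts) == 1
        assert rep.contacts[0].kind == "saltbridge"
        assert rep.contacts[0].distance == pytest.approx(3.0)

    def test_far_groups_no_contacts(self):
        st = helix_pair(separation=60.0)
        rep = interface_residues(st, "A", "B")
        assert rep.contacts == []

    def test_close_carbon_pairs_classified_hydrophobic(self):
        st = helix_pair(separation=4.0)
        rep = interface_residues(st, "A", "B")
        assert rep.contacts
        assert all(c.kind == "hydrophobic" for c in rep.contacts)


class TestExpandSymmetry:
    def test_identity_only_preserves_structure(self, minimal_structure):
        out = expand_symmetry(
            minimal_structure, [(np.eye(3), np.zeros(3))]
        )
        assert len(out) == len(minimal_structure)
        np.testing.assert_allclose(
            out.atoms.coord, minimal_structure.atoms.coord
        )

    def test_a_axis_lattice_translation(self, minimal_structure):
        out = expand_symmetry(
            minimal_structure,
            [(np.eye(3), np.zeros(3))],
            translations=(2, 1, 1),
        )
        n = len(minimal_structure)
        assert len(out) == 2 * n
        shift = out.atoms.coord[n:] - out.atoms.coord[:n]
        np.testing.assert_allclose(  # coordinates are float32
            shift, np.tile([27.19, 0.0, 0.0], (n, 1)), atol=1e-4
        )

    def test_two_fold_screw_squares_to_unit_translation(self):
        # (R|t) with R = 180° about a, t = a/2: applying twice must give
        # a pure translation by one a-repeat
        coords = ideal_helix_coords(10) + np.array([3.0, 4.0, 5.0])
        st = structure_from_coords(coords, unit_cell=(27.19, 83.71, 160.06, 90, 90, 90))
        screw = (np.diag([1.0, -1.0, -1.0]), np.array([0.5, 0.0, 0.0]))
        once = expand_symmetry(st, [screw])
        n = len(st)
        twice_coords = once.atoms.coord[n:]
        st2 = Structure(
            atoms=st.atoms.copy(), unit_cell=st.unit_cell
        )
        st2.atoms.coord = twice_coords
        again = expand_symmetry(st2, [screw])
        final = again.atoms.coord[n:]
        np.testing.assert_allclose(  # float32 coordinates
            final - st.atoms.coord,
            np.tile([27.19, 0.0, 0.0], (n, 1)),
            atol=1e-4,
        )

    def test_intra_copy_distances_preserved(self, minimal_structure):
        out = expand_symmetry(
            minimal_structure, C2221_OPS, translations=(1, 1, 1)
        )
        n = len(minimal_structure)
        d0 = np.linalg.norm(
            minimal_structure.atoms.coord[0]
            - minimal_structure.atoms.coord[2]
        )
        n_copies = len(out) // n
        for k in range(n_copies):
            dk = np.linalg.norm(
                out.atoms.coord[k * n] - out.atoms.coord[k * n + 2]
            )
            assert dk == pytest.approx(d0, rel=1e-5)  # float32 coords

    def test_missing_cell_with_translations_rejected(self):
        st = structure_from_coords(ideal_helix_coords(8))
        with pytest.raises(StructureError, match="unit cell"):
            expand_symmetry(
                st, [(np.eye(3), np.zeros(3))], translations=(2, 1, 1)
            )


class TestAntiparallelStack:
    def test_single_unit_unchanged(self):
        st = helix_pair()
        out = build_antiparallel_stack(st, 1)
        np.testing.assert_allclose(out.atoms.coord, st.atoms.coord)

    def test_alternating_orientations_and_spacing(self):
        st = helix_pair(separation=9.0)
        n = len(st)
        # helices run along z; the screw axis is perpendicular (x),
        # so each 180-degree turn flips the helix polarity
        out = build_antiparallel_stack(
            st, 4, screw=((1.0, 0.0, 0.0), 180.0, 30.0)
        )
        assert len(out) == 4 * n
        axes = [
            helix_axis(out.atoms.coord[k * n : k * n + n // 2])
            for k in range(4)
        ]
        for a, b in zip(axes, axes[1:]):
            assert float(np.dot(a, b)) < 0  # anti-parallel neighbours
        # equivalent-atom spacing along the screw axis equals the
        # screw translation
        dx = out.atoms.coord[n, 0] - out.atoms.coord[0, 0]
        assert dx == pytest.approx(30.0)

    def test_rg_grows_monotonically_with_units(self):
        from oligosaxs.guinier import auto_guinier
        from oligosaxs.synth import debye_curve_from_coords, default_s_grid

        st = helix_pair(separation=9.0)
        s = default_s_grid(150)[:100]
        rgs = []
        for n_units in (1, 2, 3):
            model = build_antiparallel_stack(
                st, n_units, screw=((0.0, 0.0, 1.0), 180.0, 32.0)
            )
            curve = debye_curve_from_coords(model.atoms.coord, s_grid=s)
            rgs.append(auto_guinier(curve).rg)
        assert rgs[0] < rgs[1] < rgs[2]

    def test_clash_warning(self):
        st = helix_pair(separation=9.0)
        # zero screw superposes the units exactly -> every atom clashes
        with pytest.warns(UserWarning, match="closer"):
            build_antiparallel_stack(
                st, 2, screw=((1.0, 0.0, 0.0), 0.0, 0.0)
            )
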