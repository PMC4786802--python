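"""Structure I/O, selections, superposition and surface areas."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from clampscreen.errors import (
    FitError,
    PDBParseError,
    ParameterError,
    SelectionError,
    TopologyError,
)
from clampscreen.structio import (
    Selection,
    Structure,
    Trajectory,
    interface_area,
    kabsch_superpose,
    read_multimodel_pdb,
    sasa,
    select,
    write_multimodel_pdb,
)

from conftest import make_atom, random_rotation


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

class TestReadMultimodelPdb:
    def test_three_model_file_gives_three_frames(self, toy_peptide, tmp_path):
        traj = Trajectory(toy_peptide, [toy_peptide.coords() + i for i in range(3)])
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == 3
        assert len(back.topology) == 5

    def test_single_model_file_gives_one_frame(self, toy_peptide, tmp_path):
        path = tmp_path / "single.pdb"
        write_multimodel_pdb(toy_peptide, path)
        assert read_multimodel_pdb(path).n_frames == 1

    def test_model_with_missing_atom_raises_naming_the_model(self, toy_peptide, tmp_path):
        traj = Trajectory(toy_peptide, [toy_peptide.coords()] * 2)
        path = tmp_path / "bad.pdb"
        write_multimodel_pdb(traj, path)
        lines = path.read_text().splitlines()
        # drop one atom from the second model
        second_atoms = [i for i, l in enumerate(lines) if l.startswith("ATOM")][5:]
        del lines[second_atoms[0]]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TopologyError, match="model 2"):
            read_multimodel_pdb(path)

    def test_unparseable_atom_line_reports_line_number(self, tmp_path):
        path = tmp_path / "garbled.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   1       xxx     0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(PDBParseError, match="line 2"):
            read_multimodel_pdb(path)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C\n"
        )
        traj = read_multimodel_pdb(path)
        assert len(traj.topology) == 1
        assert traj.topology.atoms[0].coords[0] == pytest.approx(5.0)

    def test_round_trip_preserves_records_to_pdb_precision(self, tmp_path):
        rng = np.random.default_rng(11)
        atoms = [
            make_atom(i + 1, name, el, resid, chain, rng.uniform(-40, 40, 3))
            for i, (name, el, resid, chain) in enumerate(
                [("N", "N", 771, "C"), ("CA", "C", 771, "C"), ("CB", "C", 772, "C"),
                 ("O", "O", 10, "A"), ("SD", "S", 11, "A")]
            )
        ]
        traj = Trajectory(Structure(atoms, "rt"), [np.array([a.coords for a in atoms])] * 2)
        path = tmp_path / "rt.pdb"
        write_multimodel_pdb(traj, path)
        back = read_multimodel_pdb(path)
        assert back.n_frames == 2
        for a, b in zip(traj.topology.atoms, back.topology.atoms):
            assert (a.name, a.element, a.resname, a.resid, a.chain) == \
                   (b.name, b.element, b.resname, b.resid, b.chain)
            np.testing.assert_allclose(a.coords, b.coords, atol=5e-4)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

class TestSelect:
    def test_clamp_selection_keeps_only_heavy_atoms_of_range(self):
        atoms = [
            make_atom(1, "CA", "C", 770, "C"),
            make_atom(2, "CA", "C", 771, "C"),
            make_atom(3, "H", "H", 771, "C"),
            make_atom(4, "CA", "C", 803, "C"),
            make_atom(5, "CA", "C", 804, "C"),
            make_atom(6, "CA", "C", 780, "A"),
        ]
        s = Structure(atoms)
        idx = select(s, "chain C and resid 771-803 and heavy")
        assert idx == [1, 3]

    def test_heavy_on_all_carbon_structure_selects_everything(self, toy_peptide):
        carbons = Structure([make_atom(i, "C", "C", 1) for i in range(3)])
        assert select(carbons, "heavy") == [0, 1, 2]

    @pytest.mark.parametrize("expr", ["resid 1-0", "resid x", "bogus", "chain"])
    def test_malformed_expressions_raise(self, toy_peptide, expr):
        with pytest.raises(SelectionError):
            select(toy_peptide, expr)

    def test_atom_class_keywords(self, toy_peptide):
        assert select(toy_peptide, "polar") == [0, 3]        # N and O
        assert select(toy_peptide, "hydrophobic") == [1, 2, 4]
        assert select(toy_peptide, "mainchain") == [0, 1, 2, 3]


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

class TestKabsch:
    def test_rigid_copy_fits_to_zero(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3))
        R = random_rotation(rng)
        mobile = ref @ R.T + np.array([3.0, -2.0, 7.0])
        _, _, value = kabsch_superpose(mobile, ref)
        assert value < 1e-8

    def test_identity_on_self(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(8, 3))
        R, t, value = kabsch_superpose(ref, ref)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_rmsd_invariant_under_joint_rigid_transform(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 3))
        b = a + rng.normal(0, 0.5, size=(10, 3))
        _, _, r0 = kabsch_superpose(a, b)
        R = random_rotation(rng)
        t = np.array([1.0, 2.0, 3.0])
        _, _, r1 = kabsch_superpose(a @ R.T + t, b @ R.T + t)
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_matches_svd_free_rotation_search(self):
        """Ten atoms, one coordinate perturbed: the optimal RMSD must agree
        with a direct numerical minimisation over Euler angles (no SVD)."""
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(10, 3)) * 3.0
        mobile = ref.copy()
        mobile[4, 1] += 0.8  # known perturbation
        _, _, kabsch_value = kabsch_superpose(mobile, ref)

        Pc = mobile - mobile.mean(axis=0)
        Qc = ref - ref.mean(axis=0)

        def cost(angles):
            R = Rotation.from_euler("zyx", angles).as_matrix()
            return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

        best = min(
            minimize(cost, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000}).fun
            for x0 in ([0, 0, 0], [1, 1, 1], [-1, 2, 0.5], [2, -2, 1])
        )
        assert kabsch_value == pytest.approx(best, abs=1e-5)

    def test_too_few_or_collinear_atoms_raise(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(FitError):
            kabsch_superpose(line[:2], line[:2])
        with pytest.raises(FitError):
            kabsch_superpose(line, line)


# ---------------------------------------------------------------------------
# surface areas
# ---------------------------------------------------------------------------

def _sphere_structure(specs):
    return Structure([
        make_atom(i + 1, "X", el, i + 1, coords=c) for i, (el, c) in enumerate(specs)
    ])


class TestSasa:
    def test_isolated_carbon_matches_closed_form(self):
        s = _sphere_structure([("C", (0, 0, 0))])
        area = sasa(s).sum()
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=1e-6)  # quadrature weights sum exactly

    def test_separated_atoms_are_additive(self):
        s = _sphere_structure([("C", (0, 0, 0)), ("O", (50, 0, 0))])
        parts = sasa(s)
        assert parts[0] == pytest.approx(4 * math.pi * (1.70 + 1.4) ** 2, rel=1e-6)
        assert parts[1] == pytest.approx(4 * math.pi * (1.52 + 1.4) ** 2, rel=1e-6)

    def test_two_overlapping_spheres_match_analytic_caps(self):
        d = 2.5
        s = _sphere_structure([("C", (0, 0, 0)), ("O", (d, 0, 0))])
        R1, R2 = 1.70 + 1.4, 1.52 + 1.4
        x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
        x2 = (d * d + R2 * R2 - R1 * R1) / (2 * d)
        exact = 2 * math.pi * R1 * (R1 + x1) + 2 * math.pi * R2 * (R2 + x2)
        area = sasa(s, n_points=5000).sum()
        assert area == pytest.approx(exact, rel=0.01)

    def test_per_atom_area_never_exceeds_isolated_sphere(self):
        rng = np.random.default_rng(8)
        s = _sphere_structure([("C", c) for c in rng.uniform(0, 6, size=(10, 3))])
        parts = sasa(s)
        assert np.all(parts <= 4 * math.pi * (1.70 + 1.4) ** 2 + 1e-9)

    def test_burial_monotonic_in_environment(self):
        lone = _sphere_structure([("C", (0, 0, 0))])
        crowded = _sphere_structure([("C", (0, 0, 0)), ("C", (2.0, 0, 0)), ("C", (0, 2.0, 0))])
        assert sasa(crowded)[0] < sasa(lone)[0]

    def test_agrees_with_independent_implementation(self):
        """Cross-check against biotite's Shrake-Rupley on a random cluster."""
        biotite_structure = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(21)
        coords = rng.uniform(0, 8, size=(15, 3))
        elements = ["C", "N", "O"] * 5
        s = _sphere_structure(list(zip(elements, coords)))
        mine = sasa(s, n_points=2000).sum()
        arr = biotite_structure.AtomArray(15)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(elements)
        arr.atom_name = np.array(elements)
        arr.res_id = np.arange(1, 16)
        arr.res_name = np.array(["ALA"] * 15)
        arr.chain_id = np.array(["A"] * 15)
        theirs = float(np.nansum(biotite_structure.sasa(arr, vdw_radii="Single",
                                                        point_number=2000)))
        assert mine == pytest.approx(theirs, rel=0.02)

    def test_bad_parameters_raise(self, toy_peptide):
        with pytest.raises(ParameterError):
            sasa(toy_peptide, probe=-1.0)
        with pytest.raises(ParameterError):
            sasa(toy_peptide, n_points=0)


class TestInterfaceArea:
    def test_distant_partners_bury_nothing(self):
        s = _sphere_structure([("C", (0, 0, 0)), ("C", (100, 0, 0))])
        s.atoms[1].chain = "B"
        assert interface_area(s, "chain A", "chain B") == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_the_two_selections(self):
        rng = np.random.default_rng(5)
        specs = [("C", c) for c in rng.uniform(0, 5, size=(6, 3))]
        s = _sphere_structure(specs)
        for a in s.atoms[3:]:
            a.chain = "B"
        ab = interface_area(s, "chain A", "chain B")
        ba = interface_area(s, "chain B", "chain A")
        assert ab == pytest.approx(ba, rel=1e-12)
        assert ab > 0

    def test_matches_high_density_quadrature(self):
        """Toy two-residue interface: the default quadrature must agree with a
        much denser, independently refined one."""
        rng = np.random.default_rng(6)
        left = [("C", c) for c in rng.normal(0, 1.2, size=(5, 3))]
        right = [("N", c + np.array([4.0, 0, 0])) for _, c in
                 [("", x) for x in rng.normal(0, 1.2, size=(5, 3))]]
        s = _sphere_structure(left + right)
        for a in s.atoms[5:]:
            a.chain = "B"
        coarse = interface_area(s, "chain A", "chain B", n_points=960)
        fine = interface_area(s, "chain A", "chain B", n_points=10000)
        assert coarse == pytest.approx(fine, rel=0.03)

    def test_overlapping_selections_raise(self, toy_peptide):
        with pytest.raises(SelectionError):
            interface_area(toy_peptide, "heavy", "hydrophobic")
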