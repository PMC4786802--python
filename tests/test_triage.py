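"""PDBQT pose parsing, position clustering, contact typing and the hit rule."""

import itertools

import numpy as np
import pytest

from clampscreen.errors import PDBParseError, SelectionError
from clampscreen.structio import Structure
from clampscreen.synthdata import (
    CampaignSpec,
    CompoundPlant,
    make_pose_campaign,
    make_receptor_site,
)
from clampscreen.triage import (
    Pose,
    PoseSet,
    TriageCriteria,
    cluster_poses,
    pose_contacts,
    read_vina_poses,
    select_hits,
    triage_verdict,
    write_vina_poses,
)

from conftest import make_atom


def simple_pose(coords, score, cid="c1", conf="r0", elements=None):
    coords = np.asarray(coords, dtype=float)
    return Pose(cid, conf, coords, score, elements or ["C"] * len(coords))


class TestReadVinaPoses:
    def test_two_model_file(self, tmp_path):
        path = tmp_path / "c1.pdbqt"
        path.write_text(
            "MODEL 1\n"
            "REMARK VINA RESULT:     -7.3      0.000      0.000\n"
            "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00    +0.000 C \n"
            "ENDMDL\n"
            "MODEL 2\n"
            "REMARK VINA RESULT:     -6.1      1.200      2.100\n"
            "ATOM      1  C1  LIG A   1       3.000   0.000   0.000  1.00  0.00    +0.000 C \n"
            "ENDMDL\n"
        )
        poses = read_vina_poses(path)
        assert [p.score for p in poses] == [-7.3, -6.1]
        assert min(p.score for p in poses) == -7.3

    def test_missing_remark_names_the_model(self, tmp_path):
        path = tmp_path / "bad.pdbqt"
        path.write_text(
            "MODEL 1\n"
            "REMARK VINA RESULT:     -7.3      0.000      0.000\n"
            "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00    +0.000 C \n"
            "ENDMDL\n"
            "MODEL 2\n"
            "ATOM      1  C1  LIG A   1       3.000   0.000   0.000  1.00  0.00    +0.000 C \n"
            "ENDMDL\n"
        )
        with pytest.raises(PDBParseError, match="model 2"):
            read_vina_poses(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdbqt"
        path.write_text("")
        with pytest.raises(PDBParseError):
            read_vina_poses(path)

    def test_hydrogens_dropped_by_autodock_type(self, tmp_path):
        path = tmp_path / "h.pdbqt"
        path.write_text(
            "MODEL 1\n"
            "REMARK VINA RESULT:     -5.0      0.000      0.000\n"
            "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00    +0.000 C \n"
            "ATOM      2  H1  LIG A   1       1.000   0.000   0.000  1.00  0.00    +0.000 HD\n"
            "ATOM      3  O1  LIG A   1       2.000   0.000   0.000  1.00  0.00    +0.000 OA\n"
            "ENDMDL\n"
        )
        (pose,) = read_vina_poses(path)
        assert len(pose.coords) == 2
        assert pose.elements == ["C", "O"]

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        poses = [simple_pose(np.round(rng.uniform(-20, 20, (4, 3)), 3), round(s, 3))
                 for s in (-8.123, -7.001, -6.5)]
        path = tmp_path / "rt.pdbqt"
        write_vina_poses(poses, path)
        back = read_vina_poses(path, "c1", "r0")
        assert [p.score for p in back] == [p.score for p in poses]
        for a, b in zip(poses, back):
            np.testing.assert_allclose(a.coords, b.coords, atol=5e-4)


class TestClusterPoses:
    def test_ten_near_identical_poses_form_one_cluster(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 5, (6, 3))
        group = [simple_pose(base + rng.normal(0, 0.1, base.shape), -7.0 - 0.01 * i)
                 for i in range(10)]
        assert cluster_poses(group, 2.0).max() == 0

    def test_far_apart_poses_split(self):
        a = simple_pose(np.zeros((3, 3)), -8.0)
        b = simple_pose(np.zeros((3, 3)) + 10.0, -7.0)
        assert cluster_poses([a, b], 2.0).max() == 1

    def test_planted_three_clusters_recovered(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0, 5, (5, 3))
        group, labels = [], []
        for c in range(3):
            for i in range(4):
                group.append(simple_pose(base + 8.0 * c + rng.normal(0, 0.1, base.shape),
                                         -9.0 + c + 0.1 * i))
                labels.append(c)
        assign = cluster_poses(group, 2.0)
        assert assign.max() == 2
        mapping = {}
        for got, planted in zip(assign, labels):
            assert mapping.setdefault(planted, got) == got

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(5)
        group = [simple_pose(rng.uniform(0, 12, (4, 3)), -7.0 + 0.1 * i) for i in range(12)]
        counts = [cluster_poses(group, r).max() + 1 for r in (0.5, 1.0, 2.0, 5.0, 20.0)]
        assert counts == sorted(counts, reverse=True)

    def test_best_scored_pose_seeds_first(self):
        far = simple_pose(np.zeros((2, 3)) + 20.0, -9.0)  # best score, isolated
        near = [simple_pose(np.zeros((2, 3)), -7.0 - 0.1 * i) for i in range(3)]
        assign = cluster_poses([*near, far], 2.0)
        assert assign[-1] == 0  # the best pose founded cluster 0


class TestPoseContacts:
    def test_lone_hydroxyl_counts_one_polar(self):
        receptor = Structure([
            make_atom(1, "O", "O", 1, "R", (0.0, 0.0, 0.0), resname="SIT"),
        ])
        pose = simple_pose([(0.0, 0.0, 3.2)], -7.0, elements=["O"])
        n_polar, n_hydro, residues = pose_contacts(pose, receptor, "chain R")
        assert (n_polar, n_hydro) == (1, 0)
        assert residues == [("R", 1, "SIT")]

    def test_ligand_outside_site_counts_nothing(self):
        receptor = make_receptor_site()
        pose = simple_pose(np.zeros((3, 3)) + 100.0, -7.0, elements=["C", "O", "C"])
        n_polar, n_hydro, residues = pose_contacts(pose, receptor, "chain R")
        assert (n_polar, n_hydro, residues) == (0, 0, [])

    def test_counts_match_hand_enumeration(self):
        """Toy pose against a 5-residue pocket vs an explicit all-pairs count."""
        receptor = make_receptor_site(5)
        rng = np.random.default_rng(6)
        coords = rng.uniform(-15, 15, (8, 3))
        elements = ["O", "N", "C", "C", "O", "C", "N", "C"]
        pose = simple_pose(coords, -7.5, elements=elements)
        criteria = TriageCriteria()
        n_polar, n_hydro, _ = pose_contacts(pose, receptor, "chain R", criteria)
        exp_polar = exp_hydro = 0
        for i, el in enumerate(elements):
            for resid in range(1, 6):
                ratoms = [a for a in receptor.atoms if a.resid == resid]
                if el in ("N", "O") and any(
                    a.element in ("N", "O")
                    and np.linalg.norm(coords[i] - a.coords) <= criteria.polar_cutoff
                    for a in ratoms
                ):
                    exp_polar += 1
                if el == "C" and any(
                    a.element == "C"
                    and np.linalg.norm(coords[i] - a.coords) <= criteria.hydrophobic_cutoff
                    for a in ratoms
                ):
                    exp_hydro += 1
        assert (n_polar, n_hydro) == (exp_polar, exp_hydro)

    def test_empty_site_raises(self):
        receptor = make_receptor_site()
        pose = simple_pose(np.zeros((1, 3)), -7.0)
        with pytest.raises(SelectionError):
            pose_contacts(pose, receptor, "chain Z")


class TestVerdict:
    @pytest.mark.parametrize(
        "score,n_clusters,contacts_present",
        list(itertools.product([-7.0, -6.9], [1, 2], [True, False])),
    )
    def test_all_boundary_combinations(self, score, n_clusters, contacts_present):
        """The full 2x2x2 truth table; -7.0 itself must pass the score leg."""
        n_polar = n_hydro = 1 if contacts_present else 0
        verdict, reasons = triage_verdict(score, n_clusters, n_polar, n_hydro)
        expected = score <= -7.0 and n_clusters == 1 and contacts_present
        assert verdict is expected
        if not expected:
            assert reasons

    def test_more_negative_score_never_flips_pass_to_fail(self):
        for score in (-7.0, -7.5, -9.0, -12.0):
            verdict, _ = triage_verdict(score, 1, 1, 1)
            assert verdict

    def test_multiple_clusters_reason_named(self):
        verdict, reasons = triage_verdict(-8.5, 2, 1, 1)
        assert not verdict
        assert "multiple clusters" in reasons


class TestSelectHits:
    def test_planted_campaign_recovers_verdicts(self):
        plants = tuple(
            CompoundPlant(
                f"m{i:02d}",
                best_score=-8.0 + 0.4 * i,
                n_pose_clusters=1 + (i % 3 == 0),
                n_polar=int(i % 4 != 0),
                n_hydrophobic=1,
            )
            for i in range(12)
        )
        poseset, receptors, truth, _ = make_pose_campaign(CampaignSpec(plants, seed=8))
        records = select_hits(poseset, receptors, "chain R and heavy")
        got = {r.compound_id: r.verdict for r in records}
        expected = dict(zip(truth["compound_id"], truth["verdict"]))
        assert got == expected

    def test_boundary_score_with_good_pose_passes(self):
        plants = (CompoundPlant("edge", best_score=-7.0, n_pose_clusters=1,
                                n_polar=1, n_hydrophobic=1),)
        poseset, receptors, truth, _ = make_pose_campaign(CampaignSpec(plants, seed=1))
        (rec,) = select_hits(poseset, receptors, "chain R and heavy")
        assert rec.verdict and rec.best_score == -7.0

    def test_representative_is_lowest_energy_pose(self):
        plants = (CompoundPlant("a", best_score=-8.2, n_poses=6),)
        poseset, receptors, _, _ = make_pose_campaign(CampaignSpec(plants, seed=2))
        (rec,) = select_hits(poseset, receptors, "chain R and heavy")
        all_scores = [p.score for g in poseset.groups.values() for p in g]
        assert rec.best_score == min(all_scores)

    def test_output_sorted_by_best_score(self):
        plants = tuple(CompoundPlant(f"m{i}", best_score=-6.0 - 0.5 * i) for i in range(5))
        poseset, receptors, _, _ = make_pose_campaign(CampaignSpec(plants, seed=3))
        records = select_hits(poseset, receptors, "chain R and heavy")
        scores = [r.best_score for r in records]
        assert scores == sorted(scores)
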