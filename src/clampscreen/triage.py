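"""Docking-pose triage across a receptor-conformer ensemble.

Consumes Vina-dialect PDBQT pose files (one MODEL block per pose, each with a
``REMARK VINA RESULT:`` affinity line), clusters the poses of a compound by
in-place ligand RMSD, types pose-receptor contacts inside the binding site,
and applies the hit rule: a compound is kept iff its best pose scores at least
as well as the cutoff (default -7 kcal/mol, inclusive — Vina affinities are
negative, so "at least -7 kcal/mol of binding" means score <= -7.0), its pose
group forms a single position cluster, and the best pose makes at least one
polar and one hydrophobic contact within the site.

The polar (3.5 Å) and hydrophobic (4.0 Å) typing cutoffs are interaction
cutoffs for docked poses and are deliberately distinct from the 3 Å
trajectory-contact cutoff used for persistence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterError, PDBParseError, SelectionError
from .structio import Selection, Structure, select

__all__ = [
    "Pose",
    "PoseSet",
    "TriageCriteria",
    "HitRecord",
    "read_vina_poses",
    "write_vina_poses",
    "cluster_poses",
    "pose_contacts",
    "select_hits",
]


@dataclass
class Pose:
    """One docked pose: ligand heavy-atom coordinates plus the Vina affinity."""

    compound_id: str
    conformer_id: str
    coords: np.ndarray            # heavy atoms only, Å
    score: float                  # kcal/mol, more negative = better
    elements: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.coords) == 0:
            raise ParameterError("pose has no heavy atoms")
        if not np.isfinite(self.score):
            raise ParameterError("pose score must be finite")


@dataclass
class PoseSet:
    """Poses grouped per (compound, receptor conformer), best score first."""

    groups: dict[tuple[str, str], list[Pose]] = field(default_factory=dict)

    def add(self, poses: list[Pose]) -> None:
        for p in poses:
            self.groups.setdefault((p.compound_id, p.conformer_id), []).append(p)
        for key in self.groups:
            self.groups[key].sort(key=lambda p: p.score)

    def compounds(self) -> list[str]:
        return sorted({c for c, _ in self.groups})

    def groups_for(self, compound_id: str) -> dict[str, list[Pose]]:
        return {conf: poses for (c, conf), poses in self.groups.items() if c == compound_id}


@dataclass(frozen=True)
class TriageCriteria:
    """The hit-selection rule and its geometric parameters."""

    score_max: float = -7.0            # pass iff best score <= score_max (inclusive)
    require_single_cluster: bool = True
    min_polar_contacts: int = 1
    min_hydrophobic_contacts: int = 1
    pose_cluster_radius: float = 2.0   # Å
    polar_cutoff: float = 3.5          # Å, ligand N/O vs receptor N/O
    hydrophobic_cutoff: float = 4.0    # Å, ligand C vs receptor C
    pooled_clusters: bool = False      # pool poses over all receptor conformers

    def __post_init__(self):
        if self.pose_cluster_radius <= 0 or self.polar_cutoff <= 0 or self.hydrophobic_cutoff <= 0:
            raise ParameterError("cutoffs must be positive")


@dataclass
class HitRecord:
    compound_id: str
    best_score: float
    best_conformer: str
    n_pose_clusters: int
    n_polar: int
    n_hydrophobic: int
    verdict: bool
    reasons: list[str] = field(default_factory=list)
    contacted_residues: list[tuple] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "best_score": self.best_score,
            "best_conformer": self.best_conformer,
            "n_clusters": self.n_pose_clusters,
            "n_polar": self.n_polar,
            "n_hydrophobic": self.n_hydrophobic,
            "verdict": "pass" if self.verdict else "fail",
            "reasons": ";".join(self.reasons),
        }


# ---------------------------------------------------------------------------
# PDBQT I/O (Vina dialect)
# ---------------------------------------------------------------------------

def _pdbqt_is_hydrogen(atom_type: str, name: str) -> bool:
    t = atom_type.strip().upper()
    if t:
        return t in ("H", "HD", "HS")
    return name.strip().upper().startswith("H")


def read_vina_poses(
    path: str | Path, compound_id: str | None = None, conformer_id: str = ""
) -> list[Pose]:
    """Parse a multi-MODEL Vina PDBQT file into heavy-atom poses.

    Every MODEL must carry a ``REMARK VINA RESULT:`` line whose first number
    is the affinity (kcal/mol).  AutoDock atom types (last column) distinguish
    hydrogens; aromatic-carbon type ``A`` is mapped back to element C.
    """
    path = Path(path)
    if compound_id is None:
        compound_id = path.stem
    poses: list[Pose] = []
    model_no = 0
    score: float | None = None
    coords: list[list[float]] = []
    elements: list[str] = []
    in_model = False
    saw_model_record = False

    def close_model():
        nonlocal score, coords, elements
        if score is None:
            raise PDBParseError(f"model {model_no} of {path.name} lacks a REMARK VINA RESULT line")
        if not coords:
            raise PDBParseError(f"model {model_no} of {path.name} has no heavy atoms")
        poses.append(Pose(compound_id, conformer_id, np.array(coords), score, list(elements)))
        score, coords, elements = None, [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model_record = True
                in_model = True
                model_no += 1
            elif rec == "ENDMDL":
                in_model = False
                close_model()
            elif line.startswith("REMARK VINA RESULT:"):
                if not saw_model_record:
                    saw_model_record = True
                    in_model = True
                    model_no += 1
                try:
                    score = float(line.split(":", 1)[1].split()[0])
                except (IndexError, ValueError):
                    raise PDBParseError("malformed REMARK VINA RESULT", lineno) from None
            elif rec in ("ATOM", "HETATM"):
                try:
                    name = line[12:16].strip()
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except (ValueError, IndexError) as exc:
                    raise PDBParseError(f"unparseable PDBQT atom record ({exc})", lineno) from None
                atom_type = line[77:79].strip() if len(line) > 77 else ""
                if _pdbqt_is_hydrogen(atom_type, name):
                    continue
                element = {"A": "C", "OA": "O", "NA": "N", "SA": "S"}.get(atom_type.upper(), None)
                if element is None:
                    element = atom_type[:1].upper() if atom_type else name[:1].upper()
                coords.append([x, y, z])
                elements.append(element)
    if in_model or (score is not None or coords):
        # file ended inside an (implicit) model
        close_model()
    if not poses:
        raise PDBParseError(f"no pose models in {path}")
    return poses


def write_vina_poses(poses: list[Pose], path: str | Path) -> None:
    """Write poses as a Vina-dialect multi-MODEL PDBQT file."""
    lines: list[str] = []
    for mi, pose in enumerate(poses, start=1):
        lines.append(f"MODEL {mi}")
        lines.append(f"REMARK VINA RESULT:   {pose.score:8.3f}      0.000      0.000")
        for ai, xyz in enumerate(pose.coords, start=1):
            el = pose.elements[ai - 1] if pose.elements else "C"
            name = f"{el}{ai}"
            lines.append(
                f"ATOM  {ai:5d} {name:<4.4s} LIG A   1    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00    "
                f"+0.000 {el:<2.2s}"
            )
        lines.append("ENDMDL")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pose clustering
# ---------------------------------------------------------------------------

def _inplace_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def cluster_poses(group: list[Pose], radius: float = 2.0) -> np.ndarray:
    """Leader clustering of poses by in-place ligand RMSD (no re-fitting).

    The receptor frames are assumed already superposed, so absolute ligand
    position matters.  The best-scored pose seeds the first cluster; remaining
    poses, in score order, join the first cluster whose seed lies within
    ``radius``, else found a new one.  Returns a cluster id per pose (in the
    input order of ``group``).
    """
    if radius <= 0:
        raise ParameterError("pose cluster radius must be positive")
    order = sorted(range(len(group)), key=lambda i: group[i].score)
    seeds: list[int] = []
    assign = np.empty(len(group), dtype=int)
    for i in order:
        placed = False
        for cid, s in enumerate(seeds):
            if group[i].coords.shape == group[s].coords.shape and \
               _inplace_rmsd(group[i].coords, group[s].coords) <= radius:
                assign[i] = cid
                placed = True
                break
        if not placed:
            assign[i] = len(seeds)
            seeds.append(i)
    return assign


# ---------------------------------------------------------------------------
# contact typing
# ---------------------------------------------------------------------------

def pose_contacts(
    pose: Pose,
    receptor: Structure,
    site_sel: Selection | str,
    criteria: TriageCriteria | None = None,
) -> tuple[int, int, list[tuple]]:
    """Polar / hydrophobic contact counts of a pose within the binding site.

    A polar contact is a (ligand N/O atom, site residue) pair with some
    receptor N/O atom of that residue within ``polar_cutoff``; a hydrophobic
    contact is a (ligand C atom, site residue) pair within
    ``hydrophobic_cutoff`` of a receptor carbon.  Counting is per
    (ligand atom, residue) pair.  Returns the contacted residue keys as well.
    """
    criteria = criteria or TriageCriteria()
    site_idx = [i for i in select(receptor, site_sel) if not receptor.atoms[i].is_hydrogen]
    if not site_idx:
        raise SelectionError("empty site selection")
    lig_el = pose.elements or ["C"] * len(pose.coords)

    def count(lig_elements: tuple[str, ...], rec_elements: tuple[str, ...], cutoff: float) -> tuple[int, set]:
        li = [i for i, e in enumerate(lig_el) if e in lig_elements]
        ri = [i for i in site_idx if receptor.atoms[i].element in rec_elements]
        if not li or not ri:
            return 0, set()
        rc = np.array([receptor.atoms[i].coords for i in ri])
        tree = cKDTree(rc)
        n = 0
        residues = set()
        for i in li:
            hit_res = {receptor.atoms[ri[j]].residue_key()
                       for j in tree.query_ball_point(pose.coords[i], cutoff)}
            n += len(hit_res)
            residues |= hit_res
        return n, residues

    n_polar, res_p = count(("N", "O"), ("N", "O"), criteria.polar_cutoff)
    n_hydro, res_h = count(("C",), ("C",), criteria.hydrophobic_cutoff)
    return n_polar, n_hydro, sorted(res_p | res_h)


# ---------------------------------------------------------------------------
# hit selection
# ---------------------------------------------------------------------------

def triage_verdict(
    best_score: float, n_clusters: int, n_polar: int, n_hydrophobic: int,
    criteria: TriageCriteria | None = None,
) -> tuple[bool, list[str]]:
    """The pure hit rule on (score, clusters, contacts); reasons name failures."""
    criteria = criteria or TriageCriteria()
    reasons = []
    if not best_score <= criteria.score_max:
        reasons.append(f"score {best_score:g} above cutoff {criteria.score_max:g}")
    if criteria.require_single_cluster and n_clusters != 1:
        reasons.append("multiple clusters")
    if n_polar < criteria.min_polar_contacts:
        reasons.append("no polar contact")
    if n_hydrophobic < criteria.min_hydrophobic_contacts:
        reasons.append("no hydrophobic contact")
    return not reasons, reasons


def select_hits(
    poseset: PoseSet,
    receptors: dict[str, Structure],
    site_sel: Selection | str,
    criteria: TriageCriteria | None = None,
) -> list[HitRecord]:
    """Apply the hit rule to every compound across the receptor ensemble.

    The best score is taken over all receptor conformers; the cluster rule is
    evaluated on the best-scoring conformer's pose group (or on the pooled
    poses when ``criteria.pooled_clusters``); contact typing uses the best
    pose against that conformer's receptor.  The representative pose is always
    the lowest-energy one.  Output sorted by best score ascending.
    """
    criteria = criteria or TriageCriteria()
    records: list[HitRecord] = []
    for compound in poseset.compounds():
        groups = poseset.groups_for(compound)
        if not groups:
            continue
        best_conf = min(groups, key=lambda c: groups[c][0].score)
        best_pose = groups[best_conf][0]
        if criteria.pooled_clusters:
            pooled = [p for poses in groups.values() for p in poses]
            n_clusters = int(cluster_poses(pooled, criteria.pose_cluster_radius).max()) + 1
        else:
            n_clusters = int(cluster_poses(groups[best_conf], criteria.pose_cluster_radius).max()) + 1
        receptor = receptors[best_conf] if best_conf in receptors else next(iter(receptors.values()))
        n_polar, n_hydro, contacted = pose_contacts(best_pose, receptor, site_sel, criteria)
        verdict, reasons = triage_verdict(best_pose.score, n_clusters, n_polar, n_hydro, criteria)
        records.append(HitRecord(
            compound, best_pose.score, best_conf, n_clusters,
            n_polar, n_hydro, verdict, reasons, contacted,
        ))
    records.sort(key=lambda r: (r.best_score, r.compound_id))
    return records


def hits_to_frame(records: list[HitRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in records])
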