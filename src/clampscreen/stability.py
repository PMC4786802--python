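"""Post-docking MD analytics per candidate: drift, stability score, ranking.

For each candidate complex trajectory this module measures the ligand's RMSD
inside the binding site (receptor-superposed, no ligand re-fit, so drift in
the pocket is what is measured), assigns the qualitative 3/2/1 stability
score, finds 90%-persistent ligand-residue contacts, and ranks the retained
candidates by externally supplied binding energies (end-point MM-GBSA values
computed over the last few ns by an MD package; never recomputed here).

Stability score mapping (the qualitative scale made deterministic):

* 3 — very stable: mean ligand RMSD <= ``t_stable`` and one position cluster;
* 2 — fluctuating, unique binding mode: one cluster, mean above ``t_stable``;
* 1 — different binding modes: more than one position cluster.

``t_stable`` (1.5 Å) and the snapshot-cluster radius (2.0 Å) are this
package's own defaults — the scale itself is qualitative — and are exposed in
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, WindowError
from .contacts import ContactParams, ContactTable, persistence
from .ensemble import RmsdTrace
from .structio import Selection, Trajectory, kabsch_superpose, select
from .triage import Pose, cluster_poses

__all__ = [
    "StabilityThresholds",
    "StabilityReport",
    "EnergyTable",
    "ligand_rmsd_trace",
    "snapshot_position_clusters",
    "rmsd_score",
    "ligand_persistence",
    "surrogate_energy",
    "rank_candidates",
]


@dataclass(frozen=True)
class StabilityThresholds:
    t_stable: float = 1.5              # Å, mean ligand RMSD for "very stable"
    snapshot_cluster_radius: float = 2.0   # Å, position clustering of snapshots
    persistent_threshold: float = 0.90
    min_rmsd_score: int = 2            # retention gate
    require_persistent_contact: bool = True

    def __post_init__(self):
        if self.t_stable <= 0 or self.snapshot_cluster_radius <= 0:
            raise ParameterError("thresholds must be positive")
        if self.min_rmsd_score not in (1, 2, 3):
            raise ParameterError("min_rmsd_score must be 1, 2 or 3")


@dataclass
class StabilityReport:
    compound_id: str
    rmsd_trace: RmsdTrace
    rmsd_score: int
    n_position_clusters: int
    persistent_contacts: ContactTable
    binding_energy: float | None = None
    energy_method: str = ""
    energy_window: tuple[float, float] | None = None   # ps

    @property
    def n_persistent(self) -> int:
        return len(self.persistent_contacts.entries)


@dataclass
class EnergyTable:
    """compound id -> binding energy (kcal/mol), with the method label."""

    energies: dict[str, float] = field(default_factory=dict)
    method: str = "MM-GBSA"

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EnergyTable":
        df = pd.read_csv(path, sep="\t")
        required = {"compound_id", "energy_kcal_mol"}
        if not required <= set(df.columns):
            raise InputError(f"energy table needs columns {sorted(required)}")
        if not np.all(np.isfinite(df["energy_kcal_mol"])):
            raise InputError("energy table contains non-finite energies")
        method = str(df["method"].iloc[0]) if "method" in df.columns and len(df) else "MM-GBSA"
        return cls(dict(zip(df["compound_id"].astype(str), df["energy_kcal_mol"])), method)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "compound_id": list(self.energies),
            "energy_kcal_mol": list(self.energies.values()),
            "method": self.method,
        }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ligand drift
# ---------------------------------------------------------------------------

def ligand_rmsd_trace(
    traj: Trajectory,
    ligand_sel: Selection | str,
    receptor_fit_sel: Selection | str,
    ref: int = 0,
) -> RmsdTrace:
    """Ligand heavy-atom RMSD after superposing each frame on the receptor.

    The fit uses ``receptor_fit_sel`` only; the ligand is *not* re-fitted, so
    translation of the ligand within the (fixed) site is measured.
    """
    topo = traj.topology
    lig_idx = [i for i in select(topo, ligand_sel) if not topo.atoms[i].is_hydrogen]
    fit_idx = [i for i in select(topo, receptor_fit_sel) if not topo.atoms[i].is_hydrogen]
    if not lig_idx or not fit_idx:
        raise InputError("ligand and receptor selections must both be non-empty")
    if set(lig_idx) & set(fit_idx):
        raise InputError("ligand and receptor selections overlap")
    ref_frame = traj.frames[ref]
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        R, t, _ = kabsch_superpose(frame, ref_frame, fit_idx)
        moved = frame[lig_idx] @ R.T + t
        values[i] = np.sqrt(np.mean(np.sum((moved - ref_frame[lig_idx]) ** 2, axis=1)))
    expr = receptor_fit_sel.expression if isinstance(receptor_fit_sel, Selection) else str(receptor_fit_sel)
    return RmsdTrace(traj.times(), values, ref, expr)


def snapshot_position_clusters(
    traj: Trajectory,
    ligand_sel: Selection | str,
    receptor_fit_sel: Selection | str,
    radius: float = 2.0,
    ref: int = 0,
) -> int:
    """Number of ligand position clusters over the trajectory's snapshots.

    Each frame's ligand (receptor-superposed onto the reference) is treated as
    one pose and leader-clustered at ``radius``; distinct clusters indicate
    distinct binding modes.
    """
    topo = traj.topology
    lig_idx = [i for i in select(topo, ligand_sel) if not topo.atoms[i].is_hydrogen]
    fit_idx = [i for i in select(topo, receptor_fit_sel) if not topo.atoms[i].is_hydrogen]
    ref_frame = traj.frames[ref]
    poses = []
    for fi, frame in enumerate(traj.frames):
        R, t, _ = kabsch_superpose(frame, ref_frame, fit_idx)
        poses.append(Pose("snap", str(fi), frame[lig_idx] @ R.T + t, float(fi)))
    return int(cluster_poses(poses, radius).max()) + 1


def rmsd_score(
    trace: RmsdTrace, n_clusters: int, thresholds: StabilityThresholds | None = None
) -> int:
    """Map (mean drift, binding-mode count) onto the qualitative 3/2/1 scale."""
    thresholds = thresholds or StabilityThresholds()
    if n_clusters < 1:
        raise ParameterError("n_clusters must be >= 1")
    if n_clusters > 1:
        return 1
    return 3 if trace.mean() <= thresholds.t_stable else 2


# ---------------------------------------------------------------------------
# ligand contact persistence
# ---------------------------------------------------------------------------

def ligand_persistence(
    traj: Trajectory,
    ligand_sel: Selection | str,
    site_sel: Selection | str,
    threshold: float = 0.90,
    cutoff: float = 3.0,
    window: tuple[int, int] | None = None,
) -> ContactTable:
    """Ligand-residue contacts persistent in >= ``threshold`` of the frames.

    Delegates to :func:`clampscreen.contacts.persistence` with the ligand as
    one residue group, then keeps only the pairs at or above the threshold.
    """
    params = ContactParams(
        cutoff=cutoff, persistent_threshold=threshold, very_persistent_threshold=threshold
    )
    table = persistence(traj, ligand_sel, site_sel, params, window)
    persistent = [e for e in table.entries if e.fraction >= threshold]
    return ContactTable(table.window, persistent, params)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def energy_window_frames(traj: Trajectory, last_ps: float = 4000.0) -> tuple[int, int]:
    """Frame window covering the trajectory's last ``last_ps`` picoseconds."""
    times = traj.times()
    t_cut = times[-1] - last_ps
    if t_cut < times[0] - 1e-9:
        raise WindowError(f"window of {last_ps} ps longer than trajectory")
    first = int(np.searchsorted(times, t_cut, side="left"))
    return first, traj.n_frames - 1


def surrogate_energy(n_polar: int, n_hydrophobic: int) -> float:
    """Contact-count surrogate score, kcal/mol (labelled SURROGATE in outputs).

    -1.0 per polar and -0.5 per hydrophobic site contact.  A crude stand-in
    used only to exercise the ranking stage end-to-end when no end-point
    energies are supplied; never comparable to physical binding energies.
    """
    return -1.0 * n_polar - 0.5 * n_hydrophobic


def rank_candidates(
    reports: list[StabilityReport],
    energies: EnergyTable | None = None,
    thresholds: StabilityThresholds | None = None,
    allow_surrogate: bool = False,
) -> pd.DataFrame:
    """Retain stable candidates and rank them by binding energy (ascending).

    The retention gate: at least one persistent contact (if required) and
    stability score >= ``min_rmsd_score``.  Missing energies raise unless the
    surrogate scorer is explicitly enabled.
    """
    thresholds = thresholds or StabilityThresholds()
    rows = []
    for rep in reports:
        retained = rep.rmsd_score >= thresholds.min_rmsd_score
        if thresholds.require_persistent_contact:
            retained = retained and rep.n_persistent >= 1
        if not retained:
            continue
        if energies is not None and rep.compound_id in energies.energies:
            energy = energies.energies[rep.compound_id]
            method = energies.method
        elif rep.binding_energy is not None:
            energy = rep.binding_energy
            method = rep.energy_method or "supplied"
        elif allow_surrogate:
            energy = surrogate_energy(rep.n_persistent, 0)
            method = "SURROGATE"
        else:
            raise InputError(f"no binding energy for compound {rep.compound_id!r}")
        rows.append({
            "compound_id": rep.compound_id,
            "binding_energy_kcal_mol": energy,
            "energy_method": method,
            "rmsd_score": rep.rmsd_score,
            "n_position_clusters": rep.n_position_clusters,
            "persistent_contacts": ";".join(
                f"{e.residue_b[2]}{e.residue_b[1]}" for e in rep.persistent_contacts.entries
            ),
        })
    df = pd.DataFrame(rows, columns=[
        "compound_id", "binding_energy_kcal_mol", "energy_method", "rmsd_score",
        "n_position_clusters", "persistent_contacts",
    ])
    return df.sort_values(
        ["binding_energy_kcal_mol", "compound_id"], kind="mergesort"
    ).reset_index(drop=True)
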