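"""Receptor-ensemble extraction: RMSD traces, window cuts, conformer clustering, grid boxes.

This is the relaxed-complex-scheme step: an MD run of the free receptor is
reduced to a small set of representative main-chain conformers (leader
clustering at a fixed RMSD radius, 2 Å by default) that are then docked
independently.  The grid box mirrors the docking setup: a cubic box (40 Å,
1 Å spacing) centred on the receptor's centre of gravity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError, WindowError
from .structio import (
    Selection,
    Structure,
    Trajectory,
    kabsch_superpose,
    select,
    write_multimodel_pdb,
)

__all__ = [
    "RmsdTrace",
    "ConformerSet",
    "GridBox",
    "rmsd_trace",
    "analysis_window",
    "equilibration_onset",
    "cluster_conformers",
    "pairwise_fitted_rmsd",
    "grid_box",
    "ATOMIC_MASSES",
]

# standard atomic masses (u) for the centre-of-gravity calculation
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
}


@dataclass
class RmsdTrace:
    """Per-frame RMSD (Å) against a reference frame, after superposition."""

    times: np.ndarray          # ps
    values: np.ndarray         # Å
    reference_frame: int
    fit_selection: str

    def mean(self) -> float:
        return float(np.mean(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "rmsd_A": self.values})


@dataclass
class ConformerSet:
    """Leader-clustering result: frame assignments plus one representative each.

    Cluster ids are 0..k-1 in order of decreasing size (ties: founding order).
    """

    cluster_radius: float
    assignments: np.ndarray               # frame index -> cluster id
    representatives: list[int]            # cluster id -> frame index (medoid)
    cluster_sizes: list[int]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, cluster_id: int) -> list[int]:
        return [int(i) for i in np.nonzero(self.assignments == cluster_id)[0]]

    def write_assignments_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "frame": np.arange(len(self.assignments)),
            "cluster": self.assignments,
        }).to_csv(path, sep="\t", index=False)

    def export_representatives(self, traj: Trajectory, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for cid, fi in enumerate(self.representatives):
            p = out_dir / f"conformer_{cid:02d}.pdb"
            write_multimodel_pdb(traj.frame_structure(fi), p)
            paths.append(p)
        return paths


@dataclass(frozen=True)
class GridBox:
    """Cubic docking grid: centre (Å), edge length (Å) and grid spacing (Å)."""

    center: tuple[float, float, float]
    edge: float = 40.0
    spacing: float = 1.0

    def __post_init__(self):
        if self.edge <= 0 or self.spacing <= 0 or self.spacing > self.edge:
            raise ParameterError("need 0 < spacing <= edge")

    def to_vina_config(self) -> str:
        cx, cy, cz = self.center
        return (
            f"center_x = {cx:.3f}\ncenter_y = {cy:.3f}\ncenter_z = {cz:.3f}\n"
            f"size_x = {self.edge:.1f}\nsize_y = {self.edge:.1f}\nsize_z = {self.edge:.1f}\n"
        )


# ---------------------------------------------------------------------------
# RMSD traces and windows
# ---------------------------------------------------------------------------

def rmsd_trace(
    traj: Trajectory,
    ref: int = 0,
    fit_sel: Selection | str = "mainchain",
    measure_sel: Selection | str | None = None,
) -> RmsdTrace:
    """RMSD of each frame to a reference frame, corrected for rigid motion.

    Each frame is superposed on the reference over ``fit_sel`` (Kabsch), then
    the RMSD is measured over ``measure_sel`` (default: the fit selection)
    without re-fitting.
    """
    if not 0 <= ref < traj.n_frames:
        raise WindowError(f"reference frame {ref} outside trajectory")
    fit_idx = select(traj.topology, fit_sel)
    if not fit_idx:
        raise SelectionError("empty fit selection")
    meas_idx = fit_idx if measure_sel is None else select(traj.topology, measure_sel)
    if not meas_idx:
        raise SelectionError("empty measure selection")
    ref_frame = traj.frames[ref]
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        R, t, _ = kabsch_superpose(frame, ref_frame, fit_idx)
        moved = frame[meas_idx] @ R.T + t
        values[i] = np.sqrt(np.mean(np.sum((moved - ref_frame[meas_idx]) ** 2, axis=1)))
    expr = fit_sel.expression if isinstance(fit_sel, Selection) else str(fit_sel)
    return RmsdTrace(traj.times(), values, ref, expr)


def analysis_window(traj: Trajectory, t_start: float) -> Trajectory:
    """Sub-trajectory of frames with time >= ``t_start`` (ps)."""
    times = traj.times()
    if t_start < 0 or t_start > times[-1]:
        raise WindowError(
            f"t_start {t_start} ps outside trajectory spanning {times[0]}..{times[-1]} ps"
        )
    keep = np.nonzero(times >= t_start)[0]
    return Trajectory(
        traj.topology,
        [traj.frames[i] for i in keep],
        dt=traj.dt,
        t0=float(times[keep[0]]),
    )


def equilibration_onset(
    trace: RmsdTrace, tol: float = 0.1, window: int = 20
) -> float | None:
    """First time after which the trace's running mean is stable.

    Returns the earliest time t such that, over every subsequent sliding window
    of ``window`` frames, the running mean changes by less than ``tol`` Å.
    Returns None if the trace never stabilises.  This is a reporting helper
    only — the analysis window start is always an explicit user choice.
    """
    v = np.asarray(trace.values)
    n = len(v)
    if n < 2 * window:
        return None
    means = np.convolve(v, np.ones(window) / window, mode="valid")
    drift = np.abs(np.diff(means))
    # require stability from this point to the end
    stable_from = None
    for i in range(len(drift) - 1, -1, -1):
        if drift[i] >= tol:
            break
        stable_from = i
    if stable_from is None:
        return None
    return float(trace.times[stable_from])


# ---------------------------------------------------------------------------
# conformer clustering
# ---------------------------------------------------------------------------

def _fitted_rmsd(a: np.ndarray, b: np.ndarray, idx: list[int]) -> float:
    _, _, value = kabsch_superpose(a, b, idx)
    return value


def pairwise_fitted_rmsd(traj: Trajectory, sel: Selection | str = "mainchain") -> np.ndarray:
    """Symmetric matrix of pairwise RMSDs after per-pair superposition on ``sel``."""
    idx = select(traj.topology, sel)
    if not idx:
        raise SelectionError("empty clustering selection")
    n = traj.n_frames
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _fitted_rmsd(traj.frames[i], traj.frames[j], idx)
    return mat


def cluster_conformers(
    traj: Trajectory,
    sel: Selection | str = "mainchain",
    radius: float = 2.0,
) -> ConformerSet:
    """Deterministic leader clustering of frames by main-chain RMSD.

    In frame order, a frame joins the first existing cluster whose
    representative lies within ``radius`` (inclusive boundary), else it founds
    a new cluster.  A final pass re-centres each representative on the
    cluster's medoid (the member minimising the summed RMSD to the others).
    Clusters are renumbered by decreasing size (ties: founding order).
    """
    if radius <= 0:
        raise ParameterError("cluster radius must be positive")
    idx = select(traj.topology, sel)
    if not idx:
        raise SelectionError("empty clustering selection")
    n = traj.n_frames
    if n == 0:
        raise WindowError("cannot cluster an empty trajectory")
    leaders: list[int] = []
    assign = np.empty(n, dtype=int)
    for fi in range(n):
        placed = False
        for cid, leader in enumerate(leaders):
            if _fitted_rmsd(traj.frames[fi], traj.frames[leader], idx) <= radius:
                assign[fi] = cid
                placed = True
                break
        if not placed:
            assign[fi] = len(leaders)
            leaders.append(fi)

    # medoid refinement within each cluster
    reps: list[int] = []
    for cid in range(len(leaders)):
        members = [int(i) for i in np.nonzero(assign == cid)[0]]
        if len(members) == 1:
            reps.append(members[0])
            continue
        best, best_cost = members[0], np.inf
        for m in members:
            cost = sum(
                _fitted_rmsd(traj.frames[m], traj.frames[o], idx)
                for o in members if o != m
            )
            if cost < best_cost - 1e-12:
                best, best_cost = m, cost
        reps.append(best)

    # renumber by decreasing size, founding order breaking ties
    sizes = [int(np.sum(assign == cid)) for cid in range(len(leaders))]
    order = sorted(range(len(leaders)), key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    assignments = np.array([remap[c] for c in assign], dtype=int)
    representatives = [reps[old] for old in order]
    cluster_sizes = [sizes[old] for old in order]
    return ConformerSet(radius, assignments, representatives, cluster_sizes)


# ---------------------------------------------------------------------------
# docking grid box
# ---------------------------------------------------------------------------

def grid_box(
    receptor: Structure,
    edge: float = 40.0,
    spacing: float = 1.0,
    mass_weighted: bool = True,
) -> GridBox:
    """Docking grid centred on the receptor's centre of gravity.

    The centre is the mass-weighted centroid of the heavy atoms (standard
    atomic masses); set ``mass_weighted=False`` for the geometric centroid.
    """
    heavy = [a for a in receptor.atoms if not a.is_hydrogen]
    if not heavy:
        raise SelectionError("receptor has no heavy atoms")
    coords = np.array([a.coords for a in heavy])
    if mass_weighted:
        weights = np.array([ATOMIC_MASSES.get(a.element.upper(), 12.011) for a in heavy])
    else:
        weights = np.ones(len(heavy))
    center = tuple(float(x) for x in np.average(coords, axis=0, weights=weights))
    return GridBox(center, edge, spacing)
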