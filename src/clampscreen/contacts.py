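"""Intermolecular contact persistence over an MD trajectory.

A residue pair is *in contact* in a frame when the minimum heavy-atom distance
between the two residues does not exceed the cutoff (3 Å by default, boundary
inclusive).  Persistence is the fraction of analysis-window frames in which the
contact exists; pairs reaching 80% are classed *persistent* and 90% *very
persistent* (both thresholds inclusive).  Per-residue hotspot profiles report,
for each residue of the first group, the maximum persistence against each
partner chain — the histogram used to locate interface hotspots.

The denominator is always the user-specified analysis window.  Extract the
post-equilibration window first (see :func:`clampscreen.ensemble.analysis_window`)
when equilibration frames must be excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ParameterError, SelectionError, WindowError
from .structio import Selection, Structure, Trajectory, select

__all__ = [
    "ContactParams",
    "ContactEntry",
    "ContactTable",
    "ResidueProfile",
    "frame_contacts",
    "persistence",
    "residue_profile",
    "water_bridges",
    "classify",
]

ResidueKey = tuple[str, int, str]  # (chain, resid, resname)

#: Fig-style class colour key: very persistent green, persistent yellow, poor red
CLASS_COLORS = {"very_persistent": "green", "persistent": "yellow", "poor": "red"}


@dataclass(frozen=True)
class ContactParams:
    """Distance cutoff and persistence thresholds (all boundaries inclusive)."""

    cutoff: float = 3.0
    persistent_threshold: float = 0.80
    very_persistent_threshold: float = 0.90

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive")
        if not (0 < self.persistent_threshold <= self.very_persistent_threshold <= 1):
            raise ParameterError(
                "need 0 < persistent_threshold <= very_persistent_threshold <= 1"
            )


def classify(fraction: float, params: ContactParams) -> str:
    if fraction >= params.very_persistent_threshold:
        return "very_persistent"
    if fraction >= params.persistent_threshold:
        return "persistent"
    return "poor"


@dataclass
class ContactEntry:
    residue_a: ResidueKey
    residue_b: ResidueKey
    n_frames_in_contact: int
    n_window_frames: int
    fraction: float
    contact_class: str


@dataclass
class ContactTable:
    """Per residue-pair persistence over an analysis window."""

    window: tuple[int, int]  # (first_frame, last_frame), inclusive
    entries: list[ContactEntry] = field(default_factory=list)
    params: ContactParams = field(default_factory=ContactParams)

    @property
    def n_window_frames(self) -> int:
        return self.window[1] - self.window[0] + 1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chainA": e.residue_a[0], "residA": e.residue_a[1], "resnameA": e.residue_a[2],
                "chainB": e.residue_b[0], "residB": e.residue_b[1], "resnameB": e.residue_b[2],
                "n_contact_frames": e.n_frames_in_contact,
                "n_window_frames": e.n_window_frames,
                "fraction": e.fraction,
                "class": e.contact_class,
            }
            for e in self.entries
        ]
        return pd.DataFrame(
            rows,
            columns=["chainA", "residA", "resnameA", "chainB", "residB", "resnameB",
                     "n_contact_frames", "n_window_frames", "fraction", "class"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def filter_class(self, contact_class: str) -> "ContactTable":
        return ContactTable(
            self.window,
            [e for e in self.entries if e.contact_class == contact_class],
            self.params,
        )


@dataclass
class ResidueProfile:
    """One histogram bar per (group-A residue, partner chain)."""

    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["chain", "resid", "resname", "partner_chain",
                     "max_fraction", "class", "color"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-frame contacts
# ---------------------------------------------------------------------------

def _heavy_residue_groups(
    structure: Structure, sel: Selection | str
) -> tuple[np.ndarray, list[ResidueKey], np.ndarray]:
    """Heavy-atom indices of a selection with their residue-key group labels."""
    idx = [i for i in select(structure, sel) if not structure.atoms[i].is_hydrogen]
    if not idx:
        raise SelectionError(f"selection {sel!r} contains no heavy atoms")
    keys: list[ResidueKey] = []
    key_of: dict[ResidueKey, int] = {}
    labels = np.empty(len(idx), dtype=int)
    for n, i in enumerate(idx):
        k = structure.atoms[i].residue_key()
        if k not in key_of:
            key_of[k] = len(keys)
            keys.append(k)
        labels[n] = key_of[k]
    return np.asarray(idx, dtype=int), keys, labels


def frame_contacts(
    frame: np.ndarray,
    structure: Structure,
    selA: Selection | str,
    selB: Selection | str,
    cutoff: float = 3.0,
) -> set[tuple[ResidueKey, ResidueKey]]:
    """Residue pairs of two disjoint groups within ``cutoff`` in one frame.

    A pair is reported iff the minimum heavy-atom distance is <= cutoff
    (inclusive).  Neighbour search uses a KD-tree; the result is identical to
    an all-pairs scan.
    """
    ia, keys_a, lab_a = _heavy_residue_groups(structure, selA)
    ib, keys_b, lab_b = _heavy_residue_groups(structure, selB)
    if set(ia) & set(ib):
        raise SelectionError("contact selections overlap")
    frame = np.asarray(frame, dtype=float)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    tree_b = cKDTree(frame[ib])
    for na, a_idx in enumerate(ia):
        for nb in tree_b.query_ball_point(frame[a_idx], cutoff):
            pairs.add((keys_a[lab_a[na]], keys_b[lab_b[nb]]))
    return pairs


# ---------------------------------------------------------------------------
# persistence over a window
# ---------------------------------------------------------------------------

def _resolve_window(traj: Trajectory, window: tuple[int, int] | None) -> tuple[int, int]:
    if window is None:
        window = (0, traj.n_frames - 1)
    first, last = window
    if first < 0 or last >= traj.n_frames or first > last:
        raise WindowError(
            f"window {window} outside trajectory of {traj.n_frames} frames"
        )
    return first, last


def persistence(
    traj: Trajectory,
    selA: Selection | str,
    selB: Selection | str,
    params: ContactParams | None = None,
    window: tuple[int, int] | None = None,
) -> ContactTable:
    """Contact persistence of every residue pair ever in contact in the window."""
    params = params or ContactParams()
    first, last = _resolve_window(traj, window)
    n_frames = last - first + 1
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    for fi in range(first, last + 1):
        for pair in frame_contacts(traj.frames[fi], traj.topology, selA, selB, params.cutoff):
            counts[pair] = counts.get(pair, 0) + 1
    entries = []
    for (ka, kb), n in sorted(counts.items()):
        frac = n / n_frames
        entries.append(ContactEntry(ka, kb, n, n_frames, frac, classify(frac, params)))
    # most persistent first, then residue order for determinism
    entries.sort(key=lambda e: (-e.fraction, e.residue_a, e.residue_b))
    return ContactTable((first, last), entries, params)


def residue_profile(table: ContactTable, group_by_partner_chain: bool = True) -> ResidueProfile:
    """Hotspot histogram: max persistence per group-A residue (per partner chain)."""
    if not table.entries:
        raise ParameterError("cannot profile an empty contact table")
    best: dict[tuple, ContactEntry] = {}
    for e in table.entries:
        partner = e.residue_b[0] if group_by_partner_chain else "*"
        key = (e.residue_a, partner)
        if key not in best or e.fraction > best[key].fraction:
            best[key] = e
    records = []
    for (res, partner), e in sorted(best.items()):
        records.append({
            "chain": res[0], "resid": res[1], "resname": res[2],
            "partner_chain": partner,
            "max_fraction": e.fraction,
            "class": classify(e.fraction, table.params),
            "color": CLASS_COLORS[classify(e.fraction, table.params)],
        })
    records.sort(key=lambda r: (r["chain"], r["resid"], r["partner_chain"]))
    return ResidueProfile(records)


# ---------------------------------------------------------------------------
# water-mediated bridges
# ---------------------------------------------------------------------------

def water_bridges(
    traj: Trajectory,
    selA: Selection | str,
    selB: Selection | str,
    water_sel: Selection | str = "water",
    bridge_cutoff: float = 3.5,
    params: ContactParams | None = None,
    window: tuple[int, int] | None = None,
) -> ContactTable:
    """Persistence of water-mediated residue bridges.

    A pair (a, b) is bridged in a frame iff some water oxygen lies within
    ``bridge_cutoff`` of a heavy atom of *both* residues.  Persistence uses the
    same window/threshold machinery as direct contacts.  An empty water
    selection yields an empty table.
    """
    params = params or ContactParams()
    first, last = _resolve_window(traj, window)
    n_frames = last - first + 1
    topo = traj.topology
    try:
        water_idx = [
            i for i in select(topo, water_sel)
            if topo.atoms[i].element == "O"
        ]
    except SelectionError:
        water_idx = []
    if not water_idx:
        return ContactTable((first, last), [], params)
    ia, keys_a, lab_a = _heavy_residue_groups(topo, selA)
    ib, keys_b, lab_b = _heavy_residue_groups(topo, selB)
    counts: dict[tuple[ResidueKey, ResidueKey], int] = {}
    for fi in range(first, last + 1):
        frame = traj.frames[fi]
        wtree = cKDTree(frame[water_idx])
        near_a = wtree.query_ball_point(frame[ia], bridge_cutoff)
        near_b = wtree.query_ball_point(frame[ib], bridge_cutoff)
        waters_by_res_a: dict[int, set[int]] = {}
        for na, ws in enumerate(near_a):
            waters_by_res_a.setdefault(lab_a[na], set()).update(ws)
        waters_by_res_b: dict[int, set[int]] = {}
        for nb, ws in enumerate(near_b):
            waters_by_res_b.setdefault(lab_b[nb], set()).update(ws)
        seen: set[tuple[ResidueKey, ResidueKey]] = set()
        for ga, wa in waters_by_res_a.items():
            for gb, wb in waters_by_res_b.items():
                if wa & wb:
                    seen.add((keys_a[ga], keys_b[gb]))
        for pair in seen:
            counts[pair] = counts.get(pair, 0) + 1
    entries = []
    for (ka, kb), n in sorted(counts.items()):
        frac = n / n_frames
        entries.append(ContactEntry(ka, kb, n, n_frames, frac, classify(frac, params)))
    entries.sort(key=lambda e: (-e.fraction, e.residue_a, e.residue_b))
    return ContactTable((first, last), entries, params)
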