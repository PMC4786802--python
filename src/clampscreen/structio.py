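"""Multi-model PDB structures: parsing, atom selection, superposition and surface areas.

The trajectory carrier is deliberately restricted to the text multi-model PDB
dialect (``MODEL``/``ENDMDL``/``ATOM``/``HETATM``/``TER``): frames saved from an
MD engine are assumed pre-converted to this form.  Author residue numbering is
preserved throughout, because contact tables and hotspot profiles are reported
against it (e.g. the ligase IV clamp, residues 771-803).

Atom classes used by selections and contact typing:

====================  =======================================================
keyword               meaning
====================  =======================================================
``heavy``             element is not H/D
``mainchain``         atom name in {N, CA, C, O}
``polar``             element in {N, O}
``hydrophobic``       element C (S deliberately belongs to neither class)
``water``             residue name HOH or WAT
====================  =======================================================
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    FitError,
    ParameterError,
    PDBParseError,
    SelectionError,
    TopologyError,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "Selection",
    "DEFAULT_RADII",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select",
    "kabsch_superpose",
    "superpose_coords",
    "rmsd",
    "sasa",
    "interface_area",
    "load_radii",
]

# van der Waals radii (Å) used for surface areas; overridable via a JSON table
DEFAULT_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

_MAINCHAIN_NAMES = frozenset({"N", "CA", "C", "O"})
_WATER_RESNAMES = frozenset({"HOH", "WAT"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom record with author numbering preserved."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resid, self.resname)


@dataclass
class Structure:
    """An ordered list of atoms with a label."""

    atoms: list[Atom]
    id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        if len(coords) != len(self.atoms):
            raise TopologyError(
                f"coordinate array has {len(coords)} rows for {len(self.atoms)} atoms"
            )
        atoms = [
            Atom(a.serial, a.name, a.element, a.resname, a.resid, a.chain,
                 np.asarray(c, dtype=float), a.occupancy, a.bfactor)
            for a, c in zip(self.atoms, coords)
        ]
        return Structure(atoms, id if id is not None else self.id)

    def subset(self, indices: Sequence[int], id: str | None = None) -> "Structure":
        return Structure([self.atoms[i] for i in indices], id if id is not None else self.id)


@dataclass
class Trajectory:
    """Frames sharing one atom topology; ``dt`` is the frame spacing in ps."""

    topology: Structure
    frames: list[np.ndarray]
    dt: float | None = None
    t0: float = 0.0

    def __post_init__(self):
        n = len(self.topology)
        for i, f in enumerate(self.frames):
            if len(f) != n:
                raise TopologyError(f"frame {i} has {len(f)} atoms, topology has {n}")
        if self.dt is not None and self.dt <= 0:
            raise ParameterError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        """Frame times in ps (frame index if dt is unset)."""
        dt = self.dt if self.dt is not None else 1.0
        return self.t0 + dt * np.arange(self.n_frames)

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class Selection:
    """A selection expression: clauses joined by ``and``.

    Grammar (one clause per ``and``-separated token group)::

        chain <id>[,<id>...]
        resid <a>[-<b>][,<c>[-<d>]...]
        resname <name>[,<name>...]
        name <atomname>[,<atomname>...]
        heavy | mainchain | polar | hydrophobic | water | protein | all

    ``protein`` means "not water".  Evaluation is deterministic and
    order-preserving on a given structure.
    """

    expression: str

    def indices(self, structure: Structure) -> list[int]:
        return select(structure, self)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str]:
    """Parse a fixed-width ATOM/HETATM record; returns (atom, altloc)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_s = line[54:60].strip()
        b_s = line[60:66].strip()
        occupancy = float(occ_s) if occ_s else 1.0
        bfactor = float(b_s) if b_s else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"unparseable ATOM/HETATM record ({exc})", lineno) from None
    if not element:
        # fall back on the atom-name convention: first alphabetic character,
        # honouring the 2-char element column layout for names like "CA"
        stripped = re.sub(r"\d", "", name)
        element = stripped[:1].upper()
    if not element:
        raise PDBParseError("cannot determine element", lineno)
    coords = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise PDBParseError("non-finite coordinates", lineno)
    return Atom(serial, name, element, resname, resid, chain, coords, occupancy, bfactor), altloc


def _resolve_altlocs(records: list[tuple[Atom, str]]) -> list[Atom]:
    """Keep the highest-occupancy alternate conformer (ties: first in file)."""
    best: dict[tuple, int] = {}
    order: list[tuple] = []
    for i, (atom, altloc) in enumerate(records):
        key = (atom.chain, atom.resid, atom.resname, atom.name)
        if key not in best:
            best[key] = i
            order.append(key)
        elif altloc and records[best[key]][0].occupancy < atom.occupancy:
            best[key] = i
    return [records[best[k]][0] for k in order]


def read_multimodel_pdb(path: str | Path, id: str | None = None, dt: float | None = None) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    A file without ``MODEL`` records yields a single frame.  All models must be
    atom-congruent; the first model defines the topology.  Alternate locations
    are resolved to the highest-occupancy conformer.
    """
    path = Path(path)
    models: list[list[tuple[Atom, str]]] = []
    current: list[tuple[Atom, str]] = []
    in_model = False
    seen_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                seen_model_record = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line.rstrip("\n"), lineno))
    if current or not seen_model_record:
        if current:
            models.append(current)
    if not models or all(len(m) == 0 for m in models):
        raise PDBParseError(f"no ATOM/HETATM records in {path}")
    models = [m for m in models if m]

    resolved = [_resolve_altlocs(m) for m in models]
    topo_atoms = resolved[0]
    topo_sig = [(a.chain, a.resid, a.resname, a.name) for a in topo_atoms]
    frames = [np.array([a.coords for a in topo_atoms])]
    for mi, atoms in enumerate(resolved[1:], start=2):
        sig = [(a.chain, a.resid, a.resname, a.name) for a in atoms]
        if sig != topo_sig:
            raise TopologyError(
                f"model {mi} of {path.name} is not atom-congruent with model 1 "
                f"({len(atoms)} vs {len(topo_atoms)} atoms)"
            )
        frames.append(np.array([a.coords for a in atoms]))
    topology = Structure(topo_atoms, id or path.stem)
    return Trajectory(topology, frames, dt=dt)


def _format_atom_line(a: Atom, serial: int, coords: np.ndarray) -> str:
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4.4s} {a.resname:<3.3s} {a.chain:1.1s}{a.resid:4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}{a.occupancy:6.2f}{a.bfactor:6.2f}"
        f"          {a.element:>2.2s}"
    )


def write_multimodel_pdb(traj: Trajectory | Structure, path: str | Path) -> None:
    """Write a trajectory (or single structure) as MODEL/ENDMDL PDB text."""
    if isinstance(traj, Structure):
        traj = Trajectory(traj, [traj.coords()])
    lines: list[str] = []
    multi = traj.n_frames > 1
    for fi, frame in enumerate(traj.frames, start=1):
        if multi:
            lines.append(f"MODEL     {fi:4d}")
        for si, (atom, xyz) in enumerate(zip(traj.topology.atoms, frame), start=1):
            lines.append(_format_atom_line(atom, si, xyz))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def _parse_int_ranges(spec: str) -> list[tuple[int, int]]:
    ranges = []
    for tok in spec.split(","):
        tok = tok.strip()
        if not tok:
            raise SelectionError(f"empty range in {spec!r}")
        m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", tok)
        if not m:
            raise SelectionError(f"malformed resid range {tok!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise SelectionError(f"inverted resid range {tok!r}")
        ranges.append((lo, hi))
    return ranges


def _clause_mask(clause: str, structure: Structure) -> np.ndarray:
    atoms = structure.atoms
    parts = clause.split(None, 1)
    kw = parts[0].lower()
    arg = parts[1].strip() if len(parts) > 1 else None
    if kw == "chain":
        if not arg:
            raise SelectionError("chain clause needs an argument")
        chains = {c.strip() for c in arg.split(",")}
        return np.array([a.chain in chains for a in atoms])
    if kw == "resid":
        if not arg:
            raise SelectionError("resid clause needs an argument")
        ranges = _parse_int_ranges(arg)
        return np.array([any(lo <= a.resid <= hi for lo, hi in ranges) for a in atoms])
    if kw == "resname":
        if not arg:
            raise SelectionError("resname clause needs an argument")
        names = {n.strip().upper() for n in arg.split(",")}
        return np.array([a.resname.upper() in names for a in atoms])
    if kw == "name":
        if not arg:
            raise SelectionError("name clause needs an argument")
        names = {n.strip().upper() for n in arg.split(",")}
        return np.array([a.name.upper() in names for a in atoms])
    if arg is not None:
        raise SelectionError(f"keyword {kw!r} takes no argument")
    if kw == "heavy":
        return np.array([not a.is_hydrogen for a in atoms])
    if kw == "mainchain":
        return np.array([a.name in _MAINCHAIN_NAMES for a in atoms])
    if kw == "polar":
        return np.array([a.element in ("N", "O") for a in atoms])
    if kw == "hydrophobic":
        return np.array([a.element == "C" for a in atoms])
    if kw == "water":
        return np.array([a.resname.upper() in _WATER_RESNAMES for a in atoms])
    if kw == "protein":
        return np.array([a.resname.upper() not in _WATER_RESNAMES for a in atoms])
    if kw == "all":
        return np.ones(len(atoms), dtype=bool)
    raise SelectionError(f"unknown selection keyword {kw!r}")


def select(structure: Structure, sel: Selection | str) -> list[int]:
    """Evaluate a selection expression to an ordered atom-index list."""
    expr = sel.expression if isinstance(sel, Selection) else sel
    expr = expr.strip()
    if not expr:
        raise SelectionError("empty selection expression")
    mask = np.ones(len(structure), dtype=bool)
    for clause in re.split(r"\band\b", expr):
        clause = clause.strip()
        if not clause:
            raise SelectionError(f"dangling 'and' in {expr!r}")
        mask &= _clause_mask(clause, structure)
    return [int(i) for i in np.nonzero(mask)[0]]


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_idx: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with the proper rotation ``R`` (det = +1) and
    translation ``t`` such that ``mobile @ R.T + t`` best matches ``reference``
    over ``fit_idx``; ``rmsd`` is the post-fit RMSD over the fit atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise FitError(f"shape mismatch {mobile.shape} vs {reference.shape}")
    idx = np.arange(len(mobile)) if fit_idx is None else np.asarray(list(fit_idx), dtype=int)
    if len(idx) < 3:
        raise FitError(f"need >=3 fit atoms, got {len(idx)}")
    P = mobile[idx]
    Q = reference[idx]
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinearity check: rank of the centred cloud
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise FitError("degenerate (collinear) fit geometry")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    fitted = P @ R.T + t
    value = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, value


def superpose_coords(
    mobile: np.ndarray, reference: np.ndarray, fit_idx: Sequence[int] | None = None
) -> np.ndarray:
    """Apply the Kabsch fit computed on ``fit_idx`` to the whole mobile frame."""
    R, t, _ = kabsch_superpose(mobile, reference, fit_idx)
    return np.asarray(mobile, dtype=float) @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray, idx: Sequence[int] | None = None) -> float:
    """Plain coordinate RMSD (no fitting) over ``idx`` (default: all rows)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if idx is not None:
        idx = np.asarray(list(idx), dtype=int)
        a, b = a[idx], b[idx]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def load_radii(path: str | Path) -> dict[str, float]:
    """Load a per-element van der Waals radii table from JSON."""
    table = json.loads(Path(path).read_text())
    return {str(k): float(v) for k, v in table.items()}


def sasa(
    structure: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Å²), Shrake-Rupley quadrature.

    Hydrogens are ignored (zero area).  ``radii`` overrides the default
    per-element van der Waals table; elements absent from the table raise
    :class:`ParameterError`.
    """
    if probe <= 0:
        raise ParameterError("probe radius must be positive")
    if n_points <= 0:
        raise ParameterError("n_points must be positive")
    table = DEFAULT_RADII if radii is None else radii
    heavy = [i for i, a in enumerate(structure.atoms) if not a.is_hydrogen]
    areas = np.zeros(len(structure))
    if not heavy:
        return areas
    coords = np.array([structure.atoms[i].coords for i in heavy])
    try:
        rads = np.array([table[structure.atoms[i].element] for i in heavy])
    except KeyError as exc:
        raise ParameterError(f"no vdW radius for element {exc.args[0]!r}") from None
    ext = rads + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    for k, (c, re_k) in enumerate(zip(coords, ext)):
        pts = c + re_k * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(c, re_k + ext.max()):
            if j == k:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        areas[heavy[k]] = 4.0 * math.pi * re_k**2 * accessible.sum() / n_points
    return areas


def interface_area(
    complex_structure: Structure,
    selA: Selection | str,
    selB: Selection | str,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> float:
    """Buried interface area between two halves of a complex, in Å².

    Computed as ``(SASA(A) + SASA(B) - SASA(AB)) / 2`` — the half-buried-area
    convention of the structure-analysis literature (what PISA reports).
    """
    ia = select(complex_structure, selA)
    ib = select(complex_structure, selB)
    if set(ia) & set(ib):
        raise SelectionError("interface selections overlap")
    if not ia or not ib:
        raise SelectionError("interface selections must both be non-empty")
    a = complex_structure.subset(ia, "A")
    b = complex_structure.subset(ib, "B")
    ab = complex_structure.subset(sorted(ia + ib), "AB")
    kw = dict(probe=probe, n_points=n_points, radii=radii)
    return float((sasa(a, **kw).sum() + sasa(b, **kw).sum() - sasa(ab, **kw).sum()) / 2.0)
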