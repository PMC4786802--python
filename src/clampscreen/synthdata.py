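"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator here is a pure function of its spec and a mandatory seed:
identical arguments yield byte-identical files.  The generated geometry is
deliberately non-physical — no sterics, no force field — because the analysis
stages consume only distances, scores and labels; what is emulated is the
*statistical and geometric structure* the analysis assumes:

* trajectories in which chosen residue pairs touch (min heavy-atom distance
  2.5 Å) with a planted per-frame probability, all other residues far apart;
* conformer ensembles with planted cluster structure (tight intra-cluster
  jitter, guaranteed inter-cluster main-chain RMSD separation);
* Vina-dialect pose files realizing planted scores, position-cluster layouts
  and polar/hydrophobic contact counts;
* per-candidate complex trajectories with planted stability behaviour
  (a stable single binding mode vs. two-site hopping);
* small compound libraries drawn from an internal catalogue whose descriptor
  verdicts were verified against the filter implementation's reference
  descriptors and frozen.

Ground truth always records the *realized* quantities (e.g. the realized
contact fraction, not just the target), so downstream checks can be exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SpecError
from .structio import Atom, Structure, Trajectory, write_multimodel_pdb
from .triage import Pose, PoseSet, TriageCriteria, triage_verdict, write_vina_poses
from .stability import EnergyTable

__all__ = [
    "TrajectorySpec",
    "CampaignSpec",
    "CompoundPlant",
    "make_contact_trajectory",
    "make_conformer_ensemble",
    "make_receptor_site",
    "make_pose_campaign",
    "make_stability_trajectory",
    "make_library",
    "CATALOGUE",
]

_CONTACT_DISTANCE = 2.4    # Å, planted "in contact" separation (cutoff is 3.0)
_APART_DISTANCE = 8.0      # Å, planted "no contact" separation
_PAIR_SPACING = 40.0       # Å between planted pairs along x


# ---------------------------------------------------------------------------
# contact trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Planted-contact trajectory: (residA, residB, target fraction) triples."""

    planted: tuple[tuple[int, int, float], ...]
    n_frames: int = 100
    jitter_sigma: float = 0.1
    chain_a: str = "C"
    chain_b: str = "A"
    n_extra_residues: int = 2      # far-away residues per chain, never in contact
    dt: float = 10.0               # ps between frames
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise SpecError("need at least one frame")
        for ra, rb, f in self.planted:
            if not 0.0 <= f <= 1.0:
                raise SpecError(f"fraction {f} for pair ({ra},{rb}) outside [0,1]")
        if self.jitter_sigma < 0:
            raise SpecError("jitter sigma must be >= 0")
        # jitter must not flip planted contacts across the 3 Å cutoff
        if _CONTACT_DISTANCE + 6 * self.jitter_sigma > 3.0:
            raise SpecError("jitter sigma too large: planted contacts could cross the cutoff")


def make_contact_trajectory(
    spec: TrajectorySpec, out_dir: str | Path | None = None
) -> tuple[Trajectory, pd.DataFrame]:
    """Trajectory with planted residue-pair contact persistence.

    Each planted pair occupies its own region of space; in each frame the pair
    sits at 2.5 Å (contact) with independent probability equal to its target
    fraction, else at 8 Å.  Fractions 0 and 1 are exact, not sampled.  The
    ground-truth table records target and realized fractions plus the exact
    contact frames.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[Atom] = []
    serial = 0

    def add_atom(chain: str, resid: int, pos) -> int:
        nonlocal serial
        serial += 1
        atoms.append(Atom(serial, "CA", "C", "ALA", resid, chain, np.asarray(pos, float)))
        return serial - 1

    base_a, base_b = [], []
    for k, (ra, rb, _f) in enumerate(spec.planted):
        base_a.append(add_atom(spec.chain_a, ra, [k * _PAIR_SPACING, 0.0, 0.0]))
        base_b.append(add_atom(spec.chain_b, rb, [k * _PAIR_SPACING, 0.0, 0.0]))
    n_pairs = len(spec.planted)
    for j in range(spec.n_extra_residues):
        add_atom(spec.chain_a, 900 + j, [j * _PAIR_SPACING, 150.0, 0.0])
        add_atom(spec.chain_b, 900 + j, [j * _PAIR_SPACING, 150.0, 50.0])

    # realize the planted schedule
    realized = np.zeros((n_pairs, spec.n_frames), dtype=bool)
    for k, (_ra, _rb, f) in enumerate(spec.planted):
        if f == 0.0:
            continue
        if f == 1.0:
            realized[k] = True
        else:
            realized[k] = rng.random(spec.n_frames) < f

    topo = Structure(atoms, "planted-contacts")
    base = topo.coords()
    frames = []
    for fi in range(spec.n_frames):
        coords = base.copy()
        for k in range(n_pairs):
            d = _CONTACT_DISTANCE if realized[k, fi] else _APART_DISTANCE
            coords[base_b[k]] = coords[base_a[k]] + np.array([0.0, d, 0.0])
        if spec.jitter_sigma > 0:
            coords = coords + rng.normal(0.0, spec.jitter_sigma / np.sqrt(3), coords.shape)
        frames.append(coords)
    traj = Trajectory(topo, frames, dt=spec.dt)

    truth = pd.DataFrame({
        "chainA": spec.chain_a,
        "residA": [ra for ra, _, _ in spec.planted],
        "chainB": spec.chain_b,
        "residB": [rb for _, rb, _ in spec.planted],
        "target_fraction": [f for _, _, f in spec.planted],
        "n_contact_frames": realized.sum(axis=1),
        "realized_fraction": realized.sum(axis=1) / spec.n_frames,
        "contact_frames": [",".join(map(str, np.nonzero(realized[k])[0])) for k in range(n_pairs)],
    })
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_multimodel_pdb(traj, out_dir / "trajectory.pdb")
        truth.to_csv(out_dir / "contact_truth.tsv", sep="\t", index=False)
    return traj, truth


# ---------------------------------------------------------------------------
# conformer ensembles
# ---------------------------------------------------------------------------

def _toy_backbone(n_residues: int, chain: str = "C") -> Structure:
    """A toy main chain: N, CA, C, O per residue along a gently curved path."""
    atoms = []
    serial = 0
    offsets = {"N": np.array([-0.7, 0.6, 0.0]), "CA": np.zeros(3),
               "C": np.array([0.8, 0.5, 0.2]), "O": np.array([1.0, -0.6, 0.5])}
    for i in range(n_residues):
        ca = np.array([1.8 * i, 2.0 * np.sin(0.6 * i), 2.0 * np.cos(0.6 * i)])
        for name in ("N", "CA", "C", "O"):
            serial += 1
            atoms.append(Atom(serial, name, name[0], "ALA", i + 1, chain, ca + offsets[name]))
    return Structure(atoms, "toy-backbone")


def make_conformer_ensemble(
    k: int,
    sizes: list[int] | int,
    intra_sigma: float = 0.2,
    inter_separation: float = 6.0,
    seed: int = 0,
    n_residues: int = 12,
    cluster_radius: float = 2.0,
    out_dir: str | Path | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Multi-model ensemble with ``k`` planted main-chain conformer clusters.

    Cluster centres are internal deformations of a common backbone, rescaled
    until every pair of centres is at least ``inter_separation`` apart in
    fitted main-chain RMSD; members add Gaussian jitter of ``intra_sigma`` Å
    per coordinate.  Frame order is shuffled (seeded).  Returns the trajectory
    and the planted cluster label per frame.  Recovery by leader clustering at
    ``cluster_radius`` is guaranteed when
    ``inter_separation > 2 * (cluster_radius + 3 * intra_sigma)``; a weaker
    spec emits a warning.
    """
    from .structio import kabsch_superpose  # local import to avoid cycle noise

    if k < 1:
        raise SpecError("need k >= 1 clusters")
    if isinstance(sizes, int):
        sizes = [sizes] * k
    if len(sizes) != k or any(s < 1 for s in sizes):
        raise SpecError("sizes must list one positive count per cluster")
    if inter_separation <= 2 * (cluster_radius + 3 * intra_sigma) and k > 1:
        warnings.warn(
            "inter-cluster separation does not guarantee recovery at this radius",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    topo = _toy_backbone(n_residues)
    base = topo.coords()
    n_atoms = len(base)

    # deform the backbone per cluster; rescale until pairwise fitted RMSD >= separation
    centers = [base.copy()]
    if k > 1:
        deformations = [rng.normal(0.0, 1.0, (n_atoms, 3)) for _ in range(k - 1)]
        scale = inter_separation  # starting guess; fitted RMSD grows ~linearly in scale
        for _ in range(40):
            centers = [base.copy()] + [base + scale * d for d in deformations]
            min_sep = np.inf
            for i in range(k):
                for j in range(i + 1, k):
                    _, _, r = kabsch_superpose(centers[i], centers[j])
                    min_sep = min(min_sep, r)
            if min_sep >= inter_separation:
                break
            scale *= 1.3 * inter_separation / max(min_sep, 1e-6)
        else:
            raise SpecError("could not realize the requested inter-cluster separation")

    labels = np.concatenate([np.full(s, c, dtype=int) for c, s in enumerate(sizes)])
    order = rng.permutation(len(labels))
    labels = labels[order]
    frames = [
        centers[c] + rng.normal(0.0, intra_sigma, (n_atoms, 3))
        for c in labels
    ]
    traj = Trajectory(topo, frames, dt=10.0)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_multimodel_pdb(traj, out_dir / "ensemble.pdb")
        pd.DataFrame({"frame": np.arange(len(labels)), "planted_cluster": labels}).to_csv(
            out_dir / "ensemble_labels.tsv", sep="\t", index=False
        )
    return traj, labels


# ---------------------------------------------------------------------------
# docking campaigns
# ---------------------------------------------------------------------------

def make_receptor_site(n_residues: int = 8, chain: str = "R") -> Structure:
    """A toy binding site: residues on a wide ring, one N and one C atom each.

    Residues are spaced >= 10 Å apart so a planted ligand atom contacts
    exactly one residue.
    """
    if n_residues < 3:
        raise SpecError("need at least 3 site residues")
    radius = 10.0 / (2.0 * np.sin(np.pi / n_residues))
    atoms = []
    serial = 0
    for i in range(n_residues):
        theta = 2.0 * np.pi * i / n_residues
        p = np.array([radius * np.cos(theta), radius * np.sin(theta), 0.0])
        serial += 1
        atoms.append(Atom(serial, "N", "N", "SIT", i + 1, chain, p))
        serial += 1
        atoms.append(Atom(serial, "CB", "C", "SIT", i + 1, chain, p + np.array([0.0, 0.0, 2.0])))
    return Structure(atoms, "toy-site")


@dataclass(frozen=True)
class CompoundPlant:
    """Planted docking outcome for one compound."""

    compound_id: str
    best_score: float
    n_pose_clusters: int = 1
    n_polar: int = 1
    n_hydrophobic: int = 1
    n_poses: int = 5
    stable: bool = True            # planted post-MD behaviour (see stability campaign)
    energy: float = -20.0          # planted end-point binding energy, kcal/mol
    expected_verdict: bool | None = None   # optional cross-check against the rule

    def __post_init__(self):
        if self.n_pose_clusters < 1 or self.n_poses < self.n_pose_clusters:
            raise SpecError("need n_poses >= n_pose_clusters >= 1")
        if self.n_polar < 0 or self.n_hydrophobic < 0:
            raise SpecError("contact counts must be >= 0")


@dataclass(frozen=True)
class CampaignSpec:
    compounds: tuple[CompoundPlant, ...]
    conformer_id: str = "conf00"
    seed: int = 0


def _build_pose_coords(
    plant: CompoundPlant, receptor: Structure, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Ligand heavy atoms realizing the planted contact counts exactly."""
    polar_sites = [a for a in receptor.atoms if a.element == "N"]
    hydro_sites = [a for a in receptor.atoms if a.element == "C"]
    if plant.n_polar > len(polar_sites) or plant.n_hydrophobic > len(hydro_sites):
        raise SpecError(
            f"compound {plant.compound_id}: planted contacts exceed site capacity"
        )
    coords, elements = [], []
    # polar contacts: ligand O at 3.0 Å above a residue's N (cutoff 3.5)
    for i in range(plant.n_polar):
        coords.append(polar_sites[i].coords + np.array([0.0, 0.0, -3.0]))
        elements.append("O")
    # hydrophobic contacts: ligand C at 3.5 Å above a residue's C (cutoff 4.0)
    for i in range(plant.n_hydrophobic):
        coords.append(hydro_sites[i].coords + np.array([0.0, 0.0, 3.5]))
        elements.append("C")
    # inert body atoms at the ring centre, far (> 4 Å) from every site atom
    for dz in (40.0, 41.5):
        coords.append(np.array([0.0, 0.0, dz]))
        elements.append("C")
    return np.array(coords), elements


def make_pose_campaign(
    spec: CampaignSpec,
    receptor: Structure | None = None,
    out_dir: str | Path | None = None,
    criteria: TriageCriteria | None = None,
) -> tuple[PoseSet, dict[str, Structure], pd.DataFrame, EnergyTable]:
    """Vina-dialect pose files realizing planted scores, clusters and contacts.

    Returns the in-memory pose set, the receptor-per-conformer map, the
    ground-truth table (including the verdict each compound must receive under
    the given criteria) and the planted energy table.  A plant whose
    ``expected_verdict`` contradicts the criteria raises :class:`SpecError`.
    """
    criteria = criteria or TriageCriteria()
    receptor = receptor or make_receptor_site()
    rng = np.random.default_rng(spec.seed)
    poseset = PoseSet()
    truth_rows = []
    energies = {}
    for plant in spec.compounds:
        base, elements = _build_pose_coords(plant, receptor, rng)
        poses = []
        score = plant.best_score
        for ci in range(plant.n_pose_clusters):
            # extra clusters sit far above the site, > 2 x cluster radius away
            shift = np.array([0.0, 0.0, 10.0 * ci])
            n_in_cluster = (
                plant.n_poses - plant.n_pose_clusters + 1 if ci == 0 else 1
            )
            for pi in range(n_in_cluster):
                jitter = rng.normal(0.0, 0.05, base.shape) if pi else np.zeros_like(base)
                poses.append(Pose(
                    plant.compound_id, spec.conformer_id, base + shift + jitter,
                    round(score, 3), list(elements),
                ))
                score += 0.3
        poseset.add(poses)
        verdict, reasons = triage_verdict(
            plant.best_score, plant.n_pose_clusters, plant.n_polar, plant.n_hydrophobic,
            criteria,
        )
        if plant.expected_verdict is not None and plant.expected_verdict != verdict:
            raise SpecError(
                f"compound {plant.compound_id}: planted verdict "
                f"{plant.expected_verdict} contradicts the rule ({reasons or 'pass'})"
            )
        energies[plant.compound_id] = plant.energy
        truth_rows.append({
            "compound_id": plant.compound_id,
            "best_score": plant.best_score,
            "n_pose_clusters": plant.n_pose_clusters,
            "n_polar": plant.n_polar,
            "n_hydrophobic": plant.n_hydrophobic,
            "stable": plant.stable,
            "energy": plant.energy,
            "verdict": verdict,
        })
    truth = pd.DataFrame(truth_rows)
    energy_table = EnergyTable(energies, method="planted")
    receptors = {spec.conformer_id: receptor}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for (cid, conf), poses in sorted(poseset.groups.items()):
            write_vina_poses(poses, out_dir / f"{cid}_{conf}.pdbqt")
        write_multimodel_pdb(receptor, out_dir / "receptor.pdb")
        truth.to_csv(out_dir / "campaign_truth.tsv", sep="\t", index=False)
        energy_table.write_tsv(out_dir / "energies.tsv")
    return poseset, receptors, truth, energy_table


# ---------------------------------------------------------------------------
# post-docking stability trajectories
# ---------------------------------------------------------------------------

def make_stability_trajectory(
    stable: bool,
    n_frames: int = 60,
    seed: int = 0,
    contact_fraction: float = 1.0,
    dt: float = 10.0,
) -> Trajectory:
    """Complex trajectory with planted ligand stability behaviour.

    The receptor is a rigid toy site (chain R).  A *stable* ligand (chain L)
    keeps a single binding mode: it touches residue 1 (2.5 Å) in
    ``contact_fraction`` of the frames and otherwise backs off to 3.6 Å —
    outside the 3 Å contact cutoff but within the position-cluster radius, so
    the binding mode stays unique.  An *unstable* ligand hops between two
    sites 7 Å apart in alternating blocks: two position clusters and no
    persistent contact.
    """
    rng = np.random.default_rng(seed)
    receptor = make_receptor_site()
    anchor = receptor.atoms[0].coords  # N of residue 1
    atoms = list(receptor.atoms)
    serial = max(a.serial for a in atoms)
    lig_base = []
    for j, (name, el) in enumerate([("O1", "O"), ("C1", "C"), ("C2", "C")]):
        serial += 1
        pos = anchor + np.array([0.0, 0.0, -2.5 - 1.4 * j])
        atoms.append(Atom(serial, name, el, "LIG", 1, "L", pos))
        lig_base.append(pos.copy())
    topo = Structure(atoms, "complex")
    lig_idx = list(range(len(receptor.atoms), len(atoms)))
    base = topo.coords()

    if stable:
        touching = (
            np.ones(n_frames, dtype=bool) if contact_fraction >= 1.0
            else rng.random(n_frames) < contact_fraction
        )
    else:
        block = 10
        touching = (np.arange(n_frames) // block) % 2 == 0
    frames = []
    for fi in range(n_frames):
        coords = base.copy()
        if stable:
            offset = 0.0 if touching[fi] else -1.1   # 2.5 -> 3.6 Å, same cluster
        else:
            offset = 0.0 if touching[fi] else -7.0   # hop to a site 7 Å away
        for li in lig_idx:
            coords[li] = coords[li] + np.array([0.0, 0.0, offset])
        coords[lig_idx] += rng.normal(0.0, 0.05, (len(lig_idx), 3))
        frames.append(coords)
    return Trajectory(topo, frames, dt=dt)


# ---------------------------------------------------------------------------
# compound libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CatalogueEntry:
    name: str
    smiles: str
    violations: frozenset[str]
    alt_smiles: str | None = None  # alternate spelling of the same structure

    @property
    def compliant(self) -> bool:
        return not self.violations


# Violation sets were computed with the package's own reference descriptors and
# frozen; `tests` re-verify every entry against apply_filters.
CATALOGUE: tuple[CatalogueEntry, ...] = (
    CatalogueEntry("ethanol", "CCO", frozenset(), "OCC"),
    CatalogueEntry("glycerol", "OCC(O)CO", frozenset(), "C(O)C(CO)O"),
    CatalogueEntry("prolinamide", "NC(=O)C1CCCN1", frozenset()),
    CatalogueEntry("acetamidopiperidine", "CC(=O)NC1CCNCC1", frozenset()),
    CatalogueEntry("methylurea", "CNC(N)=O", frozenset()),
    CatalogueEntry("lactamide", "CC(O)C(N)=O", frozenset()),
    CatalogueEntry("acetylmorpholine", "CC(=O)N1CCOCC1", frozenset(), "O=C(C)N1CCOCC1"),
    CatalogueEntry("imidazolylmethanol", "OCc1cnc[nH]1", frozenset()),
    CatalogueEntry("glycinamide", "NCC(N)=O", frozenset()),
    CatalogueEntry("cyclohexanol", "OC1CCCCC1", frozenset({"clogp", "sfi"})),
    CatalogueEntry("raffinose",
                   "OCC1OC(OCC2OC(OC3(CO)OC(CO)C(O)C3O)C(O)C(O)C2O)C(O)C(O)C1O",
                   frozenset({"mw", "clogp", "sfi", "tpsa", "hbd", "hba", "rotb"})),
    CatalogueEntry("dodecane", "CCCCCCCCCCCC", frozenset({"clogp", "sfi", "rotb"})),
    CatalogueEntry("glucose", "OCC1OC(O)C(O)C(O)C1O",
                   frozenset({"clogp", "sfi", "tpsa", "hba"})),
    CatalogueEntry("sorbitol", "OCC(O)C(O)C(O)C(O)CO",
                   frozenset({"clogp", "sfi", "tpsa", "hbd", "hba"})),
    CatalogueEntry("decanol", "CCCCCCCCCCO", frozenset({"clogp", "sfi", "rotb"})),
    CatalogueEntry("malonate_dianion", "[O-]C(=O)CC([O-])=O",
                   frozenset({"clogp", "sfi", "net_charge"})),
    CatalogueEntry("benzylidene_rhodanine", "O=C1C(=Cc2ccccc2)SC(=S)N1",
                   frozenset({"clogp", "sfi", "pains", "reactive:acrylamide"})),
    CatalogueEntry("catechol_azo", "Oc1ccc(N=Nc2ccccc2)cc1O",
                   frozenset({"clogp", "sfi", "pains"})),
    CatalogueEntry("acetyl_chloride", "CC(=O)Cl", frozenset({"reactive:acyl_halide"})),
    CatalogueEntry("peg_ether", "COCCOCCOCCOCCOCCOCCOCCOCCOCCOCCOCCOC",
                   frozenset({"mw", "tpsa", "hba", "rotb"})),
)


def make_library(
    n_compliant: int = 6,
    n_violators: int = 6,
    n_duplicates: int = 0,
    n_pains: int = 0,
    seed: int = 0,
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """A SMILES library with planted filter outcomes drawn from the catalogue.

    Violators cycle through the non-PAINS violating entries; PAINS decoys are
    requested separately.  Duplicates re-spell compliant entries that carry an
    alternate SMILES.  Returns the library table (id, smiles) and the ground
    truth: per-molecule expected violations plus aggregate totals.
    """
    rng = np.random.default_rng(seed)
    compliant = [e for e in CATALOGUE if e.compliant]
    violators = [e for e in CATALOGUE if e.violations and "pains" not in e.violations]
    pains = [e for e in CATALOGUE if "pains" in e.violations]
    dup_sources = [e for e in compliant if e.alt_smiles]
    if n_compliant > len(compliant) * 50 or n_violators > len(violators) * 50:
        raise SpecError("requested composition impossible from catalogue")
    if n_duplicates > n_compliant or n_duplicates > 0 and not dup_sources:
        raise SpecError("not enough duplicate-capable compliant entries")

    rows = []
    counter = 0

    def draw(pool, n, tag):
        nonlocal counter
        for i in range(n):
            e = pool[i % len(pool)]
            counter += 1
            rows.append({
                "id": f"{tag}{counter:03d}_{e.name}",
                "smiles": e.smiles,
                "expected_violations": sorted(e.violations),
                "expected_pass": e.compliant,
                "duplicate_of": None,
            })

    draw(compliant, n_compliant, "cmp")
    draw(violators, n_violators, "vio")
    draw(pains, n_pains, "pns")
    drawn_smiles = {r["smiles"] for r in rows}
    dup_sources = [e for e in dup_sources if e.smiles in drawn_smiles]
    if n_duplicates > 0 and not dup_sources:
        raise SpecError("no duplicate-capable compliant entries were drawn")
    for i in range(n_duplicates):
        e = dup_sources[i % len(dup_sources)]
        counter += 1
        original = next(r["id"] for r in rows if r["smiles"] == e.smiles)
        rows.append({
            "id": f"dup{counter:03d}_{e.name}",
            "smiles": e.alt_smiles,
            "expected_violations": sorted(e.violations),
            "expected_pass": e.compliant,
            "duplicate_of": original,
        })
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    library = pd.DataFrame(rows)

    rule_counts: dict[str, int] = {}
    for r in rows:
        for rule in r["expected_violations"]:
            rule_counts[rule] = rule_counts.get(rule, 0) + 1
    truth = {
        "n_total": len(rows),
        "n_pass": int(sum(r["expected_pass"] for r in rows)),
        "n_duplicates": n_duplicates,
        "rule_rejections": rule_counts,
    }
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w") as fh:
            for r in rows:
                fh.write(f"{r['smiles']}\t{r['id']}\n")
    return library, truth
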