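# Methods

This note documents the models and procedures `clampscreen` implements, the
parameters that matter, the deliberate design choices where conventions were
open, and what the synthetic-data tests do and do not demonstrate.

## Contact persistence and hotspot profiles

A contact between two residues of disjoint groups exists in a frame iff the
minimum Euclidean distance between their heavy atoms (element ≠ H/D) is
**≤ 3.0 Å** — the boundary is inclusive ("does not exceed").  Persistence is
`n_frames_in_contact / n_window_frames` over an explicit analysis window;
classes are *very persistent* at fraction ≥ 0.90 and *persistent* at ≥ 0.80,
again inclusive.  The denominator is always the window the caller supplies:
whether equilibration frames are excluded is an explicit decision
(`ensemble.analysis_window`), never guessed.  Contacts are residue-level
(minimum heavy-atom distance), keyed by `(chain, resid, resname)`, because
the hotspot histogram is a per-residue object: for each residue of the first
group and each partner chain it reports the maximum persistence over that
residue's pairs, with the green (≥ 90 %) / yellow (80–90 %) / red (< 80 %)
colour key.

The neighbour search uses a KD-tree per frame; a property test holds it
exactly equal to the all-pairs O(N²) scan on random frames, so the fast path
carries no approximation.

Water bridges: a pair is bridged in a frame iff one water **oxygen** lies
within 3.5 Å of heavy atoms of both residues.  The 3.5 Å value is the
standard donor–acceptor heavy-atom distance for hydrogen bonds; no angular
criterion is applied (out of scope).

## Superposition, RMSD traces and windows

Rigid-body fits use the Kabsch algorithm (SVD with a determinant correction,
so the rotation is always proper).  RMSD traces superpose each frame on the
reference over the fit selection, then measure RMSD over the measure
selection *without re-fitting* — for ligand-drift traces the fit selection is
the receptor, so translation of the ligand within the site is what is
measured.  Fewer than three fit atoms or collinear fit geometry raises an
error rather than returning an ill-conditioned rotation.

Equilibration detection is deliberately not automated into the pipeline: an
`equilibration_onset` helper reports the earliest time after which the
trace's running mean drifts by less than a tolerance per sliding window
(defaults 0.1 Å / 20 frames), but the analysis-window start is always an
explicit argument, because plateau calls on real traces are judgement calls.

## Receptor conformer clustering (relaxed complex scheme)

Frames are clustered on main-chain atoms (N, CA, C, O) by RMSD after
per-pair superposition, with deterministic leader clustering: in frame
order, a frame joins the first existing cluster whose representative is
within the radius (inclusive at the boundary), else founds a new cluster.
A final pass re-centres each representative on the cluster medoid (minimum
summed RMSD to the other members); ties and the first-founded-wins rule make
the procedure RNG-free and reproducible.  The default radius is 2.0 Å.  The
radius is applied frame-to-representative; with well-separated conformational
basins this is equivalent to the pairwise reading, and the synthetic
ensembles used in tests guarantee separation (inter-centre RMSD strictly
greater than `2·(radius + 3·jitter σ)`).

The docking grid box is a cube (default edge 40 Å, spacing 1 Å) centred on
the receptor's **mass-weighted** centroid of heavy atoms ("centre of
gravity" read literally; a flag switches to the geometric centroid).  Export
is in Vina config syntax (`center_x/y/z`, `size_x/y/z`).

## Surface areas

Solvent-accessible surface areas use Shrake–Rupley quadrature with a
deterministic golden-spiral point set (default 960 points, probe 1.4 Å) and
a per-element van der Waals radii table (C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80 Å; JSON-overridable).  Hydrogens are ignored.  The quadrature is
validated against the closed-form single-sphere and two-sphere
(spherical-cap) areas, a denser quadrature, and an independent
implementation.  The interface area between two halves of a complex is the
half-buried convention `(SASA(A) + SASA(B) − SASA(AB)) / 2` — the figure
structure-analysis services report; whether a published "interface spans X Å²"
figure used ΔSASA or ΔSASA/2 is often ambiguous, so the convention is stated
here and fixed.

## Library preparation

Descriptors are the standard cheminformatics choices, all computed with
RDKit: average-isotope molecular weight; Crippen atomic-contribution cLogP;
Ertl topological PSA; Lipinski-style donor (N/O–H) and acceptor (N + O)
counts; strict rotatable bonds (non-ring single bonds between heavy atoms,
terminal and amide C–N bonds excluded); net formal charge of the input
structure (no pKa model — protonation at assay pH is an upstream tool's
job); SFI = cLogP + aromatic ring count.

Default bounds: MW < 450 (strict, as printed), cLogP ∈ [−3, 1], SFI ∈ [−3, 1],
TPSA < 110 (strict), HBD ∈ [0, 5], HBA ∈ [0, 5], rotatable bonds ∈ [0, 6],
charge ∈ [−1, 1] (closed "between" intervals).  The SFI window mirrors the
cLogP window and is far narrower than the usual SFI < 5 solubility rule;
it is kept as the default deliberately and is configurable like every other
bound.  PAINS screening uses RDKit's built-in FilterCatalog (families A, B
and C); the reactive/warhead screen is a small versioned SMARTS list shipped
as JSON inside the package and fully swappable.  The audit records *every*
violated rule per molecule, which makes the cascade provably
order-independent (the pass set is the intersection of single-rule pass
sets); duplicates are removed by canonical SMILES, first occurrence kept
(tautomer-insensitive matching is out of scope).

Monoisotopic masses sum most-abundant-isotope masses per element and are
reported to 4 decimals, matching HRMS `calcd` arithmetic for a printed ion
formula (the [M+H]+ formula already contains the proton; no electron-mass
correction is applied, consistent with standard practice at this precision).
This utility is distinct from the MW filter, which uses average weights.

## Docking-pose triage

Vina affinities are negative (more negative = stronger), so "a score of at
least 7 kcal/mol of binding" is implemented as **pass iff score ≤ −7.0
kcal/mol, boundary inclusive** — a compound exactly at −7.0 with one cluster
and both contact types passes.  Poses of a compound are position-clustered
by in-place ligand RMSD (no re-fitting — the receptor conformers are already
in a common frame, and position inside the site is the signal), leader
clustering seeded by the best-scored pose, radius 2.0 Å by default.  Contact
typing: a polar contact is a (ligand N/O atom, site residue) pair within
3.5 Å of a receptor N/O atom; a hydrophobic contact a (ligand C, residue)
pair within 4.0 Å of a receptor carbon; sulfur belongs to neither class.
These interaction cutoffs are distinct from the 3 Å trajectory-contact
cutoff and never conflated with it.  The single-cluster rule is evaluated on
the best-scoring conformer's pose group by default; a pooled mode
(clustering all conformers' poses together) is exposed.  The verdict is a
pure function of (best score, cluster count, contact counts) and the
representative pose is always the lowest-energy one.

## Stability scoring and ranking

The qualitative 3/2/1 stability scale is made deterministic as: score 1 iff
the snapshot position clustering (radius 2.0 Å) finds more than one binding
mode; otherwise score 3 iff the mean ligand RMSD ≤ `t_stable` (default
1.5 Å), else score 2.  `t_stable` and the snapshot radius are this package's
own defaults — the scale itself is qualitative — and both are configurable.
Ligand–residue persistence reuses the contact machinery with the ligand as
one group and a 0.90 threshold.  The retention gate for ranking is
score ≥ 2 **and** at least one persistent contact (both configurable);
retained candidates sort by binding energy ascending.  Binding energies are
inputs (TSV: compound, kcal/mol, method) — end-point methods such as MM-GBSA
require a force field and are out of scope.  An optional surrogate scorer
(−1.0 kcal/mol per polar, −0.5 per hydrophobic site contact, labelled
`SURROGATE` in every output) exists solely so the funnel can run end-to-end
without external energies; its numbers are not physical.  An
`energy_window_frames` helper maps "the last Δt ns" onto frame indices
(default 4 ns) for bookkeeping of where input energies came from.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (spec, seed): identical inputs give
byte-identical files.  Geometry is deliberately non-physical — no sterics,
no force field, no solvent — because every analysis stage consumes distances,
scores and labels only.  What is emulated, with planted ground truth:

* **Contact trajectories** — each planted residue pair sits at 2.4 Å
  (contact) with independent per-frame probability equal to its target
  fraction, else 8 Å; other residues are kept far away; coordinate jitter is
  bounded so planted contacts cannot cross the 3 Å cutoff.  Ground truth
  records the *realized* per-frame outcomes, so downstream recovery checks
  are exact, while target-vs-recovered comparisons are statistical (binomial
  3σ at ≥ 100 frames).
* **Conformer ensembles** — cluster centres are internal deformations of a
  common toy backbone rescaled until all pairwise fitted RMSDs reach the
  requested separation; members add Gaussian jitter; a spec that cannot
  guarantee recovery triggers a warning, not silence.
* **Pose campaigns** — PDBQT files realizing planted scores (exactly, at the
  file format's 3-decimal precision), cluster layouts (extra clusters 10 Å
  away) and contact counts (one ligand atom placed against one distinct site
  residue per planted contact, site residues ≥ 10 Å apart so counts are
  unambiguous).  A plant whose declared verdict contradicts the triage rule
  is rejected.
* **Stability trajectories** — a stable ligand keeps one binding mode
  (occasional 1.1 Å back-off keeps sub-cutoff persistence realistic without
  creating a second cluster); an unstable one hops between sites 7 Å apart
  in alternating blocks (two clusters, ~50 % persistence).
* **Libraries** — drawn from a frozen internal catalogue of molecules whose
  violated-rule sets were verified against the reference descriptors;
  duplicates are alternate SMILES spellings of drawn entries.

Passing these tests demonstrates that the *analysis* is correct under its
stated definitions.  It does not demonstrate robustness to features of real
MD/docking data the generators do not model: correlated frames, partial
occupancy and altloc ambiguity beyond the highest-occupancy rule, borderline
contacts oscillating at the cutoff, receptor flexibility during docking, or
descriptor disagreements between cheminformatics toolkits.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script (50-atom contact
frames, 400-frame persistence runs, 44-frame 11-cluster ensembles, 60-frame
stability runs, 29-compound campaigns) are chosen so each planted structure
is unambiguous at the stated tolerances while the whole suite runs in
seconds; they mirror the funnel's shape (29 docked candidates, 11 retained)
rather than its full scale (~95,000 filtered molecules), which adds volume
but no new code paths.  Boundary semantics are inclusive wherever the rule
is phrased as "reaching" a threshold (3 Å contact, 80/90 % persistence,
−7 kcal/mol score, 2 Å cluster radius).  Degenerate inputs fail loudly:
empty selections, windows outside the trajectory, collinear fits, unknown
elements in formulas or radii tables, contradictory synthetic specs.

## Known limitations

* PDB dialect only (MODEL/ENDMDL); no mmCIF, DCD/XTC or binary MD formats —
  trajectories are assumed pre-converted.
* No hydrogen placement or protonation assignment; hydrogens present in
  input are carried but ignored by heavy-atom analyses.
* Polar/hydrophobic atom classes are minimal (N/O vs C); sulfur is typed as
  neither, aromatic/aliphatic carbons are not distinguished.
* The stability score's quantitative thresholds are package defaults for a
  qualitative scale; cross-study comparisons should state them.
* Binding energies are consumed, never computed; the surrogate scorer is a
  pipeline-plumbing device only.
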