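# clampscreen

Analytics for structure-based screening against the XRCC4 / DNA ligase IV
(Lig4) protein–protein interface — the assembly that performs the final
ligation step of Non-Homologous End-Joining and a target for radio-sensitizing
cancer therapeutics.  The XRCC4/Lig4 interface is large (~2900 Å² of buried
surface) and nanomolar-tight, so a screen cannot attack it whole: the
pipeline's job is to find the small hot region worth targeting (the Lig4
*clamp*, Helix1–Loop–Helix2, residues 771–803), produce an ensemble of
receptor conformations for docking, prepare a drug-like library, and triage
docking output into a short, ranked hit list.

`clampscreen` implements the analysis layers of that campaign as a reusable,
fully testable Python package.  MD engines and docking programs are **not**
run here — their outputs (multi-model PDB trajectories, AutoDock-Vina PDBQT
pose files, binding-energy tables) are the package's inputs, and a seeded
synthetic-data generator with planted ground truth stands in for them so the
entire funnel is verifiable at desk scale.

## What it computes

1. **Persistent-contact hotspot mapping** (`contacts`).  A residue pair of
   the complex is *in contact* in a frame when its minimum heavy-atom
   distance ≤ 3 Å; its persistence is the fraction of analysis-window frames
   with the contact.  Pairs with persistence ≥ 80 % are *persistent*, ≥ 90 %
   *very persistent*; a per-residue histogram (max persistence per partner
   chain, green/yellow/red classes) locates interface hotspots.

2. **Receptor-ensemble extraction** (`ensemble`).  RMSD traces (Kabsch
   superposition; rotation/translation of the whole complex corrected away),
   post-equilibration window cuts, and deterministic leader clustering of
   frames by main-chain RMSD at a fixed radius (2 Å default) — the
   relaxed-complex-scheme step that turns one MD run into a set of rigid
   receptor conformers.  Cubic docking grid boxes (40 Å edge, 1 Å spacing)
   centred on the receptor's centre of gravity are exported in Vina config
   syntax.

3. **Library preparation** (`libfilter`).  Eight descriptor bounds
   (MW < 450 Da; cLogP and SFI = cLogP + aromatic rings, both in [−3, 1];
   TPSA < 110 Å²; 0–5 HBD and HBA; 0–6 rotatable bonds; net formal charge in
   [−1, 1]), PAINS and reactive/warhead substructure removal, and
   canonical-SMILES deduplication — with a full per-molecule audit of *every*
   violated rule.  A separate monoisotopic-mass utility reproduces
   high-resolution-MS `calcd` arithmetic.

4. **Docking-pose triage** (`triage`).  Vina PDBQT parsing, position
   clustering of poses (leader clustering on in-place ligand RMSD), polar /
   hydrophobic contact typing inside the binding site, and the hit rule:
   best score ≤ −7 kcal/mol (inclusive), a single position cluster, and at
   least one polar and one hydrophobic site contact.

5. **Post-MD stability scoring** (`stability`).  Ligand drift inside the
   site (receptor-superposed RMSD without ligand re-fit), a 3/2/1 stability
   score (3 = very stable; 2 = fluctuating, unique binding mode; 1 = several
   binding modes), 90 %-persistent ligand–residue contacts, and ranking of
   retained candidates by externally supplied binding energies (e.g.
   MM-GBSA over the last 4 ns — consumed, never recomputed).

`structio` supplies the shared substrate: multi-model PDB I/O, a selection
mini-language, Kabsch superposition, Shrake–Rupley solvent-accessible surface
areas and half-ΔSASA interface areas.  `synthdata` generates every input
format with planted ground truth.

## Worked example

```pycon
>>> from clampscreen import persistence, monoisotopic_mass
>>> from clampscreen.synthdata import TrajectorySpec, make_contact_trajectory
>>> spec = TrajectorySpec(planted=((766, 100, 0.9), (778, 101, 0.0), (800, 102, 1.0)),
...                       n_frames=50, seed=3)
>>> traj, truth = make_contact_trajectory(spec)
>>> table = persistence(traj, "chain C and heavy", "chain A and heavy")
>>> for e in table.entries:
...     print(e.residue_a[1], e.residue_b[1], e.fraction, e.contact_class)
800 102 1.0 very_persistent
766 100 0.94 very_persistent
>>> round(monoisotopic_mass("C25H37N4O9"), 4)   # an [M+H]+ ion formula
537.2561
```

Residue 800's planted contact (target fraction 1.0) is recovered in every
frame; residue 766's 0.9-target contact realized 47/50 frames (0.94) and is
classed very persistent; the 0.0-target pair never appears.  The mass is the
`calcd` value a synthetic chemist would print for that protonated ion.

The same funnel is available from the shell:

```sh
clampscreen simulate --seed 5 --out-dir run      # synthetic campaign + ground truth
clampscreen contacts --trajectory run/trajectory/trajectory.pdb --out-dir run
clampscreen filter   --library run/library/library.smi --out-dir run
clampscreen triage   --poses-dir run/poses --receptor run/poses/receptor.pdb --out-dir run
clampscreen stability --trajectories-dir run/complex_trajectories \
                      --energy-table run/poses/energies.tsv --out-dir run
clampscreen report   --out-dir run               # merges stages into funnel.json
```

Each stage writes TSV/JSON outputs plus a `manifest.json` (package version,
config hash, seed); identical config and seed give byte-identical outputs.

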