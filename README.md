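# pepscreen

Structure-based triage toolkit for screening peptidomimetic inhibitors of
protein–protein interactions. It implements the computational stages of a
docking-centred discovery funnel:

- **Interface contact conservation** — intermolecular residue contacts at a
  4.0 Å heavy-atom cutoff, tabulated across many receptor–partner complexes
  with a configurable conservation threshold (`pepscreen.contacts`).
- **Probe-occupancy hotspot mapping** — voxel accumulation of organic-probe
  positions over the trailing window of a mixed-solvent ensemble, with
  connected-component hotspot reporting and flanking-residue annotation
  (`pepscreen.occupancy`).
- **Docking pose triage** — per-pose Ramachandran compliance, peptide-bond
  planarity/cis detection and intramolecular clash screening on the top-20
  poses of each compound, followed by a merge-and-sort across compounds and a
  −8 kcal/mol docking-energy cut (`pepscreen.posefilter`).
- **Binding-stability classification** — receptor-aligned ligand RMSD versus
  the docked pose, averaged over the trailing half of a trajectory; stable
  binder iff the mean is below 3 Å (`pepscreen.stability`).
- **Permeability prediction** — in-house Shrake–Rupley solvent-accessible
  surface area with a polar-atom restriction, averaged over a conformer
  ensemble (snapshots every 4 ps); permeable below 150 Å², synthesis cut at
  130 Å² (`pepscreen.permeability`).
- **Synthetic fixtures** — seeded generators for ideal-geometry peptides
  (internal-coordinate builder), decoy pose libraries with labeled defects,
  noisy trajectories, planted probe hotspots and toy complexes with planted
  contacts, so the whole cascade is testable offline (`pepscreen.synth`).

Supporting modules: fixed-column PDB I/O for structures, multi-model
ensembles and scored pose sets (`pepscreen.structio`); dihedral/Kabsch/RMSD
kernels (`pepscreen.geometry`); YAML run configuration (`pepscreen.config`).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(bookkeeping counts, SASA vs Monte-Carlo oracle, contact detection vs brute
force, cascade vs labeled decoys, stability statistics, hotspot recovery).
The two tests touching real RCSB entries are skipped unless the PDB files
are placed under `tests/data/rcsb/` (no network access is assumed).

## CLI

The `pepscreen` entry point exposes the pipeline stages:

```sh
pepscreen simulate poses --n-compounds 10 --out-dir poses/      # labeled decoys
pepscreen filter-poses --poses poses/ --report report.tsv --summary summary.json
pepscreen contacts --complex cx1.pdb --complex cx2.pdb \
    --receptor-chains A --partner-chains B --out table.tsv
pepscreen stability --traj traj.pdb --ref pose.pdb --ligand-chain L --receptor-chain A
pepscreen pasa --ensemble conformers.pdb
pepscreen occupancy --ensemble probes.pdb --probe-chain X=positive
pepscreen pipeline --poses poses/ --out-dir run/                # full funnel + manifest
```

All stages read a shared YAML config (`--config`); defaults encode the
published constants (4.0 Å, top 20, −8.0 kcal/mol, 3.0 Å, 150/130 Å², 4 ps).
Trajectories and conformer ensembles are plain multi-model PDB; pose sets
carry per-model `REMARK VINA RESULT` score lines.

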