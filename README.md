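# clashaudit

All-atom protein model building and model-quality auditing:

* **Structure I/O** — PDB/mmCIF reading and writing (via biotite), alternate-
  conformer resolution (highest occupancy wins), covalent-graph construction
  from residue templates.
* **Hydrogen placement** — riding hydrogens constructed at ideal nuclear
  geometry from the non-H atoms; rotatable hydrogens (hydroxyl, sulfhydryl,
  phenolic, terminal amine, water) get deterministic defaults.
* **Hydrogen-bond network optimization** — discrete states for rotatable
  hydrogens, Asp/Glu charge states, His charge/tautomer/flip states, Asn/Gln
  flips and water orientations; clusters of coupled sites are solved
  exhaustively when small, otherwise by multi-start best-response iteration,
  recombination and simulated annealing.
* **Clash detection** — nonbonded contacts classified against 0.8x (clash)
  and 0.7x (severe clash) of summed Rowland–Taylor van der Waals radii
  (H = 1.1 Å), with conservative hydrogen-bond (donor–acceptor) and
  bonded-path exclusions, plus a Richardson-system comparison mode
  (0.4 Å overlap, polar/aromatic H 1.00 Å, other H 1.17 Å).
* **Geometry statistics** — bond/angle RMSD and RMS Z scores against an
  Engh–Huber-style target table, side-chain planarity RMSD (least-squares
  planes), and peptide ω-angle deviation; frequencies reported per 100
  residues (sum/sum pooling for cohorts).
* **Fixture generator** — synthetic peptides built from internal coordinates
  using the *same* target tables the validators read, so ideal fixtures score
  exactly zero; engineered contacts at exact distance ratios; internal-
  coordinate Gaussian noise for RMS Z recovery tests; small hydrogen-bond
  network toys with enumerated optima.

## CLI

```sh
# audit a deposited all-atom structure (trust its hydrogens)
clashaudit audit model.pdb --preset deposited-h --mode both --out reports/

# build + optimize hydrogens on a united-atom model, then audit
clashaudit audit model.pdb --preset build-h --seed 1 --tsv --out reports/

# cohort table over a manifest of paths (pooled per-100 statistics)
clashaudit batch manifest.txt --out cohort.json

# emit a synthetic test peptide from a YAML spec (sequence, torsions, seed)
clashaudit fixture spec.yaml --out fixture.pdb --with-hydrogens
```

Exit codes: 0 success, 1 usage, 2 parse failure, 3 audit failure.

## Data tables

`src/clashaudit/data/` holds the residue templates (bonds, hydrogens,
donor/acceptor roles, flip and planar groups), van der Waals radii (primary,
Bondi fallback, Richardson) and geometry targets as plain JSON; radii can be
overridden at run time with `--radii FILE` (two-column `element radius`
text).
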