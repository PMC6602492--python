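# nucdock

Rigid-body docking of nucleic-acid structures (RNA–RNA, DNA–DNA, DNA–RNA):
FFT-based global sampling of binding modes over an evenly distributed set of
rotations, hierarchical rescoring with a distance-dependent knowledge-based
atom-pair potential, optional binding-site / distance restraints,
ligand-RMSD clustering of the ranked modes, and interface-RMSD evaluation
against a native complex.

## Method overview

1. **Digitisation** — receptor and ligand are mapped onto regular 3D grids
   (default spacing 1.2 Å). Fully buried receptor cells ("core", all 26
   neighbours occupied) carry a negative penalty (−15); remaining cells get
   a kernel-smoothed surface value capped at 1. The ligand grid is a binary
   occupancy mask.
2. **Global sampling** — a deterministic rotation set at a 15° angular
   interval (4392 rotations: 183 spherical-lattice axis orientations × 24
   in-plane spins) is scanned; for each rotation all in-box translations are
   scored by FFT correlation, the top 10 translations are rescored with the
   pair potential, and the single best-scored translation is retained, so
   the pooled mode count equals the rotation count.
3. **Post-processing** — modes are restraint-filtered, ranked by energy and
   clustered greedily with a 5 Å ligand C4′-RMSD cutoff (no superposition,
   receptor frame); cluster representatives become the output models (up to
   100).
4. **Evaluation** — interface residues are taken from the native complex
   (any heavy atom within 10 Å of the partner); predicted models are
   superposed on the native over interface C4′ atoms of both partners and a
   model is a hit when the residual interface RMSD is below 5.0 Å.

The pair potential ships as a small default table derived from the built-in
synthetic fixtures via inverse-Boltzmann statistics plus an iterative
native-vs-decoy refinement; `derive-potential` can rebuild it from any set
of complexes.

Everything is testable offline: the `fixtures` module generates ideal
A-form duplex complexes, perturbed decoy poses with exact RMSD tags, and
analytically known toy grids.

## CLI

A single `nucdock` entry point with subcommands:

```sh
# deterministic rotation set (one 3x3 matrix per line, row-major)
nucdock rotations --angle 15 | wc -l          # 4392

# synthetic fixture data
nucdock fixtures duplex --seq GGGGCCCC --out duplex.pdb
nucdock fixtures decoys --seq GGGGCCCC --n 10 --translation 5 --out decoys/

# dock two structures (chains selectable from multi-chain files)
nucdock dock --receptor duplex.pdb --receptor-chains A \
             --ligand duplex.pdb --ligand-chains B \
             --out run/
# restraints: quoted "site <R|L> chain:seqid[,...]" / "dist a b max"
nucdock dock ... --site "R A:5,A:6" --dist "A:5 B:12 8.0" \
             --restraint-mode filter

# evaluate models against a native complex
nucdock eval --native duplex.pdb --models run/model_*.pdb \
             --receptor-chains A --ligand-chains B

# rebuild the pair-potential table
nucdock derive-potential --complexes complex1.pdb complex2.pdb --out table.txt
```

`dock` writes `model_<rank>.pdb` (receptor + posed ligand with REMARK 3
score lines), `scores.tsv` and a `manifest.json` with resolved config and
input digests. Config precedence per key: CLI flag > `--config` file
(`key = value` lines) > built-in default.

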