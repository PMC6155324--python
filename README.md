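# hotsite

Hot-spot prediction at protein–protein interfaces. An interface residue
is a *hot spot* when mutating it to alanine changes the binding free
energy by ΔΔG ≥ 2.0 kcal/mol; `hotsite` predicts these residues from a
complex structure.

Pipeline:

1. **Parse** a PDB complex with a two-sided chain partition
   (`hotsite.structure`).
2. **Describe** every residue with 102 named site features:
   physicochemical tables, pKa, PSSM + conservation entropy, BLOSUM62
   row, solvent accessibility / ΔASA / burial weights W(i) and W_FB,
   half-sphere exposure and residue depth, normalized contacts, pair
   potentials, secondary structure, disorder tracks, hydrogen bonds,
   Voronoi contacts, plus pluggable pre-computed columns
   (`hotsite.surface`, `hotsite.descriptors`).
3. **Expand** each feature over two structural neighborhoods — Euclidean
   (min heavy-atom distance ≤ 5 Å) and Voronoi (shared Delaunay
   tetrahedron) — in raw and W_FB-weighted form, yielding a 612-column
   table (`hotsite.neighbors`, `hotsite.assembly`).
4. **Select** features in two steps: mRMR ranking, then a greedy initial
   triple plus sequential forward selection under the composite
   criterion Rc = mean over repeated stratified 10-fold CV of
   (ACC + SEN + SPE + AUC) (`hotsite.selection`).
5. **Classify** with gradient boosting (2000 trees, depth 5, split gain
   0.005 by default) and report SPE/PRE/SEN/ACC/F1/MCC plus ROC and PR
   curves (`hotsite.model`).

`hotsite.fixtures` generates every test input programmatically: ideal
poly-alanine helix dimers with a tunable interface gap, PSSM / disorder
/ DSSP-style track files matching each reader, and labeled feature
matrices with planted class-shifted columns.

## CLI

```sh
# synthetic inputs
hotsite fixtures make-dimer  --seed 3 --gap 4.0 --out dimer.pdb
hotsite fixtures make-tracks --seed 3 --outdir tracks/

# features -> selection -> model -> evaluation
hotsite extract --pdb dimer.pdb --sides A:B --labels labels.tsv \
                --tracks-dir tracks/ --out features.tsv
hotsite select  --features features.tsv --top-m 50 --pool 500 \
                --repeats 5 --seed 0 --out selection.json
hotsite train   --features features.tsv --subset selection.json --out model.pkl
hotsite predict --model model.pkl --features features.tsv --out preds.tsv
hotsite evaluate --predictions preds.tsv --features features.tsv --out report.json
hotsite crossval --features features.tsv --folds 10 --out cv.json
```

Label files are TSV with columns
`pdb_id  partition  chain  resnum  icode  value`, where `value` is
either a ΔΔG in kcal/mol (hot spot iff ≥ 2.0) or a BID-style annotation
(hot spot iff `strong`). The partition flag `--sides A:C` takes
colon-separated chain groups, commas within a group.

## Notes

- The canonical site-feature list is fixed at 102 names (the source
  inventory's block counts sum to 102, not the nominal 100); the
  assembled table therefore has 6 × 102 = 612 columns.
- External predictors (PSI-BLAST, DSSP, DISOPRED/DisEMBL, HBPLUS) are
  consumed through file readers with synthetic generator counterparts;
  nothing is downloaded or executed at test time.
- Neighborhood aggregation is a sum including the central residue;
  weighted contexts sum each neighbor's own W_FB-scaled value. Both are
  switchable (`FeatureConfig.include_center`, `apply_weighting`).
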