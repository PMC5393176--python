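# rnassess

A toolkit for assessing predicted RNA 3D models against reference crystal
structures. Given one or more predicted models (PDB or mmCIF) and one or
more references, it computes a panel of complementary quality metrics,
ranks model sets, and exports report data:

- **RMSD** — all-common-heavy-atom root mean square deviation after one
  optimal (Kabsch) superposition; the primary ranking metric.
- **DI** — deformation index, RMSD divided by INF over all interactions.
- **INF** — interaction network fidelity (geometric mean of precision and
  recall of the model's interaction set), reported over all base pairs,
  Watson-Crick pairs only, non-Watson-Crick pairs only, and stacking only.
  Pairs and stacks are detected geometrically and classified by
  Leontis-Westhof edge (WC/Hoogsteen/Sugar) and cis/trans orientation.
- **DP** — per-nucleotide deformation profile matrix (superpose on each
  residue in turn, measure everything else), with min/max/mean aggregation
  over named structural modules from a YAML domain config.
- **MCQ** — circular mean of per-angle torsion differences
  (alpha..zeta + chi), in degrees.
- **Clash score** — steric overlaps >= 0.4 A per 1000 heavy atoms, a
  hydrogen-free approximation of probe-style clash scoring (documented
  differences: no hydrogen placement, fixed vdW radii; not expected to
  match MolProbity numerically).
- **B-factor profile** — per-residue mean reference B-factors, exported
  alongside DP heat-map data.
- **Radar ranks** — per-group relative ranks of first-submitted and
  best-RMSD models across all metrics.

A synthetic structure generator (ideal A-form duplexes with known pairs,
stacks and torsions, plus Gaussian-noise / hinge / torsion-shift
degradations) makes every metric testable fully offline.

## CLI

```bash
# full metric panel for one model, one or more references
rnassess compare --model model.pdb --reference ref1.pdb --reference ref2.pdb \
    --domains domains.yaml --out report.json --dp-matrix dp.tsv

# assess a directory of models and rank them (manifest: file/group/rank TSV)
rnassess rank --models-dir models/ --reference ref.pdb \
    --manifest groups.tsv --out summary.csv --radar radar.json

# base-pair/stack annotation and extended dot-bracket (pseudoknots in [])
rnassess annotate --structure model.pdb

# synthetic fixture generation
rnassess synth duplex --seq GGGGCCCC --seed 7 --noise 0.5 \
    --out fix.pdb --truth fix.json
```

Domain config schema (`domains.yaml`), chain:start-end inclusive in author
numbering:

```yaml
domains:
  P1: ["A:2-9", "A:80-87"]
  L2: ["A:10-15"]
```

The CSV summary has exactly the columns: model, group, submitted_rank,
reference, RMSD, DI_all, INF_all, INF_wc, INF_nwc, INF_stack, MCQ, Clash,
coverage. Undefined metrics print `NA`, never 0.

## Conventions

- Author numbering is preserved; insertion codes honored; first MODEL only;
  alternate locations resolved by highest occupancy.
- Residue mapping defaults to identifier matching (chain, number, icode)
  with automatic fallback to per-chain global sequence alignment
  (match +1, mismatch -1, gap -2) when identifier coverage drops below 0.8.
- Ligands, ions and proteins are parsed but excluded from RNA metrics;
  `--include-chains` adds protein chains to the mapping and RMSD.
- G-U wobbles count as Watson-Crick when cis WC/WC (the conventional INF_wc
  reading); `strict_watson_crick` in the annotation config excludes them.
- Annotation thresholds are conventional geometric values and live in
  `AnnotationConfig`, override any of them there.

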