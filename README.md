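# glycodiff

Site-specific N-glycosylation and protein-expression differential analysis
for graded tissue cohorts, starting from label-free quantification tables.

The package implements the post-acquisition portion of a combined
proteomics / glycoproteomics workflow:

- **Glycan model** (`glycodiff.glycans`) — parsing of compact composition
  strings (`N4H5S1F1`: N-acetylhexosamine, hexose, sialic acid, fucose
  counts), monoisotopic glycan and glycopeptide masses, composition-based
  classification (oligomannose / hybrid / complex / paucimannose) and
  branching/decoration features.
- **Glycopeptide pipeline** (`glycodiff.glyco`) — retention-time IQR
  outlier filtering, AUC floor (< 1000 dropped), glycopeptide and sample
  presence filters, quotient total-area normalization, log transform,
  per-glycosite degrees of fucosylation / sialylation / galactosylation,
  cohort descriptors, and per-feature differential statistics.
- **Proteomics pipeline** (`glycodiff.proteomics`) — 60 % group-presence
  filtering, down-shifted normal imputation (shift 1.8, width 0.3),
  two-group volcano statistics with fold-change classes, one-way ANOVA with
  Tukey HSD post-hoc, Spearman-distance clustering of significant proteins
  into up/down groups, grading-scheme correlation and row Z-scoring.
- **Statistics core** (`glycodiff.stats`) — pooled-variance t-test, one-way
  ANOVA, Tukey-Kramer HSD, Benjamini-Hochberg FDR, Pearson/Spearman
  correlation and correlation-distance hierarchical clustering.
- **Synthetic cohorts** (`glycodiff.simulate`) — a generator emulating the
  study design (95 samples: 46 Normal / 9 G1 / 16 G2 / 24 G3 with a Gleason
  relabeling; 653 proteins with intensity-dependent missingness; 145
  glycopeptides over 29 glycosites of 22 glycoproteins with 53 glycans) with
  configurable spiked protein fold changes and site-metric targets, plus the
  ground truth needed for recovery tests.

## Command line

```sh
# write a synthetic cohort (three TSVs + ground-truth JSON)
glycodiff simulate --preset paper-like --seed 1 --out cohort/

# check the inputs
glycodiff validate cohort/

# run both analysis arms
glycodiff run cohort/ --scheme pathological --seed 1 --out results/
```

`results/` contains the volcano table, ANOVA/Tukey tables, cluster
assignments, Z-scored heatmap matrix, grade-scheme correlations, the
filtered/normalized glycopeptide matrix, site metric tables, dataset
descriptors, differential results and a provenance JSON with every filter
count and setting. Presets: `paper-like`, `null`, `minimal`.

## Input formats

- `glycopeptides.tsv` — long table: `sample_id, protein, glycosite, glycan,
  rt, auc`.
- `proteins.tsv` — wide log2 intensity matrix, first column `protein`,
  remaining columns sample ids, empty cell = missing.
- `metadata.tsv` — `sample_id, grade (Normal|G1|G2|G3), gleason
  (NA|GG2|GG3|GG4|GG5)`.

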