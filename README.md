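# habprof

Habitat-preference profiling and comparative-genomic variance partitioning
for microbial lineages, driven by habitat-labeled metagenomic detection
tables and per-genome annotation-count tables (real or synthetic).

## What it does

- **taxonomy** — parses GTDB-style ranked lineage strings
  (`d__...;p__...;c__...;o__...;f__...;g__...`) and aggregates detection
  tables to class / order / family resolution.
- **synthetic_data** — seeded simulators for detection tables (per-habitat
  detection probabilities, log-normal abundances) and genome tables
  (class + habitat + interaction effects, binary traits, life-history
  archetypes), each with a ground-truth record.
- **ecoprofile** — ubiquity (% of a habitat's datasets with a detection),
  soil:non-soil preference and abundance ratios, and SPL / NSPL /
  intermediate / rare calls (host-associated datasets excluded from
  comparisons by default; thresholds 75% ubiquity, ratio 4, abundance
  ratio 1, rare cutoff 4%).
- **nicherange** — habitat-breadth records from detections or genome
  provenance and generalist / specialist / indeterminate calls with
  evidence cutoffs (250 studies or 5 genomes by default).
- **varpart** — two-way sequential-SS (Type-I) ANOVA of lineage, habitat,
  and their interaction on continuous genome features and 0/1 trait
  matrices; % contribution including the residual share; p < 1e-5
  significance screen; Tukey–Kramer HSD post hoc comparisons;
  within-lineage soil vs non-soil tests.
- **lifehistory** — regulatory-flexibility (TF / total genes) and
  resource-acquisition ((secreted CAZymes + proteases + lipases + BGCs) /
  transporters) indices, and nearest-centroid Scarcity / Ruderal /
  Competitor calls trained on a labeled reference set (the packaged
  default training set is a synthetic stand-in).

## CLI

```sh
habprof simulate   --out run/ --seed 3 --datasets-per-habitat 500
habprof ecoprofile --detections run/detections.tsv --census run/census.tsv \
                   --rank class --out run/
habprof nicherange --genomes run/genomes.tsv --rank class --out run/
habprof varpart    --genomes run/genomes.tsv --out run/
habprof lifehistory --genomes run/genomes.tsv --training run/training.tsv --out run/
habprof report     --out run/
```

Every stage writes TSV outputs plus a `manifest_<stage>.json` recording
inputs, thresholds, seed, package versions, and exclusion counts; outputs
are byte-identical for identical inputs and seed.

Input schemas (TSV, header row, UTF-8):

- detections: `dataset_id  habitat  lineage  relative_abundance_pct`
- census: `habitat  n_datasets`
- genomes: `genome_id  lineage  habitat  <feature columns>`
- training: `id  regulatory_flexibility  resource_acquisition  label`

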