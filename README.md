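# tetramap

Linkage mapping and genetic-map-based scaffolding for autotetraploid F1
populations, built around SNP-array dosage data (integer 0–4 calls).

The package covers the full path from raw dosage matrices to a
chromosome-scale pseudomolecule layout:

- **`tetramap.simdata`** — simulation of autotetraploid parents, gametes
  (polysomic bivalent pairing, a simplified quadrivalent branch with
  explicit double-reduction events, configurable crossover landscape)
  and F1 dosage matrices with genotyping error and missingness. Every
  meiotic event is recorded, so all downstream estimators can be
  validated by truth recovery.
- **`tetramap.tetrapoint`** — exact two-locus gamete probabilities by
  enumeration of bivalent pairings, maximum-likelihood two-point
  recombination/LOD estimation with phase selection, a double-reduction
  estimator (4 × dosage-2 frequency at simplex × nulliplex markers, with
  a Clopper–Pearson interval), a preferential-pairing chi-square test,
  and a vectorized all-pairs estimator.
- **`tetramap.mapbuild`** — missingness filtering, duplicate-individual
  merging, duplicate-marker binning, LOD-ladder linkage-group
  clustering, coupling-phase homologue assignment with simplex × simplex
  cross-parent bridging, and marker ordering (1-D weighted
  least-squares embedding with composite-likelihood refinement and
  iterative removal of ill-fitting markers; Haldane map function).
- **`tetramap.mapmerge`** — LOD²-weighted merging of two populations'
  pairwise linkage data and consensus-map integration (single-source
  chromosomes are carried over unchanged).
- **`tetramap.anchor`** — marker-alignment filtering (coverage ≥ 0.98,
  identity ≥ 0.95, unique mapping, per-contig probe cap), contig
  placement by majority vote / mean cM / rank-correlation orientation,
  pseudomolecule construction (AGP v2.1 + FASTA, 100-N junctions),
  Marey-map landscape statistics (Spearman ρ, central-tertile fraction
  with proximal/distal classification), and marker-based synteny
  comparison (inversion runs, translocation candidates).
- **`tetramap.asmstats`** — N50/L50/GC assembly statistics, BUSCO
  full-table summaries, a duplication-minimizing contig purge (greedy
  max-coverage with an exact minimum-cover check on small instances),
  and the coverage-peak genome-size estimator.
- **`tetramap.io` / `tetramap.cli` / `tetramap.pipeline`** — TSV/FASTA/
  AGP/JSON/YAML formats, a click-based CLI, and an end-to-end pipeline.

## CLI

```bash
tetramap simulate --seed 1 --n-offspring 187 --out dosage.tsv
tetramap twopoint --dosage dosage.tsv --out pairwise.tsv
tetramap buildmap --dosage dosage.tsv --out map.tsv --expected-groups 8
tetramap mergemap --pairwise1 p1.tsv --pairwise2 p2.tsv \
                  --map1 map1.tsv --map2 map2.tsv --out consensus.tsv
tetramap anchor --map consensus.tsv --alignments aln.tsv \
                --contigs contigs.fasta --out-prefix chrom
tetramap marey --map consensus.tsv --agp chrom.agp --alignments aln.tsv \
               --out landscape.tsv
tetramap purge --busco-table full_table.tsv --contigs contigs.fasta \
               --out purge.json
tetramap stats --contigs contigs.fasta
tetramap pipeline --config config.yaml --outdir out --seed 1
```

`tetramap pipeline` runs simulate → twopoint → buildmap → mergemap →
contigs → anchor → marey → stats on synthetic data and is deterministic
under a fixed seed; see `tetramap.pipeline.PipelineConfig` for the YAML
schema (unknown keys are rejected).

## Notes

- Dosage TSVs use rows = markers, `maternal`/`paternal` columns followed
  by one column per individual, `NA` for missing.
- Estimation assumes bivalent-only polysomic inheritance; double
  reduction is quantified separately from telomeric simplex markers.
- Percentages are formatted to one decimal with ties rounded away from
  zero.
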