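# ssrforge

A toolkit for developing SSR (microsatellite) markers from genome
assemblies: genome-wide detection of high-repeat-number perfect
microsatellites, single-copy filtering by the five-fold top-score rule,
cross-assembly length-polymorphism calling via flank anchoring, constrained
primer-pair design, marker statistics (allele counts, PIC,
transferability), Nei-DA/neighbor-joining trees, and physical-map tables.
A seeded synthetic-data module generates genomes with planted SSRs, mutated
alternate genotypes and genotype matrices, so the whole pipeline is
testable without any external data.

## Pipeline stages

| stage  | operation                                                   | module                |
|--------|-------------------------------------------------------------|-----------------------|
| scan   | perfect-tandem-repeat detection, motif families, summaries  | `ssr_scan`            |
| unique | five-fold single-copy rule on alignment hit tables          | `uniqueness`          |
| compare| flank anchoring + tract re-measurement across assemblies    | `polymorphism_compare`|
| design | constrained, deterministic primer-pair selection            | `primer_design`       |
| stats  | allele frequencies, PIC, transferability                    | `genotype_stats`      |
| tree   | Nei (1983) DA distances, neighbor joining, Newick           | `diversity_tree`      |
| map    | marker ordering and neighbor gaps in Kb                     | `physical_map`        |
| sim    | planted-truth genomes, genotypes and matrices               | `synthetic_data`      |

Default scan thresholds (minimum repeat counts): Mono 20, Di 8, Tri 8,
Tetra 8, Penta 6, Hexa 6, with per-sequence overrides (e.g. `chr6:Di=5`).
Motif families group cyclic rotations on the same strand (AG ≡ GA) without
merging reverse complements. Coordinates are 1-based inclusive everywhere.

## CLI

```bash
ssrforge scan  --fasta ref.fasta --out loci.tsv [--gff3 loci.gff3] \
               [--threshold Di=8] [--override chr6:Di=5] [--flank 200]
ssrforge unique --loci loci.tsv (--hits blast.tsv | --fasta ref.fasta) \
               [--fold 5] --out single.tsv
ssrforge compare --loci single.tsv --ref ref.fasta --alt DQJ=dqj.fasta \
               [--alt N10=n10.fasta] [--min-diff 1] --out comparisons.tsv
ssrforge design --loci single.tsv --ref ref.fasta [--product 100:300] --out primers.tsv
ssrforge stats --genotypes geno.csv --out stats
ssrforge tree  --genotypes geno.csv --out-newick tree.nwk [--out-dist d.tsv]
ssrforge map   --markers single.tsv --out map.tsv
ssrforge simulate --seed 1 --length 10000 --plant seq1:500:AT:10 --out sim
ssrforge all   --config run.cfg
```

`run.cfg` is a flat key=value file (`reference=…`, `alt.NAME=…`,
`threshold.CLASS=…`, `override.SEQ.CLASS=…`, `fold=…`, `output_dir=…`);
unknown keys are rejected and the resolved config is written next to the
outputs. Exit codes: 0 ok, 1 user error, 2 internal error.

External hit tables use the standard 12-column tabular alignment format
(query, subject, %identity, length, mismatches, gap opens, qstart, qend,
sstart, send, evalue, bitscore). Genotype CSVs have a header row of
accession ids, an optional `group` row of group labels, then one row per
marker; cells are an amplicon size, `a/b` for heterozygotes, or `-` for
missing.

## Notes on method choices

- Primer melting temperatures use the Wallace rule (2·(A+T)+4·(G+C)) so
  every designed pair is exactly reproducible; this deviates from
  thermodynamic nearest-neighbor models on purpose.
- The built-in aligner is a deliberately simple exact-seed (k=15) ungapped
  extender for desk-scale self-contained runs; external tabular hit files
  are the production path for single-copy filtering.
- Neighbor joining breaks Q-criterion ties by smallest index pair and
  clamps negative branch lengths to zero, making trees reproducible.
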