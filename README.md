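# panelgraph

Analysis toolkit for inbred-panel pangenome graphs and epigenomes:

- **graph_model** — parse and validate rGFA (GFA1 with SN/SO/SR tags), assign
  every segment to an origin assembly via a configurable stable-name-prefix
  map, per-origin summary statistics (count, total/median length, longest,
  N50), unit-cost global-alignment identity, BED export on stable coordinates.
- **coverage** — per-sample length-normalised segment depths and junction
  traversal counts from GAF alignments, usage calls at configurable
  thresholds (fraction of the length-weighted mean reference depth),
  origin-class base fractions and cross-sample usage strata.
- **sv_graph** — bounded, deterministic bubble enumeration; divergent
  alternative-path calling (cumulative length > 10 kb, member divergence
  > 0.5, DNA support in ≥ 2 samples at 50 % of reference depth, RNA support
  in ≥ 8 samples at 10 %, ≥ 1 exon overlapped); large-scale deletion calling
  from junctions joining distant reference segments (gap > 10 kb, junction
  count ≥ 50 % of reference depth in at least half the panel, ≥ 1 fully
  skipped exon); a relaxed 1 kb scan without the exon criterion.
- **core_genes** — GFF3 loading with cross-transcript CDS merging;
  core / fragmented / absent classification from the fraction of coding-exon
  bases inside reference segments used by every sample (> 0.95 / = 0 / rest).
- **sv_annotation** — pLI log10-odds scoring of SVs over overlapping genes
  (clamped so pLI ∈ {0, 1} stays finite), per-type repeat-overlap fractions,
  reciprocal-overlap merging of per-sample call sets into distinct SVs with
  carrier sets, total/singleton counts.
- **meth_diff** — per-read CpG LLR aggregation to site medians,
  Kruskal-Wallis tests across samples per CpG island, Benjamini-Hochberg
  FDR, per-sample methylation states with a ±1 LLR ambiguity band,
  TSS-distance summaries and the clustering matrix for DMR heatmaps.
- **synthetic_data** — seed-deterministic generators for every input
  (rGFA with planted alternative paths/deletions plus labelled decoys, GAF
  reads at Poisson depth, GFF3, islands/repeats BED, pLI tables, per-sample
  SV call sets, two-component LLR mixtures with planted DMRs and sibling
  structure) with full ground truth.
- **pipeline** — end-to-end orchestration with stage isolation, provenance
  and byte-deterministic outputs.

## CLI

```sh
panelgraph simulate --seed 1 --out simdir/            # synthetic bundle + truth.json
panelgraph graph stats --rgfa simdir/graph.gfa
panelgraph coverage --rgfa simdir/graph.gfa --gaf simdir/gaf/S01.dna.gaf \
    --sample S01 --theta 0.05
panelgraph sv graph --rgfa simdir/graph.gfa --dna-gaf-dir simdir/gaf \
    --rna-gaf-dir simdir/gaf --gff simdir/genes.gff3 \
    --divergences simdir/divergences.tsv
panelgraph core-genes --rgfa simdir/graph.gfa \
    --usage simdir/usage_theta0.05.tsv --gff simdir/genes.gff3
panelgraph meth --calls-dir calls/ --islands cgi.bed --gff genes.gff3 --alpha 0.01
panelgraph run --out rundir/ --seed 1                 # full pipeline
```

`panelgraph run` accepts a YAML config (`--config run.yaml`) exposing every
threshold (θ, lengths, support counts, FDR α, aggregation minima, merge
parameters); all values are recorded in `provenance.json`.

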