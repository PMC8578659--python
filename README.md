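# hicarch

Cis Hi-C chromatin-architecture statistics with a planted-structure
simulator, so every statistic ships with parameter-recovery tests that need
no external data.

What it computes, per single-chromosome contact matrix:

- **Matrix transforms** (`hicarch.matrix`): exact read-pair downsampling
  (multivariate hypergeometric), matrix balancing to equal row sums,
  observed/expected by per-diagonal means, Pearson-correlation matrices.
- **Compartments** (`hicarch.compartments`): PC1 profile of the correlation
  matrix, GC-content sign orientation, five-quintile saddle maps, and the
  compartment strength ln((AA·BB)/AB²) with a per-pixel bootstrap.
- **Insulation** (`hicarch.insulation`): sliding-window insulation score
  normalized to the nearest 50 bins, boundary calls, and strand-oriented
  element-centred aggregate maps (optionally row z-scored).
- **Domain/loop pileups** (`hicarch.aggregates`): 3L-windowed domain
  aggregates rescaled to 90×90 with the within/between strength ratio; loop
  aggregates (310 kb windows at 10 kb bins) and offset-normalized loop
  strength.
- **Region enrichment** (`hicarch.enrichment`): contact values within a
  region set or between a focal locus and a set, tested against N random
  region sets of matched length multiset (Mann–Whitney U per replicate,
  p-values averaged); correlation differences and contact log2 fold changes
  between conditions.
- **Stage specificity** (`hicarch.stages`): entropy-based specificity
  scores, K-means staging clusters C1..Ck, per-cluster expression-shift
  tests.
- **Simulator** (`hicarch.simulate`): power-law decay contact maps with
  planted compartments, domains, loops, a high-contact hub and a focal
  locus, Poisson counts; stage-patterned expression with planted clusters
  and treatment shifts. Ground truth is returned alongside.

## CLI

Every subcommand writes its output plus a `*.provenance.json` record; all
stochastic stages require an explicit `--seed`.

```bash
# simulate -> balance -> O/E -> correlation -> PC1 -> saddle/strength
hicarch simulate --n-bins 300 --compartment-contrast 1.8 --seed 1 --out-prefix sim
hicarch balance sim.matrix.txt --out bal.tsv
hicarch oe bal.tsv --out oe.tsv
hicarch pcc oe.tsv --out pcc.tsv
hicarch pc1 pcc.tsv --gc sim.gc.bedgraph --out pc1.bedgraph
hicarch saddle oe.tsv pc1.bedgraph --n-boot 100 --seed 1 --out saddle.json

# insulation, pileups, enrichment, expression staging
hicarch insulation oe.tsv --out-prefix ins
hicarch tad-agg oe.tsv tads.bed --out tadagg.tsv
hicarch loop-strength oe10.tsv loops.bedpe --out loops.json
hicarch pnh-enrich oe.tsv hub.bed --seed 1 --out enrich.json
hicarch stage-score expr.tsv --out scores.tsv
hicarch stage-cluster expr.tsv --seed 1 --out clusters.tsv
```

Matrix text formats: whitespace triplets (`bin_i bin_j value`, upper
triangle sufficient) or dense TSV; both carry their genomic frame in
`# key=value` header lines. Region sets are BED3/BED6, loops BEDPE, tracks
bedGraph, expression a genes × stages TSV.

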