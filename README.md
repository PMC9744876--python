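# xenomet

Analysis toolkit for xenograft metastasis studies that sequence intact
graft+host tissue and follow tumor burden in live animals. It covers the
bespoke computations such studies need between the standard upstream
tools (aligners, callers, DE fitting) and the figures:

- **`xenomet.xenofilter`** — estimate per-gene cross-species mapping
  propensities from species-pure control libraries and exclude genes
  whose predicted cross-mapped reads exceed 10% of observed reads in
  xenograft samples.
- **`xenomet.normalize`** — median-of-ratios size factors, a
  log2-based variance-stabilizing transform stand-in, and RPKM.
- **`xenomet.signature`** — gene-signature scoring for bulk samples
  (mean of median-centered values) and single cells (per-cell mean),
  median high/low stratification, and Welch group comparison.
- **`xenomet.enrich`** — sign(log2FC)×1/adjP rank statistic, the classic
  (unweighted) running-sum enrichment score with a seeded gene-set
  permutation p-value, and hypergeometric over-representation on a
  −log10(p) scale.
- **`xenomet.variants`** — two-stage somatic variant filtering: damaging
  call quality gates, then a paired control-vs-resistant persistence
  filter (depth, allele support, NRAF level and shift, presence in all
  late in-vivo replicates) with an RPKM expression gate.
- **`xenomet.endpoints`** — tumor-burden endpoints (waterfall percent
  change, normalized curves, trapezoidal AUC, progression at 2× the
  pre-treatment baseline, resistance at 10× the post-treatment nadir,
  persistence-based incidence calls, caliper tumor volume) and the
  accompanying statistics (exact-when-feasible Mann–Whitney,
  Kaplan–Meier, log-rank).
- **`xenomet.synthdata`** — seeded generators for every input above with
  planted ground truth, used throughout the test suite for
  parameter-recovery checks.

## CLI

All stages are exposed under a single `xenomet` entry point:

```sh
# synthetic inputs with planted ground truth
xenomet simulate --seed 1 --out-dir sim/

# cross-species contamination filter
xenomet xenofilter --counts sim/counts.tsv --genes sim/genes.tsv \
    --samples sim/samples.tsv --threshold 0.10 --aggregate mean \
    --out-counts filtered.tsv --out-report report.tsv

# signature scoring + median stratification
xenomet score --matrix filtered.tsv --signature signature.txt \
    --mode bulk --out scores.tsv

# enrichment of gene sets against a DE table
xenomet enrich --de-table de.tsv --gmt sets.gmt --n-perm 1000 \
    --seed 1 --out enrichment.tsv

# two-stage variant filter
xenomet variants --table sim/variants.tsv --rpkm sim/rpkm.tsv \
    --preset dominant --out-survivors survivors.tsv --out-tally tally.tsv

# per-animal endpoint calls
xenomet endpoints --burden sim/burden.tsv --treatment-start 9 \
    --mode resistance --out calls.tsv
```

File formats are plain text: count matrices as TSV (or MatrixMarket with
sidecar index files), gene annotation TSV (`gene_id, species,
length_bp`), sample sheets (`sample_id, class`), signature lists (one
gene id per line), gene sets in GMT, variant tables as one-row-per-variant
TSV with `_C2D`/`_R2D` paired-sample suffixes, and long-format burden
tables (`animal_id, compartment, day, burden`).

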