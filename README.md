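# editrace

CRISPR–Cas9 RNP amplicon editing outcomes, from raw reads to repair
kinetics: a tested, reusable pipeline plus a calibrated repair-race
simulator so every stage can be exercised offline.

Stages:

1. **read_processing** — merge 150-bp paired-end reads into full amplicon
   fragments (overlap search, quality-aware conflict resolution) and
   demultiplex by 5' inline barcode.
2. **indel_calling** — global affine alignment against the reference
   amplicon, left-aligned edit-op extraction, a ±50 nt cut-site window
   that discards distal artifacts, and count/frequency filters that
   suppress sequencing-error alleles.
3. **repair_classification** — NHEJ / MMEJ / HDR assignment: MMEJ by
   2–16 nt junction microhomology (computed on the deletion's full
   placement-equivalence class) or the 1-nt G|G / C|C rule at the cut;
   HDR by exact donor insert with clean flanks; NHEJ as the catch-all.
   Binning schemes: `seven_group`, `eleven_cat`, `t50_bins`,
   `competition_bins`.
4. **kinetics** — T₅₀ (time to half-maximal frequency) per editing
   pattern from 4/8/12/24/48 h time courses: bounded least-squares fit of
   `f(t) = F_max·(1 − 2^(−t/T50))` with an interpolation fallback, plus
   eligibility rules (peak > 1% absolute, > 2% of total indels).
5. **pattern_stats** — top-5 Gini dispersion, relative frequencies,
   donor-present vs donor-absent competition deltas with paired t
   statistics, Pearson r², and import/concordance for external
   prediction tables.
6. **synthetic_data** — random amplicons with plantable microhomologies,
   a per-locus outcome-propensity model (−4-base-dependent +1 insertion
   bias, microhomology-kernel deletions, optional HDR channel), a
   stochastic repair race with class-specific shifted-exponential
   kinetics, and paired-FASTQ read generation with substitution errors.

## CLI

Every stage is runnable standalone on the previous stage's text outputs
(TSV/FASTQ), or everything at once from a YAML config:

```bash
editrace simulate --seed 3 --outdir sim --loci 2 --depth 5000 --timepoints 48
editrace merge    --r1 sim/locus000_t48h_R1.fastq --r2 sim/locus000_t48h_R2.fastq --out merged.fastq
editrace demux    --reads merged.fastq --barcodes sim/barcodes.tsv --outdir demuxed
editrace call     --reads demuxed/locus000.fastq --fasta sim/amplicons.fasta \
                  --sidecar sim/amplicons.tsv --amplicon-id locus000 --out alleles.tsv
editrace classify --alleles alleles.tsv --fasta sim/amplicons.fasta \
                  --sidecar sim/amplicons.tsv --out classified.tsv
editrace stats    --alleles classified.tsv --gini
editrace run      --config pipeline.yaml --outdir bundle   # all stages at once
editrace report   --bundle bundle
```

Exit codes: 0 success, 2 configuration/schema error, 3 data error.
A `run` config looks like:

```yaml
seed: 11
loci:
  - id: demoA
    minus4: T
    planted_microhomologies: [[3, 4], [4, 12]]
    # donor_insert: TCGATAAG        # optional HDR channel
simulation:
  cell_profile: iPSC                # iPSC | T | K562 | U937
  depth: 5000
  timepoints: [4, 8, 12, 24, 48]
calling:
  window: 50
  min_count: 2
  min_freq: 0.0005
```

## Conventions

Coordinates are 0-based half-open; the cut site is an inter-base index;
reported bases (insertions, the −4 base) are given in protospacer-strand
orientation regardless of the stored strand. Allele signatures are
CIGAR-like strings (`D4@103;I1@110:T`) with left-aligned indels. All
tables are TSV with a `# config=<hash>` provenance comment.
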