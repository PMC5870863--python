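# scnabench

Simulate targeted-capture tumor sequencing cohorts with a known
copy-number truth set, and benchmark somatic copy-number alteration (SCNA)
callers against it.

The package covers the full loop:

1. **Genome construction** (`scnabench.genome_forge`) — build a toy reference
   (or load a FASTA), sample a synthetic variant catalog (germline SNVs,
   indels and CNVs; somatic SNVs, indels, focal and arm-length SCNAs), and
   implant it into diploid haplotype genomes. Amplifications are tandem
   duplications; every haplotype carries a liftover map back to reference
   coordinates, and the truth table is exported as a BED-like TSV.
2. **Capture-aware read simulation** (`scnabench.capture_sim`) — random
   shearing, in-silico probe capture against padded targets with a
   GC-dependent retention weight, and paired-end FASTQ emission with a
   substitution error model. Read names carry truth tags so downstream depth
   analysis needs no alignment.
3. **Subclonal mixing and admixture** (`scnabench.clonal_mixer`) — a tumor
   read pool drawn from five clone pools at fixed proportions (default
   0.27/0.29/0.36/0.06/0.02), an admixture series replacing 0–90% of tumor
   reads with control reads at constant depth, and expected allele fractions
   per variant and admixture level.
4. **Evaluation** (`scnabench.scna_eval`) — nucleotide-, interval- and
   gene-based precision/sensitivity (inclusive 80% overlap threshold, typed
   amp/del matching, union-based denominators), allele-fraction and
   size-class stratification, and gene-count log-ratio concordance.
5. **Harness** (`scnabench.bench_harness`) — cohort orchestration, a naive
   depth-ratio caller for self-contained end-to-end runs, aggregation tables
   and fixture generation.

## CLI

```sh
# full five-replicate, ten-level cohort on the built-in toy reference
scnabench simulate --preset paper --seed 1 --out cohort/

# CI-scale cohort (2 replicates x 3 levels, with reads)
scnabench simulate --preset mini --seed 1 --out mini/

# custom design
scnabench simulate --config design.yaml --out cohort/

# naive depth-ratio caller on one sample
scnabench call --tumor-r1 mini/samples/rep1_a0.0_tumor_R1.fastq.gz \
    --control-r1 mini/samples/rep1_a0.0_control_R1.fastq.gz \
    --targets mini/targets.bed --out calls.bed

# score a call set (any BED-like "chrom start end type" file or SEG file)
scnabench evaluate --gold mini/truth_rep1.bed --calls calls.bed \
    --targets mini/targets.bed --genes mini/genes.bed --out report.tsv

# aggregate several reports
scnabench report --reports report.tsv --by approach --out summary.tsv
```

Exit codes: 0 success, 2 configuration error, 3 data error.

## File formats

- Truth tables: TSV with header
  `#chrom start end type zygosity clone_ids origin arm_flag`
  (0-based half-open, type `amp`/`del`).
- Call sets: 4+ column BED-like TSV (`chrom start end type`) or SEG
  (1-based inclusive; sign of the mean log-ratio gives the type).
- Targets: 3-column BED; genes: 4-column BED with unique names.
- Reads: gzip FASTQ pairs with truth-tagged names
  (`sample|index|chrom|hap|start|end|r1spans|r2spans`).
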