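# dhdup

Detection of collapsed gene duplicates and splice-candidate components in
doubled-haploid transcriptome assemblies.

## The problem

A doubled-haploid (DH) individual — derived by duplicating a single haploid
genome, e.g. through gynogenesis in fish — is fully homozygous. In reads
mapped back to its de novo transcriptome assembly, a position where reads
disagree therefore cannot be a true allelic SNP. The remaining explanation
is that two recently duplicated gene copies were so similar that the
assembler collapsed them into one "unigene": their fixed differences —
**paralogous sequence variants (PSVs)**, or **multisite variants (MSVs)**
when three or more alleles are involved — then surface as
heterozygous-looking pileup columns. Screening a DH transcriptome for such
sites is a cheap, assembly-only way to flag putative duplicated genes.

`dhdup` implements that screen as a tested pipeline, plus the companion
analysis of assembly **components**: Trinity's Chrysalis stage groups
sequences that share read overlap into components (`comp<N>_c<M>`), so a
component with two or more member sequences (`_seq1`, `_seq2`, …) is a
candidate alternative-splicing locus. The package locates the exact
difference blocks between members so a validation assay can span them.

Because suitable public read sets at desk scale do not exist for this
design, the package ships a first-class synthetic-data generator: a
homozygous transcriptome in which a known fraction of unigenes are
collapsed duplicate pairs with planted PSVs, a known fraction carry
exon-skip isoform pairs, and 90-bp paired-end reads with configurable
substitution error. Every planted feature is recorded in a machine-readable
truth table, so recovery can be measured exactly.

## The method

1. **QC** — reads are trimmed to the longest contiguous segment in which
   every base has Phred quality ≥ Q (DynamicTrim-style), then kept if
   longer than 25 bp. Two regimes: assembly-grade (Q ≥ 13) and the
   stricter mapping-grade re-trim (Q ≥ 20) used before duplicate detection.
2. **Mapping** — QC-passed reads are placed on unigenes by seed-and-extend
   (exact k-mer seeds, semi-global alignment via edlib) under a ≥ 99%
   identity contract; reads tying across unigenes are discarded.
3. **Duplicate scan** — per-position allele counts over quality-passing
   read bases; a site is called when all three conditions hold:
   depth ≥ 4 reads, a non-major allele supported by ≥ 2 reads, and minor
   allele frequency ≥ 10%. Sites are classed PSV (2 alleles) or MSV (≥ 3);
   unigenes with ≥ 1 site are flagged as putative duplicates and summarised
   in a 1–5/">5" sites-per-unigene histogram.
4. **Splice candidates** — components with ≥ 2 sequences are extracted;
   member pairs are globally aligned with affine gaps and maximal
   non-identity runs become difference blocks with exactly-matching flank
   windows for assay design.

## Worked example

A full synthetic run from one config — `example.yaml`:

```yaml
sim:
  n_genes: 30
  dup_fraction: 0.2        # 6 genes are collapsed duplicate pairs
  psv_per_dup: [1, 4]      # each carrying 1-4 planted variant sites
  isoform_fraction: 0.1    # 3 genes emit an exon-skip isoform pair
  exon_count_range: [4, 6]
  exon_len_range: [180, 300]
  mean_coverage: 40.0
  error_rate: 0.001
  seed: 0
```

```bash
dhdup run --config example.yaml --out demo --seed 5
```

prints the stage ledger

```
simulate: ok (in=30, out=16058) 33 unigene records
qc: ok (in=16058, out=16058)
map: ok (in=16058, out=13980) mapped 0.871, ambiguous 1970
dupscan: ok (in=13980, out=13) 6 unigenes flagged
splice: ok (in=33, out=3) 3 difference blocks
evaluate: ok (in=13, out=1)
```

— 30 genes expanded to 33 records by isoform pairs; flat Q30 qualities pass
the Q20 re-trim untouched; ~13% of reads are discarded as ambiguous because
they fall in exons shared by two isoforms of the same component; 13 PSV/MSV
sites are called in 6 unigenes. The call table (`calls.tsv`):

```
unigene_id     pos0  ref_base  major_allele  variant_alleles  depth  maf     site_class
comp3_c0_seq1  430   A         A             T:16             43     0.3721  PSV
comp3_c0_seq1  566   C         C             G:22             50     0.4400  PSV
```

Each row is one heterozygous-looking column: at position 430 of
`comp3_c0_seq1`, 16 of 43 reads carry `T` where the assembly says `A` —
with equal expression of two collapsed copies the expected minor-allele
fraction is 0.5. `metrics.tsv` scores calls against the simulator's truth
table (here all four of site/unigene sensitivity/precision are 1.0000), and
`dup_histogram.tsv` bins flagged unigenes by site count. Calls are also
written as a minimal VCF (`calls.vcf`), and `manifest.json` records the
resolved config, per-stage counts and output checksums — two runs with the
same seed are byte-identical.

Each stage is also available separately (`dhdup simulate`, `dhdup qc`,
`dhdup map`, `dhdup dupscan`, `dhdup splice`), reading and writing
FASTA/FASTQ/TSV/SAM/VCF, and everything is importable from Python
(`dhdup.scenarios.run_in_memory` runs the whole chain without touching
disk).

## Limitations

The simulator plants substitution PSVs only (no indel PSVs), spaces them
at least one read length apart, and uses flat quality strings; the scan
does not attempt copy-number estimation and, by the DH premise, makes no
attempt to separate PSVs from allelic SNPs in heterozygous material. See
`docs/methods.md` for the full model description and design rationale.
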