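# Methods

This note documents the models, thresholds and design choices behind
`dhdup`, in the order data flows through the pipeline.

## Rationale

In a doubled-haploid individual every locus is homozygous, so a read
pileup over a correctly assembled unigene should be monomorphic apart
from sequencing error. A column with substantial support for two (or
more) alleles is evidence that the unigene is a *collapsed duplicate*:
two paralogous gene copies merged by the assembler, whose fixed
differences (PSVs/MSVs) masquerade as heterozygous sites. The pipeline
makes this inference operational with explicit, conservative thresholds.

## Synthetic data generator (`dhdup.synth`)

**What it emulates.** A homozygous transcriptome of `n_genes` genes,
each a concatenation of `exon_count_range` exons of `exon_len_range` bp
of uniform random sequence. A quota of exactly
`round(dup_fraction * n_genes)` genes (selected by seeded permutation)
is emitted as collapsed duplicates: one reference sequence plus a
hidden second haplotype differing at `psv_per_dup` planted substitution
sites; the two copies are expressed at `dup_expression_ratio` (default
1:1). A disjoint quota of `round(isoform_fraction * n_genes)` genes
emits an exon-skip isoform pair (`_seq1` full, `_seq2` missing one
internal exon) under a shared `comp<N>_c0` component id. Reads are
90-bp paired-end from uniformly placed fragments
(`round(coverage * L / (2 * read_len))` pairs per record), with uniform
substitution errors at `error_rate` and flat Phred qualities at
`quality_level` (optionally a degraded 3' tail for trimmer exercises).
All randomness derives from one integer seed; identical seed and config
reproduce byte-identical FASTA/FASTQ.

**Planted-site placement.** Sites are placed at least `min_psv_spacing`
(default one read length) apart and at least `psv_end_margin` (default
one read length) from the sequence ends. Both choices make each planted
site's read evidence independent: a 90-bp read then spans at most one
variant site, and no site sits in the coverage ramp at a transcript
end. Real PSVs are not constrained this way — tandem variants closer
than a read length interact with the identity filter (a read spanning
two of them carries two mismatches and is discarded), and near-terminal
sites suffer reduced depth. Passing recovery tests on these fixtures
therefore demonstrates correctness of the filter logic under its
stated conditions, not sensitivity to tightly clustered or terminal
variants; that blind spot is intrinsic to the method, not to the
simulator.

**Deliberate non-realism.** No indel differences between copies, no
expression dispersion (read counts are deterministic per record), no
position-dependent error profile, no quality-score realism beyond
flat+tail, no alternative 5'/3' splice sites or intron retention. These
keep every test interpretable against a closed-form expectation.

## Quality control (`dhdup.qc`)

Trimming keeps the longest contiguous run of bases with quality at or
above the threshold — leftmost on ties — rather than discarding whole
reads; this is the DynamicTrim behaviour, and is consistent with a
retained-read length distribution shorter than the raw read length.
`N` bases fail any threshold (conservative). Two regimes share the
rule: assembly-grade at `trim_q` = 13 and mapping-grade at
`map_q` = 20. The published description of the mapping-grade filter
("reads with Q ≥ 20") does not say whether it was per-base, per-read
mean, or a segment rule; we adopt the per-base re-trim as the natural
stricter analogue of the assembly trim and expose the threshold in
config. "Length more than 25" is read strictly: `min_len` = 26.

## Mapping (`dhdup.mapper`)

Candidate loci come from exact k-mer seeds (k = 21, probed at
non-overlapping stride so that any placement with fewer edits than the
number of seeds retains an intact seed); candidates are verified by
semi-global alignment (edlib, read global / unigene local, unit costs).
Identity is matches over alignment columns with each gap column a
non-match.

**The 99% contract and the one-mismatch relaxation.** Applied
literally, 99% identity allows `floor(0.01 * L)` = 0 mismatches for a
90-bp read — which would discard every read carrying a PSV and make
the duplicate scan vacuous. Any pipeline that both maps at "99%
similarity" and calls variant sites from 90-bp reads must tolerate at
least one mismatch per read; the default therefore allows
`max(1, floor((1 - min_identity) * L))` edits, and `strict_identity`
restores the literal bound (under which a 100-bp read may still carry
one mismatch). This is the single most consequential interpretation in
the package and is surfaced in the config, the mapper docstring and
here.

**Ties.** A read whose best score is achieved on two or more unigenes
is discarded by default (`tie_policy="discard"`) — conservative against
cross-paralog misassignment, at the cost of losing reads in exons
shared between isoforms of one component. `"all"` keeps every tied
placement for sensitivity studies. Mates map independently; no
insert-size rescue is attempted.

## Duplicate scan (`dhdup.dupscan`)

Pileup columns count only read bases with quality ≥ `map_q`; gap
columns contribute nothing. The three call conditions (defaults):
depth ≥ 4; some non-major allele with ≥ 2 supporting reads; that
allele's frequency ≥ 10% of the column depth. Interpretation choices:

- "minimum number of variant alleles was two" is read as *read support*
  for the variant allele (≥ 2 reads), the stronger of the two plausible
  readings — it implies the weaker "two distinct alleles present".
- The major allele is the pileup majority, not the assembly base: an
  assembly consensus over collapsed copies may carry either copy's
  allele. Ties between top alleles break toward the assembly base,
  then alphabetically; the assembly base is always recorded.
- MAF is computed against total column depth (site-level denominator),
  and reported for the strongest variant allele.
- A site is a PSV when exactly two alleles pass (major + 1 variant),
  an MSV at three or more. Totals pool both classes; `site_class`
  distinguishes them.

Flagged unigenes (≥ 1 site) are binned by site count into
1, 2, 3, 4, 5, ">5". `scan_alignments` is a vectorised fast path whose
candidate prefilter (second-largest allele count vs conditions 2–3) is
provably equivalent to the generic column scan; a test asserts the two
paths produce identical calls, and `call_site` remains the sole
authority on every candidate.

## Splice candidates (`dhdup.splice`)

Components are keyed on `comp<N>_c<M>` (legacy) or `TRINITY_DN<N>_c<M>`
(modern) headers; unparseable headers are errors in strict mode and
singleton fallback clusters in lenient mode. Multi-member components
are *candidates* only — no claim of confirmed splicing is encoded.
Member pairs (all pairs within a component; quadratic is acceptable at
candidate scale) are aligned globally with affine gaps (match +2,
mismatch −3, open −10, extend −0.5: opening is expensive so a skipped
exon stays one gap block). Maximal runs of non-identity columns become
difference blocks (`insertion-in-a` / `insertion-in-b` /
`substitution-run`); pure-gap blocks are left-normalised to their
leftmost equivalent placement (the VCF indel convention) so that
coordinates are canonical when the gap's flanks share sequence.
Truth-table comparisons left-normalise the planted exon interval with
the same rule. `pick_flank_windows` returns `window_len`-bp windows on
the exactly-matching flanks (requiring flanks ≥ `min_flank`), a
coordinate-level stand-in for primer placement; thermodynamics are out
of scope.

## Pipeline and evaluation (`dhdup.pipeline`)

One YAML config drives all stages; each run writes every stage output
plus a manifest (resolved config, per-stage in/out counts, SHA-256 of
every data file) into one directory, and the resolved config is written
back out. Evaluation against truth matches sites by exact 0-based
position: a shifted call counts as both a miss and a false positive.
Undefined ratios (empty denominators) are reported as NA, never 0.

## Evaluation scenarios (`dhdup.scenarios`)

- *Specificity*: 200 genes, no duplication, error-free reads at 20×
  over 3–5 exons of 150–250 bp. With zero error and the identity
  contract, any call would be a logic fault; expected count is exactly 0.
- *Recovery*: 200 genes, 40 collapsed duplicates, 1–8 planted sites,
  default gene structure (5–8 exons × 180–320 bp, so every gene can
  host 8 spaced sites), 60× coverage, 0.1% error, 1:1 expression.
  ~110 k read pairs; runs in well under a minute. Measured site-level
  sensitivity and unigene-level precision are expected ≥ 0.95 and in
  practice sit at 1.0 under these conditions — the generator's spacing
  and margin rules (above) are what make the per-site evidence clean.

Oracle checks (site filter vs exhaustive enumeration at depth ≤ 12,
mapper vs all-vs-all alignment at 100 reads × 20 unigenes, trimmer vs
brute-force substring search at 1000 reads) use independently
re-derived implementations, both in the test suite and again in
`scripts/acceptance.py`.

## Numerical and degenerate-input conventions

- Thresholds are inclusive ("at least"): quality ≥ Q, depth ≥ 4,
  variant reads ≥ 2, MAF ≥ 0.10 (so 2/20 passes).
- Empty inputs yield empty outputs with zeroed summaries, never errors;
  genuinely inconsistent inputs (duplicate ids, unknown unigene in an
  alignment, truth/call id mismatch, unparseable strict header,
  impossible variant-density request) are hard errors.
- Determinism: all randomness flows from `numpy.random.default_rng`
  seeded from the config seed (separate child streams for sequence
  generation and read simulation); iteration orders are fixed; output
  files are byte-stable.

## Known limitations

Substitution PSVs only; no spliced or quality-aware alignment; no
copy-number estimation; candidate components are structural candidates,
not validated splicing events; sensitivity to PSVs closer than one read
length, or within one read length of a transcript end, is reduced by
construction of the method (identity filter and coverage ramp) and is
not measured by the shipped scenarios.
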