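"""Pileup construction and the three-condition PSV/MSV filter.

In a doubled-haploid (fully homozygous) individual no pileup site can
be a true allelic SNP, so a site where mapped reads disagree points at
a collapsed gene duplicate: the two paralogous copies co-assembled
into one unigene and their fixed differences — paralogous sequence
variants (PSVs), or multisite variants (MSVs) when more than two
alleles are involved — surface as heterozygous-looking columns.

A site is called when all three conditions hold:

1. depth — at least ``min_depth`` reads cover the position (default 4);
2. variant support — a non-major allele is seen in at least
   ``min_variant_reads`` reads (default 2);
3. frequency — that allele's fraction of the depth is at least
   ``min_maf`` (default 10%).

The major allele is the pileup majority (ties broken toward the
assembly base), not the assembly base itself, because the consensus
may carry either copy's allele.  Read bases below the mapping-grade
quality threshold are excluded from counts, as are gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .config import PipelineConfig
from .mapper import ReadAlignment, _CIGAR_RE
from .unigene import Unigene

__all__ = [
    "PileupColumn",
    "PsvCall",
    "DuplicateReport",
    "build_pileup",
    "call_site",
    "scan_duplicates",
    "scan_alignments",
    "write_calls_tsv",
    "write_calls_vcf",
    "write_report_tsv",
]

_ALLELES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_ALLELES):
    _CODE[ord(_b)] = _i

HISTOGRAM_BINS = ("1", "2", "3", "4", "5", ">5")


@dataclass
class PileupColumn:
    """Allele counts over the quality-passing read bases at one position."""

    unigene_id: str
    pos: int  # 0-based
    ref_base: str  # the assembly (FASTA) base
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class PsvCall:
    """One site passing all three filter conditions."""

    unigene_id: str
    pos: int  # 0-based
    ref_base: str
    major_allele: str
    variant_alleles: list[tuple[str, int]]  # (base, reads), strongest first
    depth: int
    maf: float  # frequency of the strongest variant allele
    site_class: str  # "PSV" (2 alleles) or "MSV" (>= 3)


@dataclass
class DuplicateReport:
    """Per-unigene site counts and the 1..5/">5" histogram."""

    sites_per_unigene: dict[str, int] = field(default_factory=dict)
    n_sites_total: int = 0
    n_flagged_unigenes: int = 0
    histogram: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in HISTOGRAM_BINS}
    )

    @classmethod
    def from_calls(cls, calls: Sequence[PsvCall]) -> "DuplicateReport":
        per: dict[str, int] = {}
        for call in calls:
            per[call.unigene_id] = per.get(call.unigene_id, 0) + 1
        report = cls(sites_per_unigene=per, n_sites_total=len(calls), n_flagged_unigenes=len(per))
        for n in per.values():
            report.histogram[str(n) if n <= 5 else ">5"] += 1
        return report

    def flagged_ids(self) -> set[str]:
        return set(self.sites_per_unigene)


def _aligned_columns(aln: ReadAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Read offsets and unigene positions of the non-gap alignment columns."""
    read_offs: list[np.ndarray] = []
    ref_pos: list[np.ndarray] = []
    r, u = 0, aln.start
    for n, op in _CIGAR_RE.findall(aln.cigar):
        n = int(n)
        if op in "=XM":
            read_offs.append(np.arange(r, r + n))
            ref_pos.append(np.arange(u, u + n))
            r += n
            u += n
        elif op == "I":
            r += n
        else:  # D
            u += n
    if not read_offs:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(read_offs), np.concatenate(ref_pos)


def pileup_arrays(
    alignments: Iterable[ReadAlignment],
    unigenes: Sequence[Unigene],
    cfg: PipelineConfig,
) -> dict[str, np.ndarray]:
    """Per-unigene (4, L) allele-count matrices over quality-passing bases."""
    arrays = {u.full_id: np.zeros((4, len(u.sequence)), dtype=np.uint32) for u in unigenes}
    for aln in alignments:
        arr = arrays.get(aln.unigene_id)
        if arr is None:
            raise ValueError(f"alignment references unknown unigene {aln.unigene_id!r}")
        codes = _CODE[np.frombuffer(aln.bases.encode("ascii"), dtype=np.uint8)]
        quals = np.asarray(aln.quals)
        ro, rp = _aligned_columns(aln)
        keep = (quals[ro] >= cfg.map_q) & (codes[ro] < 4)
        np.add.at(arr, (codes[ro[keep]], rp[keep]), 1)
    return arrays


def build_pileup(
    alignments: Iterable[ReadAlignment],
    unigenes: Sequence[Unigene],
    cfg: PipelineConfig,
) -> Iterator[PileupColumn]:
    """Stream covered columns ordered by (unigene, position)."""
    arrays = pileup_arrays(alignments, unigenes, cfg)
    for u in unigenes:
        arr = arrays[u.full_id]
        depth = arr.sum(axis=0)
        for pos in np.flatnonzero(depth):
            pos = int(pos)
            counts = {b: int(arr[i, pos]) for i, b in enumerate(_ALLELES)}
            yield PileupColumn(u.full_id, pos, u.sequence[pos], counts)


def call_site(col: PileupColumn, cfg: PipelineConfig) -> PsvCall | None:
    """Apply the three filter conditions to one pileup column."""
    depth = col.depth
    if depth < cfg.min_depth:
        return None
    present = {b: c for b, c in col.counts.items() if c > 0}
    if len(present) < 2:
        return None
    top = max(present.values())
    tied = sorted(b for b, c in present.items() if c == top)
    major = col.ref_base if col.ref_base in tied else tied[0]
    variants = [
        (b, c)
        for b, c in present.items()
        if b != major and c >= cfg.min_variant_reads and c / depth >= cfg.min_maf
    ]
    if not variants:
        return None
    variants.sort(key=lambda bc: (-bc[1], bc[0]))
    return PsvCall(
        unigene_id=col.unigene_id,
        pos=col.pos,
        ref_base=col.ref_base,
        major_allele=major,
        variant_alleles=variants,
        depth=depth,
        maf=variants[0][1] / depth,
        site_class="PSV" if len(variants) == 1 else "MSV",
    )


def scan_duplicates(
    pileup: Iterable[PileupColumn], cfg: PipelineConfig
) -> tuple[list[PsvCall], DuplicateReport]:
    """Call every passing site and aggregate the per-unigene report."""
    calls = []
    for col in pileup:
        call = call_site(col, cfg)
        if call is not None:
            calls.append(call)
    return calls, DuplicateReport.from_calls(calls)


def scan_alignments(
    alignments: Iterable[ReadAlignment],
    unigenes: Sequence[Unigene],
    cfg: PipelineConfig,
) -> tuple[list[PsvCall], DuplicateReport]:
    """Pileup + scan in one pass, with a vectorised candidate prefilter.

    Produces exactly the calls of ``scan_duplicates(build_pileup(...))``:
    the prefilter keeps every column whose second-largest allele count
    could satisfy conditions 2 and 3, and ``call_site`` remains the
    sole authority on each candidate.
    """
    arrays = pileup_arrays(alignments, unigenes, cfg)
    calls: list[PsvCall] = []
    for u in unigenes:
        arr = arrays[u.full_id]
        depth = arr.sum(axis=0)
        second = np.partition(arr, 2, axis=0)[2]  # second-largest of 4 counts
        with np.errstate(invalid="ignore", divide="ignore"):
            cand = (
                (depth >= cfg.min_depth)
                & (second >= cfg.min_variant_reads)
                & (second >= cfg.min_maf * depth)
            )
        for pos in np.flatnonzero(cand):
            pos = int(pos)
            counts = {b: int(arr[i, pos]) for i, b in enumerate(_ALLELES)}
            call = call_site(PileupColumn(u.full_id, pos, u.sequence[pos], counts), cfg)
            if call is not None:
                calls.append(call)
    return calls, DuplicateReport.from_calls(calls)


# ---- writers ------------------------------------------------------------


def write_calls_tsv(calls: Iterable[PsvCall], path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write(
            "unigene_id\tpos0\tref_base\tmajor_allele\tvariant_alleles\t"
            "depth\tmaf\tsite_class\n"
        )
        for c in calls:
            var = ";".join(f"{b}:{cnt}" for b, cnt in c.variant_alleles)
            fh.write(
                f"{c.unigene_id}\t{c.pos}\t{c.ref_base}\t{c.major_allele}\t{var}\t"
                f"{c.depth}\t{c.maf:.4f}\t{c.site_class}\n"
            )
            n += 1
    return n


def write_calls_vcf(calls: Iterable[PsvCall], unigenes: Sequence[Unigene], path) -> int:
    """Minimal VCF-style output: CHROM=unigene, POS 1-based, DP/AF/CLASS."""
    n = 0
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Counted read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Strongest variant allele frequency">\n')
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="PSV or MSV">\n')
        for u in unigenes:
            fh.write(f"##contig=<ID={u.full_id},length={len(u.sequence)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            alts = [b for b, _ in c.variant_alleles if b != c.ref_base]
            if c.major_allele != c.ref_base:
                alts = [c.major_allele] + alts
            fh.write(
                f"{c.unigene_id}\t{c.pos + 1}\t.\t{c.ref_base}\t{','.join(alts) or '.'}\t"
                f".\tPASS\tDP={c.depth};AF={c.maf:.4f};CLASS={c.site_class}\n"
            )
            n += 1
    return n


def write_report_tsv(report: DuplicateReport, path, histogram_path=None) -> None:
    with open(path, "w") as fh:
        fh.write("unigene_id\tn_psv_sites\tis_putative_duplicate\n")
        for uid in sorted(report.sites_per_unigene):
            fh.write(f"{uid}\t{report.sites_per_unigene[uid]}\t1\n")
    if histogram_path is not None:
        with open(histogram_path, "w") as fh:
            fh.write("n_sites\tn_unigenes\n")
            for b in HISTOGRAM_BINS:
                fh.write(f"{b}\t{report.histogram[b]}\n")
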