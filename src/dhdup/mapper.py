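"""Read-to-unigene mapping under a percent-identity contract.

Reads are placed by seed-and-extend: exact k-mers anchor candidate
unigenes, and each candidate is verified by semi-global alignment
(the read global, the unigene local) with edlib.  Identity is
``matches / alignment columns`` with every gap column counting as a
non-match, and an alignment is kept only when its edit count satisfies
the configured identity floor (99% by default).

At 99% a 90-bp read nominally allows ``floor(0.01 * 90) = 0``
mismatches, which would discard the very reads that carry variant
evidence; by default the bound is therefore relaxed to at least one
edit per read (``PipelineConfig.strict_identity`` restores the literal
rule).  Reads whose best alignment ties across different unigenes are
discarded by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .config import PipelineConfig
from .qc import Read
from .unigene import Unigene, revcomp

__all__ = [
    "ReadAlignment",
    "SeedIndex",
    "MappingSummary",
    "map_read",
    "map_all",
    "write_alignments_tsv",
    "read_alignments_tsv",
    "write_sam",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ReadAlignment:
    """One read placed on one unigene.

    ``bases``/``quals`` are stored in reference orientation (reverse
    complemented for minus-strand placements) so pileup construction
    never needs to re-orient.  The CIGAR uses ``=``/``X``/``I``/``D``
    with I = base present in the read but not the unigene.
    """

    read_id: str
    unigene_id: str
    start: int  # 0-based inclusive on the unigene
    end: int  # exclusive
    strand: str  # "+" or "-"
    cigar: str
    edits: int
    identity: float
    bases: str
    quals: np.ndarray

    def aligned_pairs(self) -> list[tuple[int | None, int | None]]:
        """(read_offset, unigene_position) per alignment column; None = gap."""
        pairs: list[tuple[int | None, int | None]] = []
        r, u = 0, self.start
        for n, op in _CIGAR_RE.findall(self.cigar):
            n = int(n)
            if op in "=XM":
                pairs.extend((r + i, u + i) for i in range(n))
                r += n
                u += n
            elif op == "I":
                pairs.extend((r + i, None) for i in range(n))
                r += n
            else:  # D
                pairs.extend((None, u + i) for i in range(n))
                u += n
        return pairs


@dataclass
class MappingSummary:
    n_reads: int = 0
    n_mapped: int = 0
    n_ambiguous: int = 0
    n_unmapped: int = 0
    per_unigene: dict[str, int] | None = None

    @property
    def mapped_fraction(self) -> float:
        return self.n_mapped / self.n_reads if self.n_reads else 0.0


class SeedIndex:
    """Exact k-mer index over the forward strands of a unigene set.

    Reverse-strand placement is handled at query time by also probing
    the read's reverse complement, so only forward k-mers are stored.
    """

    def __init__(self, unigenes: Sequence[Unigene], k: int = 21):
        if k < 8:
            raise ValueError("seed size k must be >= 8")
        self.k = k
        self.unigenes = list(unigenes)
        seen: set[str] = set()
        for u in self.unigenes:
            if u.full_id in seen:
                raise ValueError(f"duplicate unigene id {u.full_id!r}")
            seen.add(u.full_id)
        self._kmers: dict[str, list[tuple[int, int]]] = {}
        for idx, u in enumerate(self.unigenes):
            seq = u.sequence
            for pos in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[pos : pos + k], []).append((idx, pos))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        """Positions of an exact k-mer as (unigene index, offset) pairs."""
        return self._kmers.get(kmer, [])

    def candidate_unigenes(self, seq: str) -> list[int]:
        """Unigene indices sharing at least one k-mer with ``seq``.

        Seeds are probed at non-overlapping stride k, plus the final
        k-mer: with s seeds, any placement with fewer than s edits is
        guaranteed at least one intact seed (pigeonhole).
        """
        k = self.k
        if len(seq) < k:
            return []
        hits: set[int] = set()
        positions = list(range(0, len(seq) - k + 1, k))
        if positions[-1] != len(seq) - k:
            positions.append(len(seq) - k)
        for pos in positions:
            for idx, _ in self._kmers.get(seq[pos : pos + k], ()):
                hits.add(idx)
        return sorted(hits)


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, total alignment columns) from an extended CIGAR."""
    matches = columns = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def _align_to(seq: str, target: str, max_ed: int) -> tuple[int, int, int, str] | None:
    """Best semi-global placement of ``seq`` on ``target`` within ``max_ed``.

    Returns ``(edit_distance, start, end_exclusive, cigar)`` for the
    leftmost best location, or None.
    """
    res = edlib.align(seq, target, mode="HW", task="path", k=max_ed)
    if res["editDistance"] < 0:
        return None
    # locations are sorted; the cigar is computed for the first one
    start, end = res["locations"][0]
    return res["editDistance"], start, end + 1, res["cigar"]


def map_read(
    read: Read,
    index: SeedIndex,
    cfg: PipelineConfig,
) -> list[ReadAlignment]:
    """Best alignment(s) of one read.

    Returns a single-element list for a uniquely best placement, a
    multi-element list when the best score ties across unigenes
    (the caller applies the tie policy), and an empty list for an
    unmappable read.
    """
    max_ed = cfg.max_edits(len(read))
    fwd = read.bases
    rev = revcomp(fwd)
    best_ed = max_ed + 1
    # (unigene_idx, strand, start, end, cigar, ed); "+" probed first so a
    # same-unigene strand tie resolves to the forward placement
    hits: list[tuple[int, str, int, int, str, int]] = []
    for strand, seq in (("+", fwd), ("-", rev)):
        for idx in index.candidate_unigenes(seq):
            res = _align_to(seq, index.unigenes[idx].sequence, max_ed)
            if res is None:
                continue
            ed, start, end, cigar = res
            if ed < best_ed:
                best_ed = ed
                hits = [(idx, strand, start, end, cigar, ed)]
            elif ed == best_ed:
                if not any(h[0] == idx for h in hits):
                    hits.append((idx, strand, start, end, cigar, ed))
    out: list[ReadAlignment] = []
    for idx, strand, start, end, cigar, ed in hits:
        matches, columns = _cigar_stats(cigar)
        oriented = fwd if strand == "+" else rev
        quals = read.quals if strand == "+" else read.quals[::-1]
        out.append(
            ReadAlignment(
                read_id=read.id,
                unigene_id=index.unigenes[idx].full_id,
                start=start,
                end=end,
                strand=strand,
                cigar=cigar,
                edits=ed,
                identity=matches / columns if columns else 0.0,
                bases=oriented,
                quals=quals,
            )
        )
    return out


def map_all(
    reads: Iterable[Read],
    unigenes: Sequence[Unigene],
    cfg: PipelineConfig,
    index: SeedIndex | None = None,
) -> tuple[list[ReadAlignment], MappingSummary]:
    """Map a read collection; deterministic in input order."""
    if index is None:
        index = SeedIndex(unigenes, k=cfg.seed_k)
    summary = MappingSummary(per_unigene={u.full_id: 0 for u in unigenes})
    alignments: list[ReadAlignment] = []
    for read in reads:
        summary.n_reads += 1
        hits = map_read(read, index, cfg)
        if not hits:
            summary.n_unmapped += 1
            continue
        if len(hits) > 1:
            summary.n_ambiguous += 1
            if cfg.tie_policy == "discard":
                continue
        summary.n_mapped += 1
        for aln in hits:
            alignments.append(aln)
            summary.per_unigene[aln.unigene_id] += 1
    return alignments, summary


# ---- serialisation ------------------------------------------------------

_TSV_HEADER = "read_id\tunigene_id\tstart\tend\tstrand\tcigar\tedits\tidentity\tbases\tquals"


def write_alignments_tsv(alignments: Iterable[ReadAlignment], path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for a in alignments:
            quals = ",".join(str(int(q)) for q in a.quals)
            fh.write(
                f"{a.read_id}\t{a.unigene_id}\t{a.start}\t{a.end}\t{a.strand}\t"
                f"{a.cigar}\t{a.edits}\t{a.identity:.6f}\t{a.bases}\t{quals}\n"
            )
            n += 1
    return n


def read_alignments_tsv(path) -> list[ReadAlignment]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"unexpected alignment TSV header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                ReadAlignment(
                    read_id=f[0],
                    unigene_id=f[1],
                    start=int(f[2]),
                    end=int(f[3]),
                    strand=f[4],
                    cigar=f[5],
                    edits=int(f[6]),
                    identity=float(f[7]),
                    bases=f[8],
                    quals=np.array([int(q) for q in f[9].split(",")], dtype=np.int16),
                )
            )
    return out


def write_sam(
    alignments: Iterable[ReadAlignment], unigenes: Sequence[Unigene], path
) -> int:
    """Write alignments as plain-text SAM with @SQ headers and NM tags."""
    n = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for u in unigenes:
            fh.write(f"@SQ\tSN:{u.full_id}\tLN:{len(u.sequence)}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            # SAM cigar: collapse =/X to M
            sam_cigar = ""
            run_len, run_op = 0, ""
            for cnt, op in _CIGAR_RE.findall(a.cigar):
                op = "M" if op in "=X" else op
                if op == run_op:
                    run_len += int(cnt)
                else:
                    if run_op:
                        sam_cigar += f"{run_len}{run_op}"
                    run_len, run_op = int(cnt), op
            if run_op:
                sam_cigar += f"{run_len}{run_op}"
            qual = "".join(chr(int(q) + 33) for q in a.quals)
            fh.write(
                f"{a.read_id}\t{flag}\t{a.unigene_id}\t{a.start + 1}\t60\t{sam_cigar}\t"
                f"*\t0\t0\t{a.bases}\t{qual}\tNM:i:{a.edits}\n"
            )
            n += 1
    return n
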