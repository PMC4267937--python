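"""Synthetic doubled-haploid transcriptome and read simulator.

The generator emulates the situation the duplicate-detection filter is
built for: a fully homozygous individual whose transcriptome assembly
collapsed some recently duplicated gene pairs into single unigenes.
Such a collapsed unigene is emitted as ONE reference sequence plus a
hidden second haplotype that differs at a handful of planted
substitution sites — the paralogous sequence variants (PSVs) the
pipeline must recover from read pileups.  A second fraction of genes
carries an exon-skipping isoform pair sharing one Trinity-style
component identifier, the substrate of splice-candidate extraction.

Everything is driven by a single integer seed; identical seed and
configuration reproduce byte-identical FASTA/FASTQ output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .config import SimConfig
from .qc import Read
from .unigene import Unigene, revcomp

__all__ = [
    "TruthRecord",
    "TruthTable",
    "simulate_transcriptome",
    "simulate_reads",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthRecord:
    """Ground truth for one emitted unigene record."""

    record_id: str
    component_id: str
    seq_index: int
    is_duplicate: bool
    # planted PSV sites as (0-based position, reference base, hidden-copy base)
    psv_sites: list[tuple[int, str, str]] = field(default_factory=list)
    # exon inclusion mask for this record ("1101" = third exon skipped);
    # empty string for genes simulated without isoform structure
    isoform_mask: str = ""
    exon_lengths: list[int] = field(default_factory=list)


class TruthTable:
    """Per-record ground truth with TSV round-trip."""

    def __init__(self, records: Sequence[TruthRecord]):
        self.records = list(records)
        self.by_id: dict[str, TruthRecord] = {}
        for rec in self.records:
            if rec.record_id in self.by_id:
                raise ValueError(f"duplicate truth record {rec.record_id!r}")
            self.by_id[rec.record_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def planted_sites(self) -> set[tuple[str, int]]:
        """All ``(record_id, position)`` pairs carrying a planted PSV."""
        return {
            (rec.record_id, pos)
            for rec in self.records
            for pos, _, _ in rec.psv_sites
        }

    def duplicate_ids(self) -> set[str]:
        return {rec.record_id for rec in self.records if rec.is_duplicate}

    def exon_skip_events(self) -> list[tuple[str, str, str, tuple[int, int]]]:
        """Planted exon-skip events.

        Returns ``(component_id, full_record_id, skip_record_id,
        (start, end))`` with the skipped exon as a half-open interval in
        the coordinates of the full (all-exon) isoform.
        """
        by_comp: dict[str, list[TruthRecord]] = {}
        for rec in self.records:
            if rec.isoform_mask:
                by_comp.setdefault(rec.component_id, []).append(rec)
        events = []
        for comp, members in by_comp.items():
            if len(members) < 2:
                continue
            members = sorted(members, key=lambda r: r.seq_index)
            full = members[0]
            for skip in members[1:]:
                mask = skip.isoform_mask
                i = mask.index("0")
                start = sum(full.exon_lengths[:i])
                end = start + full.exon_lengths[i]
                events.append((comp, full.record_id, skip.record_id, (start, end)))
        return events

    def alternate_haplotype(self, record_id: str, reference: str) -> str:
        """Reconstruct the hidden duplicate copy of a collapsed unigene."""
        rec = self.by_id[record_id]
        if not rec.is_duplicate:
            return reference
        seq = bytearray(reference, "ascii")
        for pos, ref, alt in rec.psv_sites:
            if seq[pos] != ord(ref):
                raise ValueError(
                    f"{record_id}: reference base at {pos} is {chr(seq[pos])}, truth says {ref}"
                )
            seq[pos] = ord(alt)
        return seq.decode("ascii")

    # ---- TSV round trip -------------------------------------------------

    _COLUMNS = (
        "record_id",
        "component_id",
        "seq_index",
        "is_duplicate",
        "psv_sites",
        "isoform_mask",
        "exon_lengths",
    )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(self._COLUMNS) + "\n")
            for rec in self.records:
                psv = ";".join(f"{p}:{r}>{a}" for p, r, a in rec.psv_sites) or "."
                exons = ";".join(str(x) for x in rec.exon_lengths) or "."
                fh.write(
                    f"{rec.record_id}\t{rec.component_id}\t{rec.seq_index}\t"
                    f"{int(rec.is_duplicate)}\t{psv}\t{rec.isoform_mask or '.'}\t{exons}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        records = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != cls._COLUMNS:
                raise ValueError(f"unexpected truth table header {header}")
            for line in fh:
                rid, comp, idx, dup, psv, mask, exons = line.rstrip("\n").split("\t")
                sites = []
                if psv != ".":
                    for token in psv.split(";"):
                        pos, change = token.split(":")
                        ref, alt = change.split(">")
                        sites.append((int(pos), ref, alt))
                records.append(
                    TruthRecord(
                        record_id=rid,
                        component_id=comp,
                        seq_index=int(idx),
                        is_duplicate=bool(int(dup)),
                        psv_sites=sites,
                        isoform_mask="" if mask == "." else mask,
                        exon_lengths=[] if exons == "." else [int(x) for x in exons.split(";")],
                    )
                )
        return cls(records)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _spaced_positions(
    rng: np.random.Generator, lo: int, hi: int, k: int, gap: int
) -> np.ndarray:
    """Sample k sorted positions in [lo, hi] with pairwise distance > gap."""
    width = hi - lo + 1
    slots = width - (k - 1) * gap
    if slots < k:
        raise ValueError(
            f"cannot place {k} sites with spacing {gap} in {width} bp; "
            "sequence too short for the requested variant density"
        )
    base = np.sort(rng.choice(slots, size=k, replace=False))
    return base + lo + np.arange(k) * gap


def simulate_transcriptome(cfg: SimConfig) -> tuple[list[Unigene], TruthTable]:
    """Generate unigene records and their ground truth.

    Exactly ``round(dup_fraction * n_genes)`` genes are emitted as
    collapsed duplicates (quota sampling over a seeded permutation) and
    ``round(isoform_fraction * n_genes)`` carry an exon-skip isoform
    pair; the two sets are disjoint.  Collapsed duplicates are one
    reference sequence with ``psv_per_dup`` substitution sites planted
    in the read-covered interior (``psv_end_margin`` from either end,
    ``min_psv_spacing`` apart) so that each site's evidence is carried
    by reads spanning no other site.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n_genes
    n_dup = round(cfg.dup_fraction * n)
    n_iso = round(cfg.isoform_fraction * n)
    if n_dup + n_iso > n:
        raise ValueError(
            f"dup_fraction + isoform_fraction allocate {n_dup + n_iso} of {n} genes"
        )
    perm = rng.permutation(n)
    dup_genes = set(int(i) for i in perm[:n_dup])
    iso_genes = set(int(i) for i in perm[n_dup : n_dup + n_iso])

    unigenes: list[Unigene] = []
    records: list[TruthRecord] = []
    for gene in range(n):
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        exon_lens = [
            int(x)
            for x in rng.integers(
                cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, size=n_exons
            )
        ]
        exons = [_random_seq(rng, ln) for ln in exon_lens]
        full_seq = "".join(exons)
        component = f"comp{gene + 1}_c0"

        if gene in iso_genes:
            # exon-skip pair: seq1 keeps every exon, seq2 drops one internal exon
            skip = int(rng.integers(1, n_exons - 1))
            mask_full = "1" * n_exons
            mask_skip = mask_full[:skip] + "0" + mask_full[skip + 1 :]
            skip_seq = "".join(e for j, e in enumerate(exons) if j != skip)
            for idx, (seq, mask) in enumerate(
                [(full_seq, mask_full), (skip_seq, mask_skip)], start=1
            ):
                rid = f"{component}_seq{idx}"
                unigenes.append(Unigene(rid, component, idx, seq))
                records.append(
                    TruthRecord(rid, component, idx, False, [], mask, exon_lens)
                )
            continue

        rid = f"{component}_seq1"
        psv_sites: list[tuple[int, str, str]] = []
        if gene in dup_genes:
            k = int(rng.integers(cfg.psv_per_dup[0], cfg.psv_per_dup[1] + 1))
            lo = cfg.psv_end_margin
            hi = len(full_seq) - 1 - cfg.psv_end_margin
            positions = _spaced_positions(rng, lo, hi, k, cfg.min_psv_spacing)
            for pos in positions:
                ref = full_seq[int(pos)]
                alt = chr(
                    _BASES[
                        (int(np.flatnonzero(_BASES == ord(ref))[0]) + int(rng.integers(1, 4))) % 4
                    ]
                )
                psv_sites.append((int(pos), ref, alt))
        unigenes.append(Unigene(rid, component, 1, full_seq))
        records.append(
            TruthRecord(rid, component, 1, gene in dup_genes, psv_sites, "", exon_lens)
        )

    return unigenes, TruthTable(records)


def _apply_errors(
    rng: np.random.Generator, bases: str, error_rate: float
) -> str:
    if error_rate <= 0:
        return bases
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    if hits.size:
        # substitute with one of the three other bases, uniformly
        codes = np.searchsorted(_BASES, arr[hits])
        shift = rng.integers(1, 4, size=hits.size)
        arr[hits] = _BASES[(codes + shift) % 4]
    return arr.tobytes().decode("ascii")


def simulate_reads(
    unigenes: Iterable[Unigene], truth: TruthTable, cfg: SimConfig
) -> tuple[list[Read], list[Read]]:
    """Simulate paired-end reads over the records, honouring ground truth.

    Each record receives ``round(mean_coverage * L / (2 * read_len))``
    pairs drawn from uniformly placed fragments.  For collapsed
    duplicates a pair originates from the hidden copy B with
    probability ``dup_expression_ratio`` (0.5 = equal expression).
    Per-base substitution errors occur at ``error_rate``; qualities are
    flat at ``quality_level`` with an optional degraded 3' tail.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    rl = cfg.read_len

    def _quals(n: int) -> np.ndarray:
        q = np.full(n, cfg.quality_level, dtype=np.int16)
        if cfg.tail_len:
            q[max(0, n - cfg.tail_len) :] = cfg.tail_q
        return q

    reads1: list[Read] = []
    reads2: list[Read] = []
    for uni in unigenes:
        L = len(uni.sequence)
        if L < rl:
            logger.warning("skipping %s: length %d < read length %d", uni.full_id, L, rl)
            continue
        rec = truth.by_id[uni.full_id]
        hap_a = uni.sequence
        hap_b = truth.alternate_haplotype(uni.full_id, hap_a) if rec.is_duplicate else hap_a
        n_pairs = round(cfg.mean_coverage * L / (2 * rl))
        frag = min(L, max(200, 2 * rl))
        starts = rng.integers(0, L - frag + 1, size=n_pairs)
        if rec.is_duplicate:
            from_b = rng.random(n_pairs) < cfg.dup_expression_ratio
        else:
            from_b = np.zeros(n_pairs, dtype=bool)
        for j in range(n_pairs):
            s = int(starts[j])
            src = hap_b if from_b[j] else hap_a
            fragment = src[s : s + frag]
            b1 = _apply_errors(rng, fragment[:rl], cfg.error_rate)
            b2 = _apply_errors(rng, revcomp(fragment[frag - rl :]), cfg.error_rate)
            reads1.append(Read(f"{uni.full_id}:p{j}/1", b1, _quals(rl)))
            reads2.append(Read(f"{uni.full_id}:p{j}/2", b2, _quals(rl)))
    return reads1, reads2
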