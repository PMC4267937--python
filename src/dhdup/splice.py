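"""Splice-candidate components and inter-isoform difference blocks.

Trinity's Chrysalis stage clusters assembled sequences into components
whose members are expected to be splice isoforms or close paralogs.
Components with two or more member sequences are therefore candidate
loci for alternative splicing; locating the exact blocks where two
members differ tells a validation assay (e.g. a primer pair that must
span the difference) where to look.

Pairs of members are globally aligned with affine gap costs — gap
opening expensive, extension cheap, so a skipped exon comes out as one
contiguous gap block — and maximal runs of non-identity columns are
merged into :class:`DifferenceBlock` records.  Pure-gap blocks are
left-normalised (shifted to their leftmost equivalent placement, the
same convention VCF uses for indels) so coordinates are canonical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from .unigene import Unigene

__all__ = [
    "ComponentCluster",
    "DifferenceBlock",
    "FlankWindows",
    "cluster_components",
    "align_isoforms",
    "pick_flank_windows",
    "write_candidates_tsv",
    "write_blocks_tsv",
]


@dataclass
class ComponentCluster:
    """All unigene sequences sharing one component identifier."""

    component_id: str
    members: list[Unigene]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def is_candidate(self) -> bool:
        """Splice candidate: two or more sequences in the component."""
        return self.n_members >= 2


@dataclass
class DifferenceBlock:
    """One maximal run of disagreement between two aligned isoforms.

    Intervals are 0-based half-open in each member's own coordinates;
    ``kind`` says whether the block is sequence present only in a
    (``insertion-in-a``), only in b (``insertion-in-b``), or a run of
    substituted columns.  ``flank_left``/``flank_right`` are the lengths
    of the exactly matching stretches bounding the block.
    """

    component_id: str
    member_pair: tuple[str, str]
    kind: str
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    flank_left: int
    flank_right: int


@dataclass
class FlankWindows:
    """Conserved windows immediately flanking a difference block.

    Any amplicon spanning the left and right windows necessarily covers
    the difference.  Coordinates are given in both members; because the
    flanks are exact matches the windowed substrings are identical in a
    and b.
    """

    a_left: tuple[int, int]
    b_left: tuple[int, int]
    a_right: tuple[int, int]
    b_right: tuple[int, int]


def cluster_components(
    unigenes: Iterable[Unigene],
) -> list[ComponentCluster]:
    """Group unigenes by component id, preserving first-seen order."""
    clusters: dict[str, ComponentCluster] = {}
    for u in unigenes:
        if u.component_id not in clusters:
            clusters[u.component_id] = ComponentCluster(u.component_id, [])
        clusters[u.component_id].members.append(u)
    for c in clusters.values():
        c.members.sort(key=lambda u: u.seq_index)
    return list(clusters.values())


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=2,
    mismatch_score=-3,
    open_gap_score=-10,
    extend_gap_score=-0.5,
)


def _left_normalise(
    a: str, b: str, kind: str, a_iv: list[int], b_iv: list[int]
) -> None:
    """Shift a pure-gap block to its leftmost equivalent placement."""
    if kind == "insertion-in-a":
        s, e = a_iv
        t = b_iv[0]
        while s > 0 and t > 0 and a[s - 1] == a[e - 1] and a[s - 1] == b[t - 1]:
            s -= 1
            e -= 1
            t -= 1
        a_iv[:] = [s, e]
        b_iv[:] = [t, t]
    elif kind == "insertion-in-b":
        s, e = b_iv
        t = a_iv[0]
        while s > 0 and t > 0 and b[s - 1] == b[e - 1] and b[s - 1] == a[t - 1]:
            s -= 1
            e -= 1
            t -= 1
        b_iv[:] = [s, e]
        a_iv[:] = [t, t]


def align_isoforms(a: Unigene, b: Unigene, normalise: bool = True) -> list[DifferenceBlock]:
    """Locate every maximal difference block between two component members."""
    if a.component_id != b.component_id:
        raise ValueError(
            f"{a.full_id} and {b.full_id} belong to different components"
        )
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner.align(a.sequence, b.sequence)[0]
    ga, gb = alignment[0], alignment[1]

    # column scan: collect maximal runs of non-identity columns
    raw: list[tuple[list[int], list[int]]] = []  # (a_interval, b_interval)
    ai = bi = 0
    in_block = False
    for ca, cb in zip(ga, gb):
        match = ca == cb and ca != "-"
        if not match:
            if not in_block:
                raw.append(([ai, ai], [bi, bi]))
                in_block = True
            if ca != "-":
                raw[-1][0][1] = ai + 1
            if cb != "-":
                raw[-1][1][1] = bi + 1
        else:
            in_block = False
        if ca != "-":
            ai += 1
        if cb != "-":
            bi += 1

    blocks: list[DifferenceBlock] = []
    for a_iv, b_iv in raw:
        a_len = a_iv[1] - a_iv[0]
        b_len = b_iv[1] - b_iv[0]
        if a_len and not b_len:
            kind = "insertion-in-a"
        elif b_len and not a_len:
            kind = "insertion-in-b"
        else:
            kind = "substitution-run"
        if normalise:
            _left_normalise(a.sequence, b.sequence, kind, a_iv, b_iv)
        blocks.append(
            DifferenceBlock(
                component_id=a.component_id,
                member_pair=(a.full_id, b.full_id),
                kind=kind,
                a_interval=(a_iv[0], a_iv[1]),
                b_interval=(b_iv[0], b_iv[1]),
                flank_left=0,
                flank_right=0,
            )
        )

    # recompute exact-match flank lengths from the (possibly shifted)
    # block coordinates, bounded by sequence ends and neighbouring blocks
    for i, blk in enumerate(blocks):
        a_s, a_e = blk.a_interval
        b_s, b_e = blk.b_interval
        left_limit_a = blocks[i - 1].a_interval[1] if i else 0
        left_limit_b = blocks[i - 1].b_interval[1] if i else 0
        n = 0
        while (
            a_s - n > left_limit_a
            and b_s - n > left_limit_b
            and a.sequence[a_s - n - 1] == b.sequence[b_s - n - 1]
        ):
            n += 1
        blk.flank_left = n
        right_limit_a = blocks[i + 1].a_interval[0] if i + 1 < len(blocks) else len(a.sequence)
        right_limit_b = blocks[i + 1].b_interval[0] if i + 1 < len(blocks) else len(b.sequence)
        n = 0
        while (
            a_e + n < right_limit_a
            and b_e + n < right_limit_b
            and a.sequence[a_e + n] == b.sequence[b_e + n]
        ):
            n += 1
        blk.flank_right = n
    return blocks


def pick_flank_windows(
    block: DifferenceBlock, window_len: int, min_flank: int
) -> FlankWindows | None:
    """Conserved windows of ``window_len`` bp bounding a difference block.

    Returns None when either exact-match flank is shorter than
    ``min_flank``.  Requires ``window_len <= min_flank`` so a returned
    window always fits inside a guaranteed-identical flank.
    """
    if window_len > min_flank:
        raise ValueError("window_len must not exceed min_flank")
    if block.flank_left < min_flank or block.flank_right < min_flank:
        return None
    a_s, a_e = block.a_interval
    b_s, b_e = block.b_interval
    return FlankWindows(
        a_left=(a_s - window_len, a_s),
        b_left=(b_s - window_len, b_s),
        a_right=(a_e, a_e + window_len),
        b_right=(b_e, b_e + window_len),
    )


# ---- writers ------------------------------------------------------------


def write_candidates_tsv(clusters: Sequence[ComponentCluster], path) -> int:
    """Write multi-member components (splice candidates); returns the count."""
    n = 0
    with open(path, "w") as fh:
        fh.write("component_id\tn_members\tmember_ids\n")
        for c in clusters:
            if c.is_candidate:
                fh.write(
                    f"{c.component_id}\t{c.n_members}\t"
                    + ";".join(m.full_id for m in c.members)
                    + "\n"
                )
                n += 1
    return n


def write_blocks_tsv(blocks: Iterable[DifferenceBlock], path) -> int:
    """Difference blocks with 1-based inclusive coordinates for reporting."""
    n = 0
    with open(path, "w") as fh:
        fh.write(
            "component_id\tmember_a\tmember_b\tkind\t"
            "a_start\ta_end\tb_start\tb_end\tflank_left\tflank_right\n"
        )
        for b in blocks:
            a_s, a_e = b.a_interval
            b_s, b_e = b.b_interval
            fh.write(
                f"{b.component_id}\t{b.member_pair[0]}\t{b.member_pair[1]}\t{b.kind}\t"
                f"{a_s + 1}\t{a_e}\t{b_s + 1}\t{b_e}\t{b.flank_left}\t{b.flank_right}\n"
            )
            n += 1
    return n
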