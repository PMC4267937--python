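"""Read quality control.

Two regimes mirror the two uses the pipeline makes of the raw reads:

* ``assembly`` — trim at Q13, keep reads longer than 25 bp (the grade
  of data fed to de novo assembly);
* ``mapping`` — the stricter Q20 re-trim applied before reads are
  mapped back to unigenes for duplicate detection.

Trimming keeps the longest contiguous segment in which every base
meets the quality threshold (DynamicTrim-style), leftmost on ties.
``N`` bases fail any threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Read", "QcSummary", "trim_read", "filter_reads"]


@dataclass
class Read:
    """A sequencing read: bases over {A,C,G,T,N} plus per-base Phred scores."""

    id: str
    bases: str
    quals: np.ndarray  # int array, one Phred score per base

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class QcSummary:
    """Counts in/out and mean retained length for one filtering pass."""

    regime: str = ""
    n_in: int = 0
    n_out: int = 0
    bases_in: int = 0
    bases_out: int = 0

    @property
    def mean_retained_len(self) -> float:
        return self.bases_out / self.n_out if self.n_out else 0.0


def _longest_pass_run(mask: np.ndarray) -> tuple[int, int] | None:
    """Leftmost longest run of True in ``mask`` as a half-open interval."""
    if not mask.any():
        return None
    padded = np.concatenate(([False], mask, [False]))
    edges = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    i = int(np.argmax(ends - starts))  # argmax takes the first maximum: leftmost
    return int(starts[i]), int(ends[i])


def trim_read(read: Read, q_threshold: int) -> Read | None:
    """Trim to the longest contiguous segment of bases with quality >= threshold.

    Returns ``None`` when no base qualifies.  ``N`` bases always fail.
    """
    mask = read.quals >= q_threshold
    if "N" in read.bases:
        ns = np.frombuffer(read.bases.encode("ascii"), dtype=np.uint8) == ord("N")
        mask = mask & ~ns
    run = _longest_pass_run(mask)
    if run is None:
        return None
    s, e = run
    if s == 0 and e == len(read.bases):
        return read
    return Read(read.id, read.bases[s:e], read.quals[s:e])


def filter_reads(
    reads,
    cfg,
    regime: str = "assembly",
) -> tuple[list[Read], QcSummary]:
    """Trim every read under the given regime and keep those long enough.

    ``assembly`` trims at ``cfg.trim_q``; ``mapping`` trims at
    ``cfg.map_q``.  Both keep reads of length >= ``cfg.min_len``.
    """
    if regime == "assembly":
        q = cfg.trim_q
    elif regime == "mapping":
        q = cfg.map_q
    else:
        raise ValueError(f"unknown QC regime {regime!r}")

    summary = QcSummary(regime=regime)
    kept: list[Read] = []
    for read in reads:
        summary.n_in += 1
        summary.bases_in += len(read)
        trimmed = trim_read(read, q)
        if trimmed is not None and len(trimmed) >= cfg.min_len:
            kept.append(trimmed)
            summary.n_out += 1
            summary.bases_out += len(trimmed)
    return kept, summary
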