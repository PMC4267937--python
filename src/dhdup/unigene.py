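"""Assembled unigene records and Trinity-style header parsing.

Two header dialects are understood:

* legacy ``comp<N>_c<M>_seq<K>`` (Chrysalis component + sequence index);
* modern ``TRINITY_DN<N>_c<M>_g<G>_i<I>``.

The *component* (``comp<N>_c<M>`` / ``TRINITY_DN<N>_c<M>``) is the
clustering key: sequences sharing a component are candidate splice
isoforms or close paralogs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["Unigene", "parse_unigene_id", "load_unigenes", "revcomp"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]

_LEGACY = re.compile(r"^(comp\d+_c\d+)_seq(\d+)$")
_TRINITY = re.compile(r"^(TRINITY_DN\d+_c\d+)_g\d+_i(\d+)$")


def parse_unigene_id(full_id: str, strict: bool = True) -> tuple[str, int] | None:
    """Split a unigene id into ``(component_id, seq_index)``.

    In strict mode an unparseable header raises ``ValueError``; in
    lenient mode it returns ``None`` so the caller can fall back to a
    singleton component.
    """
    for pattern in (_LEGACY, _TRINITY):
        m = pattern.match(full_id)
        if m:
            return m.group(1), int(m.group(2))
    if strict:
        raise ValueError(f"cannot parse unigene header {full_id!r}")
    return None


@dataclass
class Unigene:
    """One assembled transcript with its parsed component identity."""

    full_id: str
    component_id: str
    seq_index: int
    sequence: str

    @classmethod
    def from_header(cls, full_id: str, sequence: str, strict: bool = True) -> "Unigene":
        parsed = parse_unigene_id(full_id, strict=strict)
        if parsed is None:
            # lenient fallback: the record is its own singleton component
            return cls(full_id, full_id, 1, sequence)
        component_id, seq_index = parsed
        return cls(full_id, component_id, seq_index, sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def load_unigenes(path, strict: bool = True) -> list[Unigene]:
    """Read unigenes from FASTA, parsing component identifiers."""
    from .io import read_fasta

    unigenes = [Unigene.from_header(name, seq, strict=strict) for name, seq in read_fasta(path)]
    seen: set[str] = set()
    for u in unigenes:
        if u.full_id in seen:
            raise ValueError(f"duplicate unigene id {u.full_id!r}")
        seen.add(u.full_id)
    return unigenes
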