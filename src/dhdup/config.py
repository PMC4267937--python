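"""Configuration objects for the duplicate-detection pipeline.

Two dataclasses carry every tunable number:

* :class:`PipelineConfig` — the analysis thresholds (read trimming,
  mapping identity, and the three-condition PSV filter).
* :class:`SimConfig` — the synthetic doubled-haploid transcriptome
  generator (see :mod:`dhdup.synth`).

Both round-trip through plain dicts / YAML so a single run file can
drive the whole pipeline.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["PipelineConfig", "SimConfig", "RunConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds.

    Parameters
    ----------
    trim_q
        Phred threshold for assembly-grade trimming: bases below this
        quality break the retained segment (Q13 ~ 5% error).
    min_len
        Minimum retained read length after trimming, in bp.  26 encodes
        a strict "longer than 25 bp" rule.
    map_q
        Stricter Phred threshold used when re-trimming reads before
        duplicate-detection mapping, and for excluding low-quality
        bases from pileup counts (Q20 = 1% error).
    min_identity
        Minimum read-to-unigene alignment identity (matches / alignment
        columns, gaps counting as non-matches).
    min_depth
        Condition 1 of the PSV filter: minimum reads covering a site.
    min_variant_reads
        Condition 2: minimum reads supporting a variant (non-major)
        allele.
    min_maf
        Condition 3: minimum minor allele frequency at the site.
    strict_identity
        If True, a read of length L may carry at most
        ``floor((1 - min_identity) * L)`` edits — zero for a 90-bp read
        at 99%.  The default (False) relaxes the bound to at least one
        edit so that a read spanning a single paralogous variant site
        can still map; without this relaxation the filter could never
        see variant evidence from 90-bp reads.
    tie_policy
        ``"discard"`` drops reads whose best alignment is equally good
        on two or more unigenes (conservative against cross-paralog
        misassignment); ``"all"`` keeps every tied alignment.
    seed_k
        k-mer size of the mapper's seed index.
    """

    trim_q: int = 13
    min_len: int = 26
    map_q: int = 20
    min_identity: float = 0.99
    min_depth: int = 4
    min_variant_reads: int = 2
    min_maf: float = 0.10
    strict_identity: bool = False
    tie_policy: str = "discard"
    seed_k: int = 21

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError(f"min_maf must lie in [0, 0.5], got {self.min_maf}")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.min_variant_reads < 1:
            raise ValueError("min_variant_reads must be >= 1")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in (0, 1]")
        if self.tie_policy not in ("discard", "all"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        if self.min_len < 1 or self.trim_q < 0 or self.map_q < 0:
            raise ValueError("min_len must be >= 1 and Phred thresholds >= 0")

    def max_edits(self, read_len: int) -> int:
        """Maximum alignment edits allowed for a read of ``read_len`` bp.

        Strict mode applies the identity bound literally; the default
        mode guarantees at least one edit is tolerated regardless of
        read length.
        """
        floor_edits = math.floor((1.0 - self.min_identity) * read_len)
        if self.strict_identity:
            return floor_edits
        return max(1, floor_edits)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class SimConfig:
    """Synthetic doubled-haploid transcriptome generator settings.

    The generated individual is fully homozygous, so the only
    heterozygous-looking pileup sites come from *collapsed duplicates*:
    gene pairs so similar that assembly merged them into one unigene.
    A fraction ``dup_fraction`` of genes are emitted as one reference
    sequence plus a hidden second haplotype differing at
    ``psv_per_dup`` planted substitution sites.

    Reads are 90-bp paired-end with flat per-base quality and an
    optional low-quality 3' tail (for trimmer exercises), uniform
    substitution errors at ``error_rate``, and each pair drawn from
    duplicate copy A or B with probability ``dup_expression_ratio``
    for B (1:1 by default).
    """

    n_genes: int = 200
    dup_fraction: float = 0.2
    psv_per_dup: tuple[int, int] = (1, 8)
    isoform_fraction: float = 0.1
    exon_count_range: tuple[int, int] = (5, 8)
    exon_len_range: tuple[int, int] = (180, 320)
    read_len: int = 90
    mean_coverage: float = 60.0
    error_rate: float = 0.001
    quality_level: int = 30
    seed: int = 0
    # copy-B share of duplicate expression; 0.5 = equal expression
    dup_expression_ratio: float = 0.5
    # planted sites keep this many bp between each other and from the
    # sequence ends, so each site's read evidence is independent
    min_psv_spacing: int = 90
    psv_end_margin: int = 90
    # optional degraded 3' tail on every read (trimmer exercises)
    tail_len: int = 0
    tail_q: int = 2

    def __post_init__(self) -> None:
        for name in ("dup_fraction", "isoform_fraction", "dup_expression_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("psv_per_dup", "exon_count_range", "exon_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be a nonempty positive range, got ({lo}, {hi})")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.isoform_fraction > 0 and self.exon_count_range[0] < 3:
            raise ValueError(
                "exon skipping needs >= 3 exons; raise exon_count_range[0] "
                "or set isoform_fraction to 0"
            )
        if self.tail_len < 0 or self.tail_q < 0:
            raise ValueError("tail_len and tail_q must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for name in ("psv_per_dup", "exon_count_range", "exon_len_range"):
            d[name] = list(d[name])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        for name in ("psv_per_dup", "exon_count_range", "exon_len_range"):
            if name in d:
                d[name] = tuple(d[name])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class RunConfig:
    """One file that drives a full simulate → qc → map → scan → splice run."""

    sim: SimConfig = field(default_factory=SimConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    write_sam: bool = False

    def to_dict(self) -> dict[str, Any]:
        return {
            "sim": self.sim.to_dict(),
            "pipeline": self.pipeline.to_dict(),
            "write_sam": self.write_sam,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(
            sim=SimConfig.from_dict(d.get("sim", {})),
            pipeline=PipelineConfig.from_dict(d.get("pipeline", {})),
            write_sam=bool(d.get("write_sam", False)),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
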