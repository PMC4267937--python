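"""Canonical evaluation scenarios and an in-memory pipeline runner.

These configurations define the study conditions under which the
pipeline's operating characteristics are measured:

* :func:`specificity_scenario` — a homozygous transcriptome with no
  collapsed duplicates and error-free reads; any PSV call is a false
  positive, so the expected call count is exactly zero.
* :func:`recovery_scenario` — 200 unigenes of which 40 are collapsed
  duplicate pairs carrying 1–8 planted variant sites, sequenced at
  60× with 0.1% substitution error and equal expression of the two
  copies; measures site-level sensitivity and unigene-level precision.

Scenario sizes (gene structure, coverage) are fixed here so tests,
scripts and documentation all speak about the same experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import dupscan, mapper, qc, synth
from .config import PipelineConfig, SimConfig
from .dupscan import DuplicateReport, PsvCall
from .pipeline import TruthMetrics, evaluate_against_truth
from .synth import TruthTable
from .unigene import Unigene

__all__ = [
    "specificity_scenario",
    "recovery_scenario",
    "InMemoryRun",
    "run_in_memory",
]


def specificity_scenario(seed: int) -> SimConfig:
    """200 genes, no duplication, error-free reads: the specificity floor."""
    return SimConfig(
        n_genes=200,
        dup_fraction=0.0,
        isoform_fraction=0.0,
        exon_count_range=(3, 5),
        exon_len_range=(150, 250),
        mean_coverage=20.0,
        error_rate=0.0,
        seed=seed,
    )


def recovery_scenario(seed: int) -> SimConfig:
    """200 genes, 40 collapsed duplicates, 60x, 0.1% error, 1:1 expression."""
    return SimConfig(
        n_genes=200,
        dup_fraction=0.2,
        psv_per_dup=(1, 8),
        isoform_fraction=0.0,
        mean_coverage=60.0,
        error_rate=0.001,
        dup_expression_ratio=0.5,
        seed=seed,
    )


@dataclass
class InMemoryRun:
    unigenes: list[Unigene]
    truth: TruthTable
    n_reads: int
    n_kept: int
    mapped_fraction: float
    calls: list[PsvCall]
    report: DuplicateReport
    metrics: TruthMetrics


def run_in_memory(sim: SimConfig, cfg: PipelineConfig | None = None) -> InMemoryRun:
    """simulate → qc(mapping) → map → scan → evaluate, without touching disk."""
    cfg = cfg or PipelineConfig()
    unigenes, truth = synth.simulate_transcriptome(sim)
    reads1, reads2 = synth.simulate_reads(unigenes, truth, sim)
    kept, qc_summary = qc.filter_reads(reads1 + reads2, cfg, regime="mapping")
    alignments, map_summary = mapper.map_all(kept, unigenes, cfg)
    calls, report = dupscan.scan_alignments(alignments, unigenes, cfg)
    metrics = evaluate_against_truth(calls, report, truth)
    return InMemoryRun(
        unigenes=unigenes,
        truth=truth,
        n_reads=qc_summary.n_in,
        n_kept=qc_summary.n_out,
        mapped_fraction=map_summary.mapped_fraction,
        calls=calls,
        report=report,
        metrics=metrics,
    )
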