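"""End-to-end orchestration: simulate → qc → map → dupscan → splice.

A single :class:`~dhdup.config.RunConfig` drives every stage; each run
writes its outputs plus a JSON manifest (resolved config, per-stage
record counts, output checksums) into one directory.  Reruns with the
same config and seed reproduce byte-identical data files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import dupscan, io, mapper, qc, splice, synth
from .config import RunConfig
from .dupscan import DuplicateReport, PsvCall
from .synth import TruthTable

__all__ = ["RunManifest", "StageStatus", "run_pipeline", "evaluate_against_truth", "TruthMetrics"]

logger = logging.getLogger(__name__)


@dataclass
class StageStatus:
    name: str
    status: str = "ok"
    n_in: int = 0
    n_out: int = 0
    detail: str = ""


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[StageStatus] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)  # name -> sha256

    def to_json(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "stages": [dataclasses.asdict(s) for s in self.stages],
            "files": self.files,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> RunManifest:
    """Run every stage under ``out_dir`` and return the manifest.

    ``seed`` overrides the simulator seed from the config; it is the
    only source of randomness in the whole run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = RunConfig(
            sim=dataclasses.replace(config.sim, seed=seed),
            pipeline=config.pipeline,
            write_sam=config.write_sam,
        )
    cfg = config.pipeline
    manifest = RunManifest(config=config.to_dict(), seed=config.sim.seed)
    config_path = out / "resolved_config.yaml"
    config.to_yaml(str(config_path))

    def stage(name: str, n_in: int, n_out: int, detail: str = "") -> None:
        manifest.stages.append(StageStatus(name, "ok", n_in, n_out, detail))
        logger.info("stage %-10s in=%-8d out=%-8d %s", name, n_in, n_out, detail)

    try:
        # --- simulate ----------------------------------------------------
        unigenes, truth = synth.simulate_transcriptome(config.sim)
        reads1, reads2 = synth.simulate_reads(unigenes, truth, config.sim)
        io.write_fasta(((u.full_id, u.sequence) for u in unigenes), out / "unigenes.fasta")
        io.write_fastq(reads1, out / "reads_1.fastq")
        io.write_fastq(reads2, out / "reads_2.fastq")
        truth.to_tsv(out / "truth.tsv")
        n_reads = len(reads1) + len(reads2)
        stage("simulate", config.sim.n_genes, n_reads, f"{len(unigenes)} unigene records")

        # --- qc (mapping regime: duplicate detection is the consumer) ----
        kept, qc_summary = qc.filter_reads(reads1 + reads2, cfg, regime="mapping")
        io.write_fastq(kept, out / "trimmed.fastq")
        with open(out / "qc_report.tsv", "w") as fh:
            fh.write("regime\tn_in\tn_out\tbases_in\tbases_out\tmean_retained_len\n")
            fh.write(
                f"{qc_summary.regime}\t{qc_summary.n_in}\t{qc_summary.n_out}\t"
                f"{qc_summary.bases_in}\t{qc_summary.bases_out}\t"
                f"{qc_summary.mean_retained_len:.2f}\n"
            )
        stage("qc", qc_summary.n_in, qc_summary.n_out)

        # --- map ---------------------------------------------------------
        alignments, map_summary = mapper.map_all(kept, unigenes, cfg)
        mapper.write_alignments_tsv(alignments, out / "aln.tsv")
        if config.write_sam:
            mapper.write_sam(alignments, unigenes, out / "aln.sam")
        stage(
            "map",
            map_summary.n_reads,
            len(alignments),
            f"mapped {map_summary.mapped_fraction:.3f}, ambiguous {map_summary.n_ambiguous}",
        )

        # --- dupscan -----------------------------------------------------
        calls, report = dupscan.scan_alignments(alignments, unigenes, cfg)
        dupscan.write_calls_tsv(calls, out / "calls.tsv")
        dupscan.write_calls_vcf(calls, unigenes, out / "calls.vcf")
        dupscan.write_report_tsv(report, out / "dup_report.tsv", out / "dup_histogram.tsv")
        stage("dupscan", len(alignments), len(calls), f"{report.n_flagged_unigenes} unigenes flagged")

        # --- splice ------------------------------------------------------
        clusters = splice.cluster_components(unigenes)
        candidates = [c for c in clusters if c.is_candidate]
        blocks = []
        for cluster in candidates:
            for i in range(len(cluster.members)):
                for j in range(i + 1, len(cluster.members)):
                    blocks.extend(
                        splice.align_isoforms(cluster.members[i], cluster.members[j])
                    )
        splice.write_candidates_tsv(clusters, out / "candidates.tsv")
        splice.write_blocks_tsv(blocks, out / "blocks.tsv")
        stage("splice", len(unigenes), len(candidates), f"{len(blocks)} difference blocks")

        # --- evaluate ----------------------------------------------------
        metrics = evaluate_against_truth(calls, report, truth)
        metrics.to_tsv(out / "metrics.tsv")
        stage("evaluate", len(calls), 1)
    except Exception as exc:
        manifest.stages.append(
            StageStatus(name="failed", status="error", detail=f"{type(exc).__name__}: {exc}")
        )
        manifest.to_json(out / "manifest.json")
        raise

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.files[f.name] = _sha256(f)
    manifest.to_json(out / "manifest.json")
    return manifest


@dataclass
class TruthMetrics:
    """Recovery metrics against the simulator's ground truth.

    ``None`` marks an undefined ratio (empty denominator), reported as
    NA rather than 0.
    """

    site_tp: int
    site_fp: int
    site_fn: int
    unigene_tp: int
    unigene_fp: int
    unigene_fn: int
    site_sensitivity: float | None
    site_precision: float | None
    unigene_sensitivity: float | None
    unigene_precision: float | None
    calls_by_class: dict[str, int]
    true_sites_by_class: dict[str, int]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for name in (
                "site_tp",
                "site_fp",
                "site_fn",
                "unigene_tp",
                "unigene_fp",
                "unigene_fn",
            ):
                fh.write(f"{name}\t{getattr(self, name)}\n")
            for name in (
                "site_sensitivity",
                "site_precision",
                "unigene_sensitivity",
                "unigene_precision",
            ):
                v = getattr(self, name)
                fh.write(f"{name}\t{'NA' if v is None else f'{v:.4f}'}\n")
            for cls, n in sorted(self.calls_by_class.items()):
                fh.write(f"calls_{cls}\t{n}\n")
            for cls, n in sorted(self.true_sites_by_class.items()):
                fh.write(f"true_calls_{cls}\t{n}\n")


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def evaluate_against_truth(
    calls: Sequence[PsvCall], report: DuplicateReport, truth: TruthTable
) -> TruthMetrics:
    """Score calls against planted sites by exact 0-based position match."""
    known_ids = set(truth.by_id)
    for call in calls:
        if call.unigene_id not in known_ids:
            raise ValueError(f"call on {call.unigene_id!r} absent from truth table")

    planted = truth.planted_sites()
    called = {(c.unigene_id, c.pos) for c in calls}
    site_tp = len(called & planted)
    site_fp = len(called - planted)
    site_fn = len(planted - called)

    true_dups = truth.duplicate_ids()
    flagged = report.flagged_ids()
    uni_tp = len(flagged & true_dups)
    uni_fp = len(flagged - true_dups)
    uni_fn = len(true_dups - flagged)

    calls_by_class: dict[str, int] = {"PSV": 0, "MSV": 0}
    true_by_class: dict[str, int] = {"PSV": 0, "MSV": 0}
    for c in calls:
        calls_by_class[c.site_class] += 1
        if (c.unigene_id, c.pos) in planted:
            true_by_class[c.site_class] += 1

    return TruthMetrics(
        site_tp=site_tp,
        site_fp=site_fp,
        site_fn=site_fn,
        unigene_tp=uni_tp,
        unigene_fp=uni_fp,
        unigene_fn=uni_fn,
        site_sensitivity=_ratio(site_tp, len(planted)),
        site_precision=_ratio(site_tp, len(called)),
        unigene_sensitivity=_ratio(uni_tp, len(true_dups)),
        unigene_precision=_ratio(uni_tp, len(flagged)),
        calls_by_class=calls_by_class,
        true_sites_by_class=true_by_class,
    )
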