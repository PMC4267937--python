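"""Simulator: determinism, quotas, planted-truth conservation."""

import numpy as np
import pytest

from dhdup.config import SimConfig
from dhdup.synth import TruthTable, simulate_reads, simulate_transcriptome


def tiny(**kw):
    defaults = dict(
        n_genes=10,
        dup_fraction=0.2,
        psv_per_dup=(1, 3),
        isoform_fraction=0.0,
        exon_count_range=(3, 4),
        exon_len_range=(150, 250),
        mean_coverage=20.0,
        error_rate=0.0,
        seed=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestTranscriptome:
    def test_degenerate_single_gene(self):
        unigenes, truth = simulate_transcriptome(tiny(n_genes=1, dup_fraction=0.0))
        assert len(unigenes) == 1
        assert truth.planted_sites() == set()
        assert truth.records[0].psv_sites == []

    def test_quota_sampling_is_exact(self):
        unigenes, truth = simulate_transcriptome(tiny(n_genes=100, dup_fraction=0.2))
        assert len(truth.duplicate_ids()) == 20
        assert len(unigenes) == 100

    def test_psv_count_forced_by_degenerate_range(self):
        _, truth = simulate_transcriptome(tiny(n_genes=50, psv_per_dup=(3, 3)))
        dups = [r for r in truth if r.is_duplicate]
        assert dups and all(len(r.psv_sites) == 3 for r in dups)

    def test_planted_positions_valid_and_spaced(self):
        cfg = tiny(n_genes=40, psv_per_dup=(2, 5), exon_count_range=(5, 6))
        unigenes, truth = simulate_transcriptome(cfg)
        by_id = {u.full_id: u for u in unigenes}
        for rec in truth:
            L = len(by_id[rec.record_id].sequence)
            positions = sorted(p for p, _, _ in rec.psv_sites)
            for p, ref, alt in rec.psv_sites:
                assert cfg.psv_end_margin <= p < L - cfg.psv_end_margin
                assert by_id[rec.record_id].sequence[p] == ref
                assert alt != ref and alt in "ACGT"
            assert all(
                b - a >= cfg.min_psv_spacing for a, b in zip(positions, positions[1:])
            )

    def test_non_duplicate_records_have_no_planted_sites(self):
        _, truth = simulate_transcriptome(tiny(n_genes=30, isoform_fraction=0.2))
        for rec in truth:
            if not rec.is_duplicate:
                assert rec.psv_sites == []

    def test_truth_table_complete_and_unique(self):
        unigenes, truth = simulate_transcriptome(tiny(n_genes=30, isoform_fraction=0.2))
        assert sorted(truth.by_id) == sorted(u.full_id for u in unigenes)

    def test_isoform_components_share_component_id(self):
        unigenes, truth = simulate_transcriptome(tiny(n_genes=30, isoform_fraction=0.2))
        events = truth.exon_skip_events()
        assert len(events) == round(0.2 * 30)
        by_id = {u.full_id: u for u in unigenes}
        for comp, full_id, skip_id, (s, e) in events:
            full, skip = by_id[full_id], by_id[skip_id]
            assert full.component_id == skip.component_id == comp
            # the skipped isoform is the full one with [s, e) excised
            assert skip.sequence == full.sequence[:s] + full.sequence[e:]

    def test_range_exhaustion_is_explicit_error(self):
        cfg = tiny(
            n_genes=10,
            dup_fraction=1.0,
            psv_per_dup=(8, 8),
            exon_count_range=(3, 3),
            exon_len_range=(150, 150),  # 450 bp cannot host 8 spaced sites
        )
        with pytest.raises(ValueError, match="too short"):
            simulate_transcriptome(cfg)

    def test_overallocated_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_transcriptome(tiny(dup_fraction=0.8, isoform_fraction=0.5,
                                        exon_count_range=(3, 4)))


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        cfg = tiny(n_genes=15, error_rate=0.01, isoform_fraction=0.2)
        u1, t1 = simulate_transcriptome(cfg)
        u2, t2 = simulate_transcriptome(cfg)
        assert [(u.full_id, u.sequence) for u in u1] == [(u.full_id, u.sequence) for u in u2]
        ra1, rb1 = simulate_reads(u1, t1, cfg)
        ra2, rb2 = simulate_reads(u2, t2, cfg)
        assert [(r.id, r.bases) for r in ra1] == [(r.id, r.bases) for r in ra2]
        assert [(r.id, r.bases) for r in rb1] == [(r.id, r.bases) for r in rb2]

    def test_different_seed_differs(self):
        u1, _ = simulate_transcriptome(tiny(seed=1))
        u2, _ = simulate_transcriptome(tiny(seed=2))
        assert [u.sequence for u in u1] != [u.sequence for u in u2]


class TestReads:
    def test_pair_count_formula(self):
        # one 900 bp unigene at 60x with 90 bp reads: 60*900/(2*90) = 300 pairs
        cfg = tiny(
            n_genes=1,
            dup_fraction=0.0,
            exon_count_range=(3, 3),
            exon_len_range=(300, 300),
            mean_coverage=60.0,
        )
        unigenes, truth = simulate_transcriptome(cfg)
        assert len(unigenes[0].sequence) == 900
        r1, r2 = simulate_reads(unigenes, truth, cfg)
        assert len(r1) == len(r2) == 300

    def test_zero_error_reads_match_reference_exactly(self):
        cfg = tiny(n_genes=5, dup_fraction=0.0, error_rate=0.0)
        unigenes, truth = simulate_transcriptome(cfg)
        by_id = {u.full_id: u.sequence for u in unigenes}
        r1, _ = simulate_reads(unigenes, truth, cfg)
        for read in r1:
            ref = by_id[read.id.rsplit(":", 1)[0]]
            assert read.bases in ref

    def test_hidden_haplotype_differs_only_at_planted_sites(self):
        cfg = tiny(n_genes=10, dup_fraction=0.5, psv_per_dup=(2, 4))
        unigenes, truth = simulate_transcriptome(cfg)
        for u in unigenes:
            rec = truth.by_id[u.full_id]
            hap_b = truth.alternate_haplotype(u.full_id, u.sequence)
            diffs = {i for i, (x, y) in enumerate(zip(u.sequence, hap_b)) if x != y}
            assert diffs == {p for p, _, _ in rec.psv_sites}

    def test_copy_b_fraction_near_expression_ratio(self):
        # single collapsed duplicate with one planted site: at that column the
        # copy-B allele fraction should sit within 5 binomial s.e. of 0.5
        cfg = tiny(
            n_genes=1,
            dup_fraction=1.0,
            psv_per_dup=(1, 1),
            exon_count_range=(4, 4),
            exon_len_range=(300, 300),
            mean_coverage=150.0,
            seed=17,
        )
        unigenes, truth = simulate_transcriptome(cfg)
        (u,) = unigenes
        (pos, ref, alt) = truth.records[0].psv_sites[0]
        r1, r2 = simulate_reads(unigenes, truth, cfg)
        n_alt = n_cov = 0
        for read in r1 + r2:
            # reconstruct placement from the deterministic fragment model:
            # locate read in either haplotype
            hap_b = truth.alternate_haplotype(u.full_id, u.sequence)
            for hap, is_b in ((u.sequence, False), (hap_b, True)):
                i = hap.find(read.bases)
                rc = read.bases[::-1].translate(str.maketrans("ACGT", "TGCA"))
                if i < 0:
                    i = hap.find(rc)
                if i >= 0:
                    if i <= pos < i + 90:
                        n_cov += 1
                        if is_b:
                            n_alt += 1
                    break
        assert n_cov > 100
        se = 0.5 / np.sqrt(n_cov)
        assert abs(n_alt / n_cov - 0.5) < 5 * se

    def test_short_unigene_skipped_with_warning(self, caplog):
        cfg = tiny(n_genes=1, dup_fraction=0.0, exon_count_range=(3, 3), exon_len_range=(150, 150))
        unigenes, truth = simulate_transcriptome(cfg)
        import dataclasses

        short_cfg = dataclasses.replace(cfg, read_len=900)
        import logging

        with caplog.at_level(logging.WARNING, logger="dhdup.synth"):
            r1, r2 = simulate_reads(unigenes, truth, short_cfg)
        assert r1 == [] and "skipping" in caplog.text

    def test_error_rate_perturbs_bases(self):
        cfg = tiny(n_genes=3, dup_fraction=0.0, error_rate=0.05)
        unigenes, truth = simulate_transcriptome(cfg)
        by_id = {u.full_id: u.sequence for u in unigenes}
        r1, _ = simulate_reads(unigenes, truth, cfg)
        mismatched = sum(r.bases not in by_id[r.id.rsplit(":", 1)[0]] for r in r1)
        # at 5% per-base error essentially every 90-bp read carries >= 1 error
        assert mismatched / len(r1) > 0.9


def test_truth_table_tsv_round_trip(tmp_path):
    cfg = tiny(n_genes=20, dup_fraction=0.3, isoform_fraction=0.2, exon_count_range=(3, 5))
    _, truth = simulate_transcriptome(cfg)
    path = tmp_path / "truth.tsv"
    truth.to_tsv(path)
    back = TruthTable.from_tsv(path)
    assert len(back) == len(truth)
    for a, b in zip(truth, back):
        assert (a.record_id, a.is_duplicate, a.psv_sites, a.isoform_mask, a.exon_lengths) == (
            b.record_id,
            b.is_duplicate,
            b.psv_sites,
            b.isoform_mask,
            b.exon_lengths,
        )
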