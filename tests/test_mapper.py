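"""Mapping: identity contract, seeds vs brute force, strand symmetry."""

import edlib
import numpy as np
import pytest

from dhdup.config import PipelineConfig
from dhdup.mapper import SeedIndex, map_all, map_read, read_alignments_tsv, write_alignments_tsv
from dhdup.unigene import Unigene, parse_unigene_id, revcomp

from conftest import make_read


def _random_unigenes(rng, n, length):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        Unigene(
            f"comp{i + 1}_c0_seq1",
            f"comp{i + 1}_c0",
            1,
            bases[rng.integers(0, 4, size=length)].tobytes().decode(),
        )
        for i in range(n)
    ]


class TestHeaderParsing:
    @pytest.mark.parametrize(
        "full_id,component,idx",
        [
            ("comp69204_c0_seq1", "comp69204_c0", 1),
            ("comp73211_c0_seq2", "comp73211_c0", 2),
            ("TRINITY_DN1000_c3_g1_i2", "TRINITY_DN1000_c3", 2),
        ],
    )
    def test_both_dialects(self, full_id, component, idx):
        assert parse_unigene_id(full_id) == (component, idx)

    def test_strict_rejects_garbage(self):
        with pytest.raises(ValueError):
            parse_unigene_id("contig_17")
        assert parse_unigene_id("contig_17", strict=False) is None

    def test_lenient_fallback_is_singleton_component(self):
        u = Unigene.from_header("contig_17", "ACGT", strict=False)
        assert u.component_id == "contig_17"


class TestSeedIndex:
    def test_seed_count_on_single_unigene(self):
        rng = np.random.default_rng(0)
        (u,) = _random_unigenes(rng, 1, 90)
        idx = SeedIndex([u], k=31)
        assert sum(len(v) for v in idx._kmers.values()) == 90 - 31 + 1

    def test_self_lookup_returns_true_position(self):
        rng = np.random.default_rng(1)
        (u,) = _random_unigenes(rng, 1, 200)
        idx = SeedIndex([u], k=31)
        assert (0, 50) in idx.lookup(u.sequence[50:81])

    def test_empty_set_maps_nothing(self, cfg):
        idx = SeedIndex([], k=21)
        assert map_read(make_read("ACGT" * 25), idx, cfg) == []

    def test_duplicate_id_is_hard_error(self):
        u = Unigene("comp1_c0_seq1", "comp1_c0", 1, "ACGT" * 30)
        with pytest.raises(ValueError):
            SeedIndex([u, u])

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            SeedIndex([], k=4)


class TestMapRead:
    @pytest.fixture
    def unigenes(self):
        rng = np.random.default_rng(42)
        return _random_unigenes(rng, 5, 500)

    @pytest.fixture
    def index(self, unigenes):
        return SeedIndex(unigenes, k=21)

    def test_exact_window_maps_with_identity_1(self, unigenes, index, cfg):
        read = make_read(unigenes[2].sequence[100:190])
        (aln,) = map_read(read, index, cfg)
        assert aln.unigene_id == unigenes[2].full_id
        assert (aln.start, aln.end, aln.strand) == (100, 190, "+")
        assert aln.identity == 1.0 and aln.edits == 0

    def test_one_mismatch_90bp(self, unigenes, index, cfg):
        """89/90 ~ 0.989 < 0.99: rejected under the literal rule, kept by default."""
        window = list(unigenes[2].sequence[100:190])
        window[45] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[45]]
        read = make_read("".join(window))
        (aln,) = map_read(read, index, cfg)
        assert aln.edits == 1 and aln.identity == pytest.approx(89 / 90)
        strict = PipelineConfig(strict_identity=True)
        assert map_read(read, index, strict) == []

    def test_one_mismatch_100bp_passes_strict_floor(self, unigenes, index):
        """floor(0.01 * 100) = 1 mismatch is within the literal 99% bound."""
        window = list(unigenes[2].sequence[100:200])
        window[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[50]]
        read = make_read("".join(window))
        strict = PipelineConfig(strict_identity=True)
        (aln,) = map_read(read, index, strict)
        assert aln.edits == 1 and aln.identity == pytest.approx(99 / 100)

    def test_strand_round_trip(self, unigenes, index, cfg):
        read = make_read(unigenes[3].sequence[200:290])
        rev = make_read(revcomp(read.bases))
        (fwd_aln,) = map_read(read, index, cfg)
        (rev_aln,) = map_read(rev, index, cfg)
        assert (fwd_aln.start, fwd_aln.end) == (rev_aln.start, rev_aln.end)
        assert fwd_aln.strand == "+" and rev_aln.strand == "-"
        assert rev_aln.bases == read.bases  # stored in reference orientation

    def test_cross_unigene_tie_discarded_by_default(self, cfg):
        rng = np.random.default_rng(3)
        (u1,) = _random_unigenes(rng, 1, 300)
        u2 = Unigene("comp2_c0_seq1", "comp2_c0", 1, u1.sequence)
        index = SeedIndex([u1, u2], k=21)
        read = make_read(u1.sequence[10:100])
        hits = map_read(read, index, cfg)
        assert len(hits) == 2  # caller applies the tie policy
        alns, summary = map_all([read], [u1, u2], cfg)
        assert alns == [] and summary.n_ambiguous == 1
        all_cfg = PipelineConfig(tie_policy="all")
        alns_all, _ = map_all([read], [u1, u2], all_cfg)
        assert {a.unigene_id for a in alns_all} == {u1.full_id, u2.full_id}

    def test_unmappable_read_yields_nothing(self, index, cfg):
        assert map_read(make_read("A" * 90), index, cfg) == []


def brute_force_best(read, unigenes, cfg):
    """Oracle: exhaustive semi-global alignment against every unigene/strand."""
    max_ed = cfg.max_edits(len(read))
    best_ed, hits = max_ed + 1, []
    for strand, seq in (("+", read.bases), ("-", revcomp(read.bases))):
        for u in unigenes:
            res = edlib.align(seq, u.sequence, mode="HW", k=max_ed)
            ed = res["editDistance"]
            if ed < 0:
                continue
            if ed < best_ed:
                best_ed, hits = ed, [(u.full_id, strand)]
            elif ed == best_ed and not any(h[0] == u.full_id for h in hits):
                hits.append((u.full_id, strand))
    return best_ed, hits


def test_seeded_mapping_equals_brute_force(cfg):
    """Seed-and-extend finds exactly the alignments exhaustive search finds."""
    rng = np.random.default_rng(2024)
    unigenes = _random_unigenes(rng, 20, 400)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads = []
    for i in range(100):
        u = unigenes[rng.integers(0, 20)]
        s = int(rng.integers(0, len(u.sequence) - 90 + 1))
        window = bytearray(u.sequence[s : s + 90], "ascii")
        for _ in range(int(rng.integers(0, 3))):  # 0-2 mutations
            p = int(rng.integers(0, 90))
            window[p] = bases[(int(np.searchsorted(bases, window[p])) + 1) % 4]
        seq = window.decode()
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(make_read(seq, rid=f"r{i}"))

    index = SeedIndex(unigenes, k=cfg.seed_k)
    for read in reads:
        seeded = map_read(read, index, cfg)
        oracle_ed, oracle_hits = brute_force_best(read, unigenes, cfg)
        assert {(a.unigene_id, a.strand) for a in seeded} == set(oracle_hits)
        if seeded:
            assert all(a.edits == oracle_ed for a in seeded)


def test_identity_contract_on_every_stored_alignment(cfg):
    rng = np.random.default_rng(5)
    unigenes = _random_unigenes(rng, 10, 300)
    reads = [
        make_read(u.sequence[i : i + 90], rid=f"{u.full_id}:{i}")
        for u in unigenes
        for i in (0, 100, 200)
    ]
    alignments, _ = map_all(reads, unigenes, cfg)
    assert alignments
    for a in alignments:
        assert a.edits <= cfg.max_edits(len(a.bases))
        assert 0 <= a.start < a.end <= 300


def test_alignment_tsv_round_trip(tmp_path, cfg):
    rng = np.random.default_rng(6)
    unigenes = _random_unigenes(rng, 3, 200)
    reads = [make_read(u.sequence[50:140], rid=u.full_id + ":r") for u in unigenes]
    alignments, _ = map_all(reads, unigenes, cfg)
    path = tmp_path / "aln.tsv"
    write_alignments_tsv(alignments, path)
    back = read_alignments_tsv(path)
    assert len(back) == len(alignments)
    for a, b in zip(alignments, back):
        assert (a.read_id, a.unigene_id, a.start, a.end, a.cigar) == (
            b.read_id,
            b.unigene_id,
            b.start,
            b.end,
            b.cigar,
        )
        assert list(a.quals) == list(b.quals)
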