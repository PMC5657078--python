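"""Seed-and-extend mapping: index construction, tiering, pairing, and the
exhaustive-scoring oracle."""

import logging
import random

import pytest

from bsvalid.aligner import (
    AlignParams,
    PERMISSIVE,
    STRICT,
    align_read_all_tasks,
    build_index,
    pair_mates,
    seed_and_extend,
    seed_offsets,
    two_tier_align,
)
from bsvalid.conversion import convert_c2t, prepare_reference, revcomp
from bsvalid.pipeline import PipelineConfig, run_pipeline
from bsvalid.seqio import Genome, ReadRecord
from bsvalid.simulate import SimConfig, simulate_genome, simulate_reads


def _ref(seq, *ks):
    conv = prepare_reference(Genome({"c1": seq}))
    for k in ks:
        build_index(conv, k)
    return conv


def brute_best_score(read: str, ref: str, params: AlignParams):
    """Independent oracle: exhaustively score the read at every reference
    offset (gap-free); returns (best score or None, argmax offsets)."""
    best, offsets = None, []
    for off in range(len(ref) - len(read) + 1):
        mm = sum(
            1 for a, b in zip(read, ref[off : off + len(read)]) if a != b or a == "N"
        )
        if mm > params.max_mismatches_converted:
            continue
        score = (len(read) - mm) * params.match_reward - mm * params.mismatch_penalty
        if best is None or score > best:
            best, offsets = score, [off]
        elif score == best:
            offsets.append(off)
    return best, offsets


def _has_clean_seed(read: str, ref: str, off: int, k: int) -> bool:
    for s in seed_offsets(len(read), k):
        seed = read[s : s + k]
        if "N" not in seed and ref[off + s : off + s + k] == seed:
            return True
    return False


class TestIndex:
    def test_enumeration(self):
        conv = _ref("ATGTATGA" * 3, 8)
        table = conv.indexes[("CT", 8)].table
        assert table["ATGTATGA"] == [("c1", 0), ("c1", 8), ("c1", 16)]
        assert all(0 <= off <= 24 - 8 for hits in table.values() for _, off in hits)

    def test_kmers_with_n_absent(self):
        conv = _ref("ATGTANGTATTG", 8)
        table = conv.indexes[("CT", 8)].table
        assert all("N" not in kmer for kmer in table)
        assert "GTATTG" not in table  # too short anyway; N split leaves <8-mers only
        assert table == {}

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            build_index(
                prepare_reference(Genome({})), 8
            )

    def test_k_longer_than_contig_rejected(self):
        with pytest.raises(ValueError, match="shortest contig"):
            _ref("ATGTA", 8)


def test_seed_offsets_cover_read_end():
    assert seed_offsets(75, 20) == [0, 20, 40, 55]
    assert seed_offsets(80, 20) == [0, 20, 40, 60]
    assert seed_offsets(8, 8) == [0]


class TestSeedAndExtend:
    def test_unique_zero_mismatch_placement(self):
        # brute force over every offset of the contig confirms offset 3 is
        # the unique 0-mismatch placement of this 12-mer
        contig = "TTGATGGATTTGTAATTGGA"
        read = "ATGGATTTGTAA"
        params = AlignParams(k=8, max_mismatches_converted=0)
        best, offs = brute_best_score(read, contig, params)
        assert (best, offs) == (12, [3])
        conv = _ref(contig, 8)
        cands = seed_and_extend(read, "CT", "forward", conv, params)
        assert len(cands) == 1
        assert (cands[0].start, cands[0].cigar, cands[0].conv_score) == (3, "12M", 12)

    def test_repeat_gives_tied_candidates_ordered_by_start(self):
        unit = "ATGGATTTGTAATG"
        contig = unit + "TTTTTTTT" + unit
        conv = _ref(contig, 8)
        params = AlignParams(k=8, max_mismatches_converted=0)
        cands = seed_and_extend(unit, "CT", "forward", conv, params)
        assert [c.start for c in cands] == [0, 22]
        assert cands[0].conv_score == cands[1].conv_score

    def test_all_n_read_maps_nowhere(self):
        conv = _ref("ATGGATTTGTAATGGA", 8)
        assert seed_and_extend("N" * 12, "CT", "forward", conv, AlignParams(k=8)) == []

    def test_short_read_warns_and_returns_empty(self, caplog):
        conv = _ref("ATGGATTTGTAATGGA", 8)
        with caplog.at_level(logging.WARNING, logger="bsvalid"):
            assert seed_and_extend("ATG", "CT", "forward", conv, AlignParams(k=8)) == []
        assert "shorter than seed" in caplog.text

    def test_reverse_orientation_reports_forward_coordinates(self):
        contig = "TTGATGGATTTGTAATTGGA"
        read = revcomp(contig[3:15])
        conv = _ref(contig, 8)
        cands = seed_and_extend(
            read, "CT", "reverse", conv, AlignParams(k=8, max_mismatches_converted=0)
        )
        assert [c.start for c in cands] == [3]

    def test_determinism(self):
        genome = simulate_genome(3000, 0.5, seed=9)
        conv = prepare_reference(genome)
        build_index(conv, 12)
        read = convert_c2t(genome.contigs["sim1"][500:560])
        params = AlignParams(k=12, max_mismatches_converted=3)
        a = seed_and_extend(read, "CT", "forward", conv, params)
        b = seed_and_extend(read, "CT", "forward", conv, params)
        assert a == b


def test_oracle_equivalence_over_random_cases():
    """Whenever some exhaustive-best offset has a clean seed, seed-and-extend
    attains exactly the exhaustive best score (gap-free, >=200 cases)."""
    rng = random.Random(42)
    checked = 0
    for _ in range(450):
        glen = rng.randint(200, 2000)
        genome = simulate_genome(glen, rng.uniform(0.3, 0.7), seed=rng.randrange(2**31))
        ct = convert_c2t(genome.contigs["sim1"])
        rlen = rng.randint(20, 50)
        start = rng.randrange(glen - rlen + 1)
        read = list(ct[start : start + rlen])
        for _ in range(rng.randint(0, 4)):  # plant substitutions
            read[rng.randrange(rlen)] = rng.choice("ACGT")
        read = "".join(read)
        k = rng.choice([8, 10, 12])
        params = AlignParams(k=k, max_mismatches_converted=rng.randint(0, 4))
        if rlen < k:
            continue
        best, offs = brute_best_score(read, ct, params)
        if best is None or not any(_has_clean_seed(read, ct, o, k) for o in offs):
            continue
        conv = prepare_reference(genome)
        build_index(conv, k)
        cands = seed_and_extend(read, "CT", "forward", conv, params)
        assert cands, f"no candidate despite clean seed (case {checked})"
        assert cands[0].conv_score == best
        checked += 1
    assert checked >= 200


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(genome_length=10_000, n_reads=40, seed=17,
                    conversion_failure=0.0, error_rate_start=0.0,
                    error_rate_end=0.0, directional=False)
    genome = simulate_genome(cfg.genome_length, cfg.gc_fraction, cfg.seed)
    reads, truths = simulate_reads(genome, {}, cfg)
    conv = prepare_reference(genome)
    build_index(conv, STRICT.k)
    return genome, conv, reads, truths


@pytest.fixture(scope="module")
def small_ref():
    genome = simulate_genome(5000, 0.5, seed=3)
    return genome, prepare_reference(genome)


class TestAllTasks:
    def test_true_locus_found_under_true_task(self, sim):
        _genome, conv, reads, truths = sim
        truth = {t.read_id: t for t in truths}
        for read in reads:
            t = truth[read.read_id]
            cands = align_read_all_tasks(read, conv, STRICT, "non-directional")
            best = cands[0]
            assert (best.task, best.contig, best.start) == (
                t.strand_task, t.contig, t.start
            )

    def test_directional_mode_disables_pcr_tasks(self, sim):
        _genome, conv, reads, truths = sim
        truth = {t.read_id: t for t in truths}
        ctob = [r for r in reads if truth[r.read_id].strand_task in ("CTOT", "CTOB")]
        assert ctob, "fixture should contain PCR-strand reads"
        read = ctob[0]
        t = truth[read.read_id]
        directional = align_read_all_tasks(read, conv, STRICT, "directional")
        assert not any(
            c.contig == t.contig and c.start == t.start for c in directional
        )
        full = align_read_all_tasks(read, conv, STRICT, "non-directional")
        assert any(c.start == t.start and c.task == t.strand_task for c in full)


class TestTwoTier:
    def test_clean_read_stays_tier1(self, small_ref):
        genome, ref = small_ref
        read = ReadRecord("a", genome.contigs["sim1"][100:175])
        out = two_tier_align([read], ref, STRICT, PERMISSIVE, "directional")
        assert out["a"] and all(c.tier == 1 for c in out["a"])

    def test_three_mismatches_fall_through_to_tier2(self, small_ref):
        genome, ref = small_ref
        seq = list(genome.contigs["sim1"][100:175])
        for pos in (5, 30, 60):
            seq[pos] = {"A": "G", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        read = ReadRecord("m3", "".join(seq))
        strict = AlignParams(k=20, max_mismatches_converted=2)
        permissive = AlignParams(k=12, max_mismatches_converted=4, allow_gaps=True)
        out = two_tier_align([read], ref, strict, permissive, "directional")
        assert out["m3"], "tier 2 should rescue the read"
        assert all(c.tier == 2 for c in out["m3"])
        assert any(c.start == 100 for c in out["m3"])

    def test_unalignable_read_empty_in_both_tiers(self, small_ref):
        genome, ref = small_ref
        rng = random.Random(1)
        read = ReadRecord("junk", "".join(rng.choice("ACGT") for _ in range(75)))
        # verified unmatchable by exhaustive scoring in converted space
        best, _ = brute_best_score(
            convert_c2t(read.seq), convert_c2t(genome.contigs["sim1"]), PERMISSIVE
        )
        assert best is None
        out = two_tier_align([read], ref, STRICT, PERMISSIVE, "directional")
        assert out["junk"] == []

    def test_tier2_never_removes_tier1_mapping(self, small_ref):
        genome, ref = small_ref
        reads = [
            ReadRecord(f"r{i}", genome.contigs["sim1"][i * 50 : i * 50 + 75])
            for i in range(20)
        ]
        with_t2 = two_tier_align(reads, ref, STRICT, PERMISSIVE, "directional")
        without = two_tier_align(reads, ref, STRICT, None, "directional")
        for rid, cands in without.items():
            if cands:
                assert with_t2[rid] == cands


class TestPairMates:
    def test_simulated_pair_round_trip(self):
        cfg = SimConfig(genome_length=8000, n_reads=15, seed=21, paired=True,
                        conversion_failure=0.0, error_rate_start=0.0,
                        error_rate_end=0.0, insert_mean=200.0, insert_sd=20.0)
        genome = simulate_genome(cfg.genome_length, cfg.gc_fraction, cfg.seed)
        reads, truths = simulate_reads(genome, {}, cfg)
        conv = prepare_reference(genome)
        build_index(conv, STRICT.k)
        truth = {t.read_id: t for t in truths}
        for i in range(0, len(reads), 2):
            r1, r2 = reads[i], reads[i + 1]
            c1 = align_read_all_tasks(r1, conv, STRICT, "directional")
            c2 = align_read_all_tasks(r2, conv, STRICT, "directional")
            pairs = pair_mates(c1, c2, 100, 500)
            assert pairs, f"no proper pair for {r1.read_id}"
            a, b = pairs[0]
            assert a.start == truth[f"{r1.read_id}/1"].start
            assert b.start == truth[f"{r1.read_id}/2"].start
            # narrow window excludes the true insert
            assert pair_mates(c1, c2, 100, 150) == []

    def test_unmapped_mate_gives_no_pairs(self):
        genome = simulate_genome(5000, 0.5, seed=3)
        conv = prepare_reference(genome)
        build_index(conv, STRICT.k)
        r1 = ReadRecord("p", genome.contigs["sim1"][100:175])
        c1 = align_read_all_tasks(r1, conv, STRICT, "directional")
        assert pair_mates(c1, [], 0, 1000) == []
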