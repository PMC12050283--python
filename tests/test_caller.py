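"""Concatemer decomposition, identification filters and locus calling."""

import edlib
import numpy as np
import pytest

from eccforge._seq import mutate_positions, random_seq, revcomp
from eccforge.caller import (
    CallerParams,
    EccLocus,
    ReadCandidate,
    ReadTooShortError,
    TandemDecomposition,
    call_loci,
    call_sample,
    decompose_concatemer,
    is_genomic_tandem,
    map_consensus,
    passes_unit_filters,
    process_read,
)
from eccforge.mapper import map_query
from eccforge.sim import ReadSimConfig, plant_circles, simulate_background_reads, \
    simulate_rca_reads
from eccforge.sim.circles import monomer_sequence, single_fragment_template

PARAMS = CallerParams()


class TestDecompose:
    def test_error_free_four_copy_concatemer(self):
        rng = np.random.default_rng(0)
        monomer = random_seq(500, rng)
        dec = decompose_concatemer(monomer * 4, PARAMS)
        assert dec is not None
        assert 495 <= dec.unit_length <= 505
        assert 3.8 <= dec.n_units <= 4.2
        assert dec.unit_divergence < 0.01
        # consensus recovers a rotation of the monomer
        doubled = monomer * 2
        assert dec.consensus in doubled

    def test_random_sequence_yields_none(self):
        rng = np.random.default_rng(1)
        assert decompose_concatemer(random_seq(2000, rng), PARAMS) is None

    def test_divergence_matches_pairwise_edit_distance_oracle(self):
        # three copies, each independently carrying 10% substitutions:
        # expected adjacent-unit divergence ~ 2p(1-p) + collision terms
        rng = np.random.default_rng(2)
        monomer = random_seq(600, rng)
        units = [mutate_positions(monomer, 60, rng) for _ in range(3)]
        read = "".join(units)
        dec = decompose_concatemer(read, PARAMS)
        assert dec is not None
        assert dec.unit_divergence == pytest.approx(0.18, abs=0.05)
        # independent oracle: brute edit distance between the true units
        oracle = np.mean([
            edlib.align(units[0], units[1], task="distance")["editDistance"],
            edlib.align(units[1], units[2], task="distance")["editDistance"],
        ]) / 600
        assert dec.unit_divergence == pytest.approx(oracle, abs=0.03)

    def test_too_short_read_raises(self):
        with pytest.raises(ReadTooShortError):
            decompose_concatemer("ACGT" * 5, PARAMS)

    def test_partial_pass_gives_fractional_unit_count(self):
        rng = np.random.default_rng(3)
        monomer = random_seq(400, rng)
        dec = decompose_concatemer(monomer * 3 + monomer[:200], PARAMS)
        assert dec is not None
        assert 3.3 <= dec.n_units <= 3.7


class TestUnitFilters:
    @pytest.mark.parametrize(
        "unit_length,n_units,divergence,expected",
        [
            (199, 3.0, 0.05, False),   # below the 200 bp floor
            (200, 3.0, 0.05, True),    # exactly at the floor
            (250, 1.6, 0.05, False),   # fewer than two repeat units
            (250, 2.0, 0.05, True),    # exactly two units
            (250, 2.5, 0.24, True),    # below the divergence bound
            (250, 2.5, 0.25, True),    # bound is inclusive ("exceeding" rejects)
            (250, 2.5, 0.2501, False), # strictly above
        ],
    )
    def test_filter_boundaries(self, unit_length, n_units, divergence, expected):
        dec = TandemDecomposition("r", unit_length, n_units, divergence, "A" * unit_length)
        assert passes_unit_filters(dec, PARAMS) is expected


class TestMapConsensus:
    def test_exact_substring_maps_fully_at_identity_one(self, genome, genome_index):
        query = genome.fetch("chr01", 20_000, 20_800)
        segs = map_consensus(query, genome_index)
        best = max(segs, key=lambda s: s.n_seed_bases)
        assert (best.chrom, best.ref_start, best.ref_end) == ("chr01", 20_000, 20_800)
        assert best.strand == "+" and best.identity == 1.0
        assert best.read_start == 0 and best.read_end == 800

    def test_reverse_complement_maps_on_minus_strand(self, genome, genome_index):
        query = revcomp(genome.fetch("chr02", 40_000, 40_600))
        segs = map_consensus(query, genome_index)
        best = max(segs, key=lambda s: s.n_seed_bases)
        assert best.strand == "-"
        assert (best.ref_start, best.ref_end) == (40_000, 40_600)

    def test_two_percent_substitutions_keep_boundaries_within_10bp(self, genome, genome_index):
        rng = np.random.default_rng(4)
        query = mutate_positions(genome.fetch("chr01", 55_000, 55_700), 14, rng)
        segs = map_consensus(query, genome_index)
        best = max(segs, key=lambda s: s.n_seed_bases)
        assert abs(best.ref_start - 55_000) <= 10
        assert abs(best.ref_end - 55_700) <= 10

    def test_foreign_sequence_has_no_hits(self, genome_index):
        rng = np.random.default_rng(5)
        assert map_consensus(random_seq(500, rng), genome_index) == []


class TestGenomicTandemExclusion:
    def test_planted_tandem_read_is_excluded(self, genome, genome_index):
        reads, _ = simulate_background_reads(genome, 0, 5, seed=10)
        for seq in reads.values():
            assert is_genomic_tandem(seq, genome_index, PARAMS)

    def test_linear_read_is_excluded(self, genome, genome_index):
        reads, _ = simulate_background_reads(genome, 5, 0, seed=10)
        for seq in reads.values():
            assert is_genomic_tandem(seq, genome_index, PARAMS)

    def test_rca_read_of_a_circle_is_not_excluded(self, genome, genome_index):
        tpl = plant_circles(genome, 1, 0, seed=12, single_lengths=[500])
        cfg = ReadSimConfig(seed=12, n_reads_per_template=3, mean_full_passes=5)
        reads, _ = simulate_rca_reads(genome, tpl, cfg)
        for seq in reads.values():
            assert not is_genomic_tandem(seq, genome_index, PARAMS)


def _candidate(read_id, start, end, af=1.0, chrom="chr01"):
    return ReadCandidate(read_id, chrom, start, end, af)


class TestCallLoci:
    def test_three_reads_make_one_locus_two_do_not(self):
        reads3 = [_candidate(f"r{i}", 1000, 1500) for i in range(3)]
        assert len(call_loci(reads3, PARAMS, "s")) == 1
        assert call_loci(reads3[:2], PARAMS, "s") == []

    def test_low_aligned_fraction_read_does_not_count(self):
        cands = [_candidate(f"r{i}", 1000, 1500) for i in range(3)]
        cands.append(_candidate("r_low", 1000, 1500, af=0.7))
        (locus,) = call_loci(cands, PARAMS, "s")
        assert locus.n_reads == 3

    def test_interval_is_member_median(self):
        cands = [
            _candidate("a", 1000, 1500),
            _candidate("b", 1004, 1508),
            _candidate("c", 1010, 1510),
        ]
        (locus,) = call_loci(cands, PARAMS, "s")
        assert (locus.start, locus.end) == (1004, 1508)

    def test_raising_min_reads_never_adds_loci(self):
        rng = np.random.default_rng(6)
        cands = []
        for i in range(30):
            start = int(rng.integers(0, 50_000))
            for j in range(int(rng.integers(1, 6))):
                cands.append(_candidate(f"r{i}_{j}", start, start + 400))
        previous = None
        for min_reads in (1, 2, 3, 4, 5):
            params = CallerParams(min_locus_reads=min_reads)
            n = len(call_loci(cands, params, "s"))
            if previous is not None:
                assert n <= previous
            previous = n

    def test_batch_order_does_not_matter(self):
        rng = np.random.default_rng(7)
        cands = [_candidate(f"r{i}", int(rng.integers(0, 20_000)), 0) for i in range(40)]
        cands = [ReadCandidate(c.read_id, c.chrom, c.start, c.start + 300, 1.0)
                 for c in cands]
        a = call_loci(cands, PARAMS, "s")
        b = call_loci(list(reversed(cands)), PARAMS, "s")
        assert [(l.chrom, l.start, l.end, l.n_reads) for l in a] == \
               [(l.chrom, l.start, l.end, l.n_reads) for l in b]


class TestEndToEnd:
    def test_planted_circles_recovered_with_tight_boundaries(self, genome, genome_index):
        templates = plant_circles(genome, 8, 0, seed=13)
        cfg = ReadSimConfig(seed=13, n_reads_per_template=6)
        reads, _ = simulate_rca_reads(genome, templates, cfg)
        loci, audit = call_sample(reads, genome_index, PARAMS, "S1")
        assert len(loci) == len(templates)
        truth = sorted((t.fragments[0][0], t.fragments[0][1], t.fragments[0][2])
                       for t in templates)
        called = sorted((l.chrom, l.start, l.end) for l in loci)
        for (tc, ts, te), (cc, cs, ce) in zip(truth, called):
            assert tc == cc and abs(ts - cs) <= 20 and abs(te - ce) <= 20

    def test_all_emitted_loci_respect_floor_invariants(self, genome, genome_index):
        templates = plant_circles(genome, 6, 0, seed=14)
        cfg = ReadSimConfig(seed=14, sub_rate=0.01, ins_rate=0.005, del_rate=0.005)
        reads, _ = simulate_rca_reads(genome, templates, cfg)
        loci, _ = call_sample(reads, genome_index, PARAMS, "S1")
        for locus in loci:
            assert locus.length >= PARAMS.min_unit_length
            assert locus.n_reads >= PARAMS.min_locus_reads
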