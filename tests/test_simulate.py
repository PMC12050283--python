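"""Synthetic-data generator: determinism, construction identities, rates."""

import numpy as np
import pytest

from eccforge._seq import revcomp
from eccforge.sim import (
    CountSimDesign,
    GenomeSpec,
    LTR_SUPERFAMILIES,
    ReadSimConfig,
    SizingError,
    generate_genome,
    monomer_sequence,
    plant_circles,
    simulate_background_reads,
    simulate_count_matrix,
    simulate_rca_reads,
)


class TestGenerateGenome:
    def test_counts_and_lengths_match_spec(self, genome):
        spec = genome.spec
        assert len(genome.seqs) == spec.n_chromosomes
        assert all(len(s) == spec.chrom_length for s in genome.seqs.values())
        assert len(genome.genes) == spec.n_genes
        assert len(genome.track("TE")) == spec.n_tes
        assert len(genome.track("repeat_unit")) == spec.n_repeat_units
        assert len(genome.tandem_arrays) == spec.n_genomic_tandem_arrays

    def test_same_seed_is_byte_identical(self):
        a = generate_genome(GenomeSpec(seed=5))
        b = generate_genome(GenomeSpec(seed=5))
        assert a.seqs == b.seqs
        assert a.genes == b.genes
        assert a.tracks == b.tracks

    def test_empty_te_track_leaves_others_untouched(self):
        g = generate_genome(GenomeSpec(seed=5, n_tes=0))
        assert g.track("TE") == []
        assert len(g.genes) == GenomeSpec().n_genes

    def test_genes_tile_and_do_not_overlap(self, genome):
        for g in genome.genes:
            ivs = sorted(g.utr5 + g.cds_exons + g.utr3)
            assert ivs[0][0] == g.start and ivs[-1][1] == g.end
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 == s2  # contiguous tiling
        by_chrom = {}
        for g in genome.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(e1 <= s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))

    def test_tandem_arrays_are_literal_repeats(self, genome):
        for arr in genome.tandem_arrays:
            seq = genome.fetch(arr.chrom, arr.start, arr.end)
            mono = seq[: arr.monomer_length]
            copies = arr.length // arr.monomer_length
            assert copies >= 3
            assert seq == mono * copies

    def test_chromosome_too_small_raises(self):
        with pytest.raises(SizingError):
            generate_genome(GenomeSpec(chrom_length=20_000))


class TestPlantCircles:
    def test_single_sizes_within_printed_range(self, genome):
        templates = plant_circles(genome, 100, 0, seed=3)
        assert all(200 <= t.total_length <= 37_000 for t in templates)

    def test_forced_fragment_count(self, genome):
        templates = plant_circles(genome, 0, 5, seed=3, fragment_count=5)
        assert all(len(t.fragments) == 5 for t in templates)

    def test_cross_chromosome_template_exists(self, genome):
        templates = plant_circles(genome, 0, 4, seed=3)
        chroms_per = [{f[0] for f in t.fragments} for t in templates]
        assert any(len(c) > 1 for c in chroms_per)

    def test_ltr_flanked_pair_gap_contains_single_subfamily_ltr(self, genome):
        (t,) = plant_circles(genome, 0, 0, seed=3, n_ltr_flanked=1)
        assert t.origin_tag == "ltr_flanked_pair"
        (c1, _, gap_lo, _), (c2, gap_hi, _, _) = t.fragments
        assert c1 == c2
        inside = [f for f in genome.track("TE")
                  if f.superfamily in LTR_SUPERFAMILIES
                  and f.chrom == c1 and f.start >= gap_lo and f.end <= gap_hi]
        assert inside
        assert len({f.subfamily for f in inside}) == 1

    def test_total_length_is_sum_of_fragments(self, genome):
        for t in plant_circles(genome, 5, 5, seed=3):
            assert t.total_length == sum(e - s for _, s, e, _ in t.fragments)


class TestSimulateRcaReads:
    def test_error_free_read_is_a_rotation_of_the_monomer(self, genome):
        tpl = plant_circles(genome, 1, 0, seed=4, single_lengths=[500])
        cfg = ReadSimConfig(seed=4, n_reads_per_template=4, revcomp_prob=0.0)
        reads, truth = simulate_rca_reads(genome, tpl, cfg)
        monomer = monomer_sequence(genome, tpl[0])
        for row in truth.itertuples():
            seq = reads[row.read_id]
            rot = monomer[row.phase_offset:] + monomer[: row.phase_offset]
            assert seq == (rot * 40)[: len(seq)]
            # rotation by one monomer maps the read onto itself
            assert seq[500:] == seq[: len(seq) - 500]

    def test_revcomp_reads_reconstruct_after_flip(self, genome):
        tpl = plant_circles(genome, 1, 0, seed=4, single_lengths=[400])
        cfg = ReadSimConfig(seed=5, n_reads_per_template=8, revcomp_prob=1.0)
        reads, truth = simulate_rca_reads(genome, tpl, cfg)
        monomer = monomer_sequence(genome, tpl[0])
        for row in truth.itertuples():
            seq = revcomp(reads[row.read_id])
            rot = monomer[row.phase_offset:] + monomer[: row.phase_offset]
            assert seq == (rot * 40)[: len(seq)]

    def test_substitution_rate_matches_truth_counts(self, genome):
        tpl = plant_circles(genome, 2, 0, seed=6, single_lengths=[2000, 3000])
        cfg = ReadSimConfig(seed=6, n_reads_per_template=10, sub_rate=0.02)
        reads, truth = simulate_rca_reads(genome, tpl, cfg)
        total = truth.read_length.sum()
        assert total >= 50_000
        rate = truth.n_sub.sum() / total
        assert rate == pytest.approx(0.02, abs=0.005)
        assert (truth.n_ins == 0).all() and (truth.n_del == 0).all()

    def test_zero_reads_per_template_is_empty(self, genome):
        tpl = plant_circles(genome, 1, 0, seed=4)
        reads, truth = simulate_rca_reads(
            genome, tpl, ReadSimConfig(seed=4, n_reads_per_template=0))
        assert reads == {} and len(truth) == 0

    def test_one_truth_row_per_read_and_min_one_pass(self, genome):
        tpl = plant_circles(genome, 3, 1, seed=7)
        reads, truth = simulate_rca_reads(genome, tpl, ReadSimConfig(seed=7))
        assert sorted(truth.read_id) == sorted(reads)
        assert truth.read_id.is_unique
        assert (truth.n_passes >= 1).all()

    def test_determinism(self, genome):
        tpl = plant_circles(genome, 2, 1, seed=8)
        cfg = ReadSimConfig(seed=8, sub_rate=0.02, ins_rate=0.01, del_rate=0.01)
        r1, t1 = simulate_rca_reads(genome, tpl, cfg)
        r2, t2 = simulate_rca_reads(genome, tpl, cfg)
        assert r1 == r2 and t1.equals(t2)


class TestBackgroundReads:
    def test_linear_read_is_contiguous_genomic_substring(self, genome):
        reads, truth = simulate_background_reads(genome, 10, 0, seed=9)
        for row in truth.itertuples():
            seq = reads[row.read_id]
            if row.strand == "-":
                seq = revcomp(seq)
            assert seq == genome.fetch(row.chrom, row.start, row.end)

    def test_tandem_read_spans_at_least_two_monomers(self, genome):
        reads, truth = simulate_background_reads(genome, 0, 10, seed=9)
        arrays = {(a.chrom): a for a in genome.tandem_arrays}
        for row in truth.itertuples():
            assert row.background_kind == "genomic_tandem"
            assert row.end - row.start >= 2 * row.monomer_length

    def test_empty_request_gives_empty_output(self, genome):
        reads, truth = simulate_background_reads(genome, 0, 0, seed=9)
        assert reads == {} and len(truth) == 0


class TestCountMatrix:
    def test_exclusive_features_are_present_absent_by_construction(self):
        design = CountSimDesign(seed=1)
        counts, truth = simulate_count_matrix(design)
        a_cols = [s for s in counts.columns if s.startswith("A_")]
        b_cols = [s for s in counts.columns if s.startswith("B_")]
        ex_b = counts.loc[truth == "exclusive_B"]
        assert (ex_b[a_cols] == 0).all().all()
        assert (ex_b[b_cols] > 0).all().all()
        ex_a = counts.loc[truth == "exclusive_A"]
        assert (ex_a[b_cols] == 0).all().all()
        assert (ex_a[a_cols] > 0).all().all()

    def test_full_zero_inflation_gives_all_zero_matrix(self):
        design = CountSimDesign(seed=1, zero_inflation_pi=1.0,
                                n_exclusive_a=0, n_exclusive_b=0, n_differential=0)
        counts, _ = simulate_count_matrix(design)
        assert (counts == 0).all().all()

    def test_null_zero_fraction_matches_pi(self):
        design = CountSimDesign(seed=2, n_exclusive_a=0, n_exclusive_b=0,
                                n_differential=0)
        counts, truth = simulate_count_matrix(design)
        assert (truth == "null").all()
        zero_frac = (counts == 0).values.mean()
        assert zero_frac == pytest.approx(0.3, abs=0.02)

    def test_planted_sets_are_disjoint_and_counted(self):
        design = CountSimDesign(seed=3)
        _, truth = simulate_count_matrix(design)
        assert (truth == "exclusive_A").sum() == design.n_exclusive_a
        assert (truth == "exclusive_B").sum() == design.n_exclusive_b
        assert truth.str.startswith("differential").sum() == design.n_differential
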