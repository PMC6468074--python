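"""Translated Smith-Waterman target identification."""

import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from capmark import LocusSequence, call_target, smith_waterman_protein, split_outputs
from capmark.simulate import SimulationConfig, simulate_capture

from oracles import sw_score_enumeration, sw_score_oracle

AMINO = "ARNDCQEGHIKLMNPQSTVWY"


class TestSmithWaterman:
    def test_identical_triplet_scores_diagonal_sum(self):
        # BLOSUM62 diagonal: M=5, K=5, T=5
        aln = smith_waterman_protein("MKT", "MKT")
        assert aln.score == 15.0
        assert aln.query_span == (0, 3)

    def test_empty_sequence_scores_zero(self):
        aln = smith_waterman_protein("", "MKT")
        assert aln.score == 0.0
        assert aln.query_span == (0, 0)

    def test_self_score_is_diagonal_sum(self, rng):
        m = substitution_matrices.load("BLOSUM62")
        for _ in range(20):
            s = "".join(rng.choice(list(AMINO), size=rng.integers(1, 15)))
            expected = sum(float(m[c, c]) for c in s)
            assert smith_waterman_protein(s, s).score == expected

    def test_symmetric_in_arguments(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list(AMINO), size=rng.integers(1, 10)))
            b = "".join(rng.choice(list(AMINO), size=rng.integers(1, 10)))
            assert (
                smith_waterman_protein(a, b).score
                == smith_waterman_protein(b, a).score
            )

    def test_matches_bruteforce_on_random_pairs(self, rng):
        for _ in range(60):
            a = "".join(rng.choice(list(AMINO), size=rng.integers(0, 9)))
            b = "".join(rng.choice(list(AMINO), size=rng.integers(0, 9)))
            assert smith_waterman_protein(a, b).score == sw_score_oracle(a, b)

    def test_oracle_agrees_with_pure_enumeration(self, rng):
        """Validates the recursion oracle itself at enumerable sizes."""
        for _ in range(15):
            a = "".join(rng.choice(list(AMINO), size=rng.integers(0, 5)))
            b = "".join(rng.choice(list(AMINO), size=rng.integers(0, 5)))
            assert sw_score_oracle(a, b) == sw_score_enumeration(a, b)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman_protein("M@T", "MKT")


def _single_locus_capture(seed, coding_rate=0.0):
    cfg = SimulationConfig(
        seed=seed, n_loci=1, taxa_per_group=1, groups=("G1",),
        flank_len_mean=60.0, flank_len_sd=10.0, exon_len_range=(60, 150),
        coding_rate=coding_rate,
    )
    cap = simulate_capture(cfg)
    locus = cap.loci[0]
    taxon = next(iter(cap.contigs))
    return cap, locus, cap.contigs[taxon][locus], cap.exon_spans[(taxon, locus)]


class TestCallTarget:
    def test_exact_match_with_symmetric_flanks(self):
        exon = "ATGAAAACCGGGCATCATCATCATCATCATGCCGCCGCCGCCGCCGCCTTTGGGCATAAA"  # 60 nt
        bait = str(Seq(exon).translate())
        contig = LocusSequence(
            locus_id="c1", sequence="A" * 30 + exon + "C" * 30
        )
        call = call_target("L1", bait, [contig])
        assert call.exon_span == (30, 90)
        assert call.left_flank_len == 30 and call.right_flank_len == 30
        assert call.exon_sequence == exon

    def test_below_threshold_returns_none(self):
        contig = LocusSequence(locus_id="c1", sequence="ACGT" * 30)
        assert call_target("L1", "WWWWWWWW", [contig], min_score=40) is None

    def test_reverse_complement_contig_yields_identical_exon(self):
        cap, locus, contig, span = _single_locus_capture(seed=11)
        rc = LocusSequence(
            locus_id=contig.locus_id, taxon=contig.taxon,
            sequence=str(Seq(contig.sequence).reverse_complement()),
        )
        fwd = call_target(locus, cap.bait_proteins[locus], [contig])
        rev = call_target(locus, cap.bait_proteins[locus], [rc])
        assert fwd.frame > 0 > rev.frame
        assert fwd.exon_sequence == rev.exon_sequence
        assert fwd.exon_span == rev.exon_span == span

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_exon_recovered_under_mild_divergence(self, seed):
        """~3.5%-per-site coding divergence still yields exact span recovery."""
        cap, locus, contig, span = _single_locus_capture(seed, coding_rate=0.035)
        call = call_target(locus, cap.bait_proteins[locus], [contig])
        assert call is not None
        assert call.exon_span == span

    def test_best_contig_wins_over_decoy(self):
        cap, locus, contig, span = _single_locus_capture(seed=13)
        decoy = LocusSequence(locus_id="decoy", sequence="ACGT" * 60)
        call = call_target(locus, cap.bait_proteins[locus], [decoy, contig])
        assert call.contig_id == contig.header

    def test_score_tie_broken_by_longer_then_smaller_id(self):
        exon = "ATGAAAACCGGGCATCATCATCATCATCATGCCGCCGCCGCCGCCGCC"
        bait = str(Seq(exon).translate())
        short = LocusSequence(locus_id="a_short", sequence=exon)
        long_b = LocusSequence(locus_id="b_long", sequence=exon + "ACGTAA")
        long_c = LocusSequence(locus_id="c_long", sequence=exon + "GGGTTT")
        call = call_target("L1", bait, [short, long_c, long_b])
        assert call.contig_id == "b_long"

    def test_empty_contig_list_rejected(self):
        with pytest.raises(ValueError):
            call_target("L1", "MKT", [])


class TestSplitOutputs:
    def test_flanked_record_longer_by_flank_sum(self):
        cap, locus, contig, span = _single_locus_capture(seed=5)
        call = call_target(locus, cap.bait_proteins[locus], [contig])
        exon_recs, flank_recs = split_outputs([call])
        assert len(flank_recs[0].sequence) - len(exon_recs[0].sequence) == (
            call.left_flank_len + call.right_flank_len
        )
        assert flank_recs[0].exon_span == call.exon_span

    def test_zero_calls_give_empty_outputs(self):
        assert split_outputs([]) == ([], [])

    def test_id_sets_identical_across_both_outputs(self):
        calls = []
        for seed in range(4):
            cap, locus, contig, _ = _single_locus_capture(seed)
            calls.append(call_target(locus, cap.bait_proteins[locus], [contig]))
        exon_recs, flank_recs = split_outputs(calls)
        assert [r.locus_id for r in exon_recs] == [r.locus_id for r in flank_recs]
        assert len(exon_recs) == 4
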