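"""Flank filtering, consensus references, and one-best-SNP export."""

import numpy as np

from capmark.metrics import SiteAlignment
from capmark.simulate import SimulationConfig, simulate_capture
from capmark.variation import (
    LONG_INDEL,
    PASS,
    TOO_SHORT,
    UNALIGNABLE,
    Flank,
    filter_flanks,
    flank_variability,
    majority_consensus,
    select_best_snp,
    snp_density_per_kb,
    snp_sites,
)


def _flank(seq, taxon="t1", locus="L1", side="left"):
    return Flank(locus_id=locus, taxon=taxon, side=side, sequence=seq)


class TestFilterFlanks:
    def test_19nt_flank_too_short(self):
        (f,) = filter_flanks([_flank("A" * 19)])
        assert f.status == TOO_SHORT

    def test_zero_length_flank_too_short(self):
        (f,) = filter_flanks([_flank("")])
        assert f.status == TOO_SHORT

    def test_20nt_flank_passes_length_rule(self):
        (f,) = filter_flanks([_flank("A" * 20)])
        assert f.status == PASS

    def test_long_gap_run_flagged(self):
        seq = "A" * 30 + "-" * 40 + "A" * 30
        (f,) = filter_flanks([_flank(seq)], max_gap_run=30)
        assert f.status == LONG_INDEL

    def test_divergent_flank_unalignable(self):
        base = "ACGTACGTACGTACGTACGTACGTACGT"
        flipped = "TGCATGCATGCATGCATGCATGCATGCA"
        flanks = [
            _flank(base, taxon="t1"),
            _flank(base, taxon="t2"),
            _flank(flipped, taxon="t3"),
        ]
        result = {f.taxon: f.status for f in filter_flanks(flanks, max_pdist=0.6)}
        assert result["t1"] == result["t2"] == PASS
        assert result["t3"] == UNALIGNABLE

    def test_sequences_never_modified(self):
        flanks = [_flank("A" * 10), _flank("C" * 50, taxon="t2")]
        out = filter_flanks(flanks)
        assert [f.sequence for f in out] == [f.sequence for f in flanks]


class TestFlankVariability:
    def test_identical_flanks_zero_pdist(self):
        flanks = [_flank("ACGT" * 10, taxon=t) for t in ("t1", "t2")]
        stats = flank_variability(filter_flanks(flanks))
        assert stats["pdists"] == [0.0]

    def test_three_flanks_give_three_pairs(self):
        flanks = [_flank("ACGT" * 10, taxon=t) for t in ("t1", "t2", "t3")]
        stats = flank_variability(filter_flanks(flanks))
        assert len(stats["pdists"]) == 3

    def test_flank_density_exceeds_coding_density(self):
        """Flanks mutated faster than coding yield a higher SNP density."""
        cfg = SimulationConfig(
            seed=3, n_loci=12, taxa_per_group=2, groups=("Ga", "Gb"),
            flank_len_mean=300.0, flank_len_sd=30.0,
            coding_rate=0.035, flank_rate=0.050,
        )
        cap = simulate_capture(cfg)
        coding = [a for a in (cap.coding_alignment(l) for l in cap.loci) if a]
        flanks = [
            a
            for l in cap.loci
            for a in (cap.flank_alignment(l, "left"), cap.flank_alignment(l, "right"))
            if a
        ]
        assert snp_density_per_kb(flanks) > snp_density_per_kb(coding)


class TestMajorityConsensus:
    def _aln(self, *rows):
        return SiteAlignment(taxa=[f"t{i}" for i in range(len(rows))], rows=list(rows))

    def test_simple_majority(self):
        assert majority_consensus(self._aln("A", "A", "C")) == "A"

    def test_tie_becomes_iupac_code(self):
        assert majority_consensus(self._aln("A", "A", "C", "C")) == "M"

    def test_majority_gap_column_omitted(self):
        assert majority_consensus(self._aln("-A", "-A", "AA")) == "A"

    def test_all_missing_column_is_n(self):
        assert majority_consensus(self._aln("NA", "NA", "NA")) == "NA"

    def test_identical_rows_reproduce_row(self):
        row = "ACGTTGCA"
        assert majority_consensus(self._aln(row, row, row)) == row


VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=L1>
##contig=<ID=L2>
##contig=<ID=L3>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
"""


def _write_vcf(tmp_path, body):
    path = tmp_path / "calls.vcf"
    path.write_text(VCF_HEADER + body)
    return path


class TestSelectBestSnp:
    def test_highest_qual_snp_kept_per_locus(self, tmp_path):
        body = (
            "L1\t10\t.\tA\tC\t50\t.\t.\tGT\t0/1\t1/1\n"
            "L1\t40\t.\tG\tT\t99\t.\t.\tGT\t0/0\t0/1\n"
        )
        matrix, choices = select_best_snp(_write_vcf(tmp_path, body))
        assert [c.position for c in choices] == [40]
        assert matrix.loc["s1", "L1"] == 0.0
        assert matrix.loc["s2", "L1"] == 1.0

    def test_indel_only_locus_absent(self, tmp_path):
        body = (
            "L1\t10\t.\tA\tC\t50\t.\t.\tGT\t0/1\t1/1\n"
            "L2\t5\t.\tAT\tA\t99\t.\t.\tGT\t0/1\t0/1\n"
        )
        matrix, _ = select_best_snp(_write_vcf(tmp_path, body))
        assert list(matrix.columns) == ["L1"]

    def test_multiallelic_snp_dropped(self, tmp_path):
        body = "L3\t7\t.\tA\tC,G\t80\t.\t.\tGT\t0/1\t0/2\n"
        matrix, _ = select_best_snp(_write_vcf(tmp_path, body))
        assert matrix.empty or "L3" not in matrix.columns

    def test_missing_genotype_is_nan(self, tmp_path):
        body = "L1\t10\t.\tA\tC\t50\t.\t.\tGT\t./.\t1/1\n"
        matrix, _ = select_best_snp(_write_vcf(tmp_path, body))
        assert np.isnan(matrix.loc["s1", "L1"])
        assert matrix.loc["s2", "L1"] == 2.0

    def test_at_most_one_column_per_locus(self, tmp_path):
        body = (
            "L1\t10\t.\tA\tC\t50\t.\t.\tGT\t0/1\t1/1\n"
            "L1\t20\t.\tG\tT\t50\t.\t.\tGT\t0/1\t0/1\n"
            "L2\t10\t.\tA\tG\t70\t.\t.\tGT\t1/1\t0/0\n"
        )
        matrix, choices = select_best_snp(_write_vcf(tmp_path, body))
        assert list(matrix.columns) == ["L1", "L2"]
        # QUAL tie at L1 -> fewer missing genotypes, then smaller position
        assert choices[0].position == 10


class TestSnpSites:
    def test_counts_segregating_columns(self):
        aln = SiteAlignment(taxa=["a", "b"], rows=["ACGT", "ACGA"])
        assert snp_sites(aln) == 1

    def test_gap_only_variation_not_counted(self):
        aln = SiteAlignment(taxa=["a", "b"], rows=["AC-T", "ACGT"])
        assert snp_sites(aln) == 0
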