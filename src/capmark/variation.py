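"""Flank filtering, variability statistics, consensus references, and
one-best-SNP genotype export.

Flanking regions are co-captured by hitchhiking and are typically more
variable than the targeted coding sequence, which makes them informative at
shallow divergences but also noisy: before summarizing variability, flanks
shorter than 20 nt, flanks with long indel runs, and flanks too diverged
from their locus consensus to be trusted as aligned are filtered out.

SNP densities are reported per kilobase of surveyed reference sequence,
separately for coding and flanking partitions.  For population work, a
majority-rule consensus per locus serves as the mapping reference, and one
best SNP per locus (highest quality) is exported as a diploid dosage matrix
so downstream ordination does not double-count linked sites.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import BASES, SiteAlignment, p_distance

logger = logging.getLogger(__name__)

PASS = "pass"
TOO_SHORT = "too_short"
LONG_INDEL = "long_indel"
UNALIGNABLE = "unalignable"

DEFAULT_MIN_FLANK_LEN = 20
DEFAULT_MAX_GAP_RUN = 30
DEFAULT_MAX_PDIST = 0.6

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


@dataclass
class Flank:
    """One (possibly gap-aligned) flanking sequence of one taxon at one locus."""

    locus_id: str
    taxon: str
    side: str  # "left" | "right"
    sequence: str
    status: str = PASS

    @property
    def ungapped_len(self) -> int:
        return sum(c not in "-" for c in self.sequence)

    @property
    def max_gap_run(self) -> int:
        best = run = 0
        for c in self.sequence:
            run = run + 1 if c == "-" else 0
            best = max(best, run)
        return best


def filter_flanks(
    flanks: Sequence[Flank],
    min_len: int = DEFAULT_MIN_FLANK_LEN,
    max_gap_run: int = DEFAULT_MAX_GAP_RUN,
    max_pdist: float = DEFAULT_MAX_PDIST,
) -> list[Flank]:
    """Classify flanks as pass / too_short / long_indel / unalignable.

    Rules apply in that order and the first failure is the recorded reason:
    ungapped length < ``min_len``; any gap run longer than ``max_gap_run``
    (only meaningful for aligned flanks); p-distance to the per-locus-side
    consensus above ``max_pdist``.  Sequences are never modified, only
    statuses assigned.
    """
    out: list[Flank] = []
    by_key: dict[tuple[str, str], list[Flank]] = {}
    for f in flanks:
        by_key.setdefault((f.locus_id, f.side), []).append(f)
    for key, group in by_key.items():
        same_len = len({len(f.sequence) for f in group}) == 1
        consensus = None
        if same_len and len(group) >= 2:
            consensus = majority_consensus(
                SiteAlignment(
                    taxa=[f.taxon for f in group], rows=[f.sequence for f in group]
                ),
                keep_gapped_columns=True,
            )
        for f in group:
            if f.ungapped_len < min_len:
                status = TOO_SHORT
            elif f.max_gap_run > max_gap_run:
                status = LONG_INDEL
            elif consensus is not None:
                d = p_distance(f.sequence, consensus)
                status = UNALIGNABLE if d is not None and d > max_pdist else PASS
            else:
                status = PASS
            out.append(replace(f, status=status))
    return out


def flank_variability(
    flanks: Sequence[Flank], passing_only: bool = True
) -> dict[str, object]:
    """Length and pairwise p-distance distributions of flanking sequences.

    p-distances are computed within each locus/side group between all pairs
    of (by default passing) aligned flanks.
    """
    chosen = [f for f in flanks if not passing_only or f.status == PASS]
    lengths = [f.ungapped_len for f in chosen]
    pdists: list[float] = []
    by_key: dict[tuple[str, str], list[Flank]] = {}
    for f in chosen:
        by_key.setdefault((f.locus_id, f.side), []).append(f)
    for group in by_key.values():
        if len({len(f.sequence) for f in group}) != 1:
            continue
        for a, b in itertools.combinations(group, 2):
            d = p_distance(a.sequence, b.sequence)
            if d is not None:
                pdists.append(d)
    return {"lengths": lengths, "pdists": pdists}


def snp_sites(aln: SiteAlignment) -> int:
    """Number of columns with at least two distinct unambiguous bases."""
    n = 0
    for i in range(aln.n_sites):
        if len({c for c in aln.column(i) if c in BASES}) >= 2:
            n += 1
    return n


def snp_density_per_kb(alignments: Sequence[SiteAlignment]) -> float:
    """SNPs per kilobase of surveyed reference sequence.

    The surveyed length of an alignment is its number of non-(majority-gap)
    columns — the length of the consensus reference the reads would map to.
    Returns NaN when nothing is surveyed.
    """
    snps = sum(snp_sites(a) for a in alignments)
    surveyed = sum(len(majority_consensus(a)) for a in alignments)
    if surveyed == 0:
        return float("nan")
    return 1000.0 * snps / surveyed


def majority_consensus(
    aln: SiteAlignment, keep_gapped_columns: bool = False
) -> str:
    """Majority-rule consensus of an alignment.

    Per column the most frequent unambiguous base wins; ties become the
    IUPAC ambiguity code of the tied bases; columns where gaps are the
    strict majority are omitted (kept as ``-`` with ``keep_gapped_columns``);
    all-missing columns yield N.
    """
    out = []
    n = len(aln.rows)
    for i in range(aln.n_sites):
        col = aln.column(i)
        gaps = sum(c == "-" for c in col)
        if 2 * gaps > n:
            if keep_gapped_columns:
                out.append("-")
            continue
        counts = Counter(c for c in col if c in BASES)
        if not counts:
            out.append("N")
            continue
        top = max(counts.values())
        tied = frozenset(b for b, c in counts.items() if c == top)
        out.append(IUPAC[tied])
    return "".join(out)


# --- one-best-SNP genotype export -----------------------------------------

MISSING_GT = np.nan


@dataclass(frozen=True)
class SnpChoice:
    locus_id: str
    position: int  # 1-based POS of the chosen SNP
    qual: float
    ref: str
    alt: str


def select_best_snp(
    vcf_path: str | Path,
    locus_of_chrom=None,
) -> tuple[pd.DataFrame, list[SnpChoice]]:
    """One best biallelic SNP per locus from a VCF, as a dosage matrix.

    Indels are discarded; multi-allelic SNPs are dropped (logged).  Per locus
    the SNP with the highest QUAL wins, ties broken by lowest missingness
    then smallest position.  The returned DataFrame is samples x loci with
    entries 0/1/2 (alternate-allele dosage) or NaN for missing genotypes.
    """
    from cyvcf2 import VCF

    locus_of_chrom = locus_of_chrom or (lambda chrom: chrom)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    best: dict[str, tuple] = {}  # locus -> (-qual, missing, pos, dosages, choice)
    for rec in vcf:
        if rec.is_indel or not rec.is_snp:
            continue
        if len(rec.ALT) != 1:
            logger.info("multi-allelic SNP at %s:%d dropped", rec.CHROM, rec.POS)
            continue
        locus = locus_of_chrom(rec.CHROM)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dosage = np.array(
            [{0: 0.0, 1: 1.0, 2: MISSING_GT, 3: 2.0}[g] for g in rec.gt_types]
        )
        missing = int(np.isnan(dosage).sum())
        qual = float(rec.QUAL) if rec.QUAL is not None else 0.0
        key = (-qual, missing, rec.POS)
        choice = SnpChoice(
            locus_id=locus, position=rec.POS, qual=qual,
            ref=rec.REF, alt=rec.ALT[0],
        )
        if locus not in best or key < best[locus][0]:
            best[locus] = (key, dosage, choice)
    loci = sorted(best)
    matrix = pd.DataFrame(
        {locus: best[locus][1] for locus in loci}, index=samples
    )
    return matrix, [best[locus][2] for locus in loci]
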