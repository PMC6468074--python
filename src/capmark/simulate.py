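"""Seeded synthetic data emulating a multi-project exon-capture study.

Every input the pipeline consumes can be generated here with a fixed seed:
reference exons and their bait proteins, per-taxon contigs (flank + mutated
exon + flank), per-position depth profiles with injected high-depth
plateaus, genome annotations with planted off-target best hits, and
tree-evolved alignments for parsimony statistics.  Truth tables record what
was planted so recovery can be checked exactly.

Defaults describe a realistic capture experiment: exons of 100-600 nt,
flanks centered around 800 nt, polymorphic-site densities of 0.035 per site
in coding and 0.050 per site in flanking sequence, and depth anomalies at
200-fold over a Poisson background.  Variation is planned per locus — each
site is polymorphic with probability equal to the configured rate, with one
derived allele carried by each taxon at frequency 1/2 — so the configured
rate is directly the expected SNP density of the generated data.  Sites are
i.i.d. with no rate heterogeneity, there is no indel process (same-locus
sequences are aligned by construction), and terminal exon codons stay
invariant so the planted exon boundary is the unique optimal
local-alignment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io import DepthProfile, HitRecord, LocusSequence, TargetAnnotation
from .markers import DEFAULT_GROUPS

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
CODONS = [
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
]
GENETIC_CODE: dict[str, str] = {}


def _init_code() -> None:
    from Bio.Seq import Seq

    for codon in CODONS:
        GENETIC_CODE[codon] = str(Seq(codon).translate())


_init_code()


@dataclass
class SimulationConfig:
    """Knobs of the synthetic capture experiment (see module docstring)."""

    seed: int = 0
    n_loci: int = 30
    groups: tuple[str, ...] = DEFAULT_GROUPS
    taxa_per_group: int = 2
    exon_len_range: tuple[int, int] = (100, 600)
    flank_len_mean: float = 800.0
    flank_len_sd: float = 150.0
    coding_rate: float = 0.035
    flank_rate: float = 0.050
    missingness: float = 0.0
    decisive_fraction: float = 1.0
    paralog_fraction: float = 0.0
    mean_depth: float = 30.0
    anomaly_prob: float = 0.0
    anomaly_len: int = 50
    anomaly_fold: float = 200.0

    def __post_init__(self) -> None:
        for r in (self.coding_rate, self.flank_rate, self.missingness,
                  self.decisive_fraction, self.paralog_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates and fractions must be in [0, 1]")
        if self.n_loci < 1 or self.taxa_per_group < 1:
            raise ValueError("n_loci and taxa_per_group must be >= 1")
        if self.exon_len_range[0] < 9:
            raise ValueError("exons must be at least 9 nt")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def taxa(self) -> list[str]:
        return [
            f"{g}_sp{k + 1}" for g in self.groups for k in range(self.taxa_per_group)
        ]

    @property
    def group_of(self) -> dict[str, str]:
        return {t: t.rsplit("_sp", 1)[0] for t in self.taxa}


@dataclass
class SimulatedCapture:
    """Synthetic capture study with its ground truth."""

    cfg: SimulationConfig
    reference_exons: dict[str, str]
    bait_proteins: dict[str, str]
    contigs: dict[str, dict[str, LocusSequence]]  # taxon -> locus -> contig
    exon_spans: dict[tuple[str, str], tuple[int, int]]  # (taxon, locus) -> span
    decisive_truth: set[str]
    group_of: dict[str, str]

    @property
    def loci(self) -> list[str]:
        return sorted(self.reference_exons)

    def project(self) -> dict[str, dict[str, str]]:
        """The capture result as one {taxon: {locus: exon sequence}} project."""
        out: dict[str, dict[str, str]] = {}
        for taxon, by_locus in self.contigs.items():
            for locus, contig in by_locus.items():
                s, e = self.exon_spans[(taxon, locus)]
                out.setdefault(taxon, {})[locus] = contig.sequence[s:e]
        return out

    def coding_alignment(self, locus: str):
        """Aligned coding sequences of one locus (None if <2 taxa have it)."""
        from .metrics import SiteAlignment

        taxa = [t for t in sorted(self.contigs) if locus in self.contigs[t]]
        if len(taxa) < 2:
            return None
        rows = []
        for t in taxa:
            s, e = self.exon_spans[(t, locus)]
            rows.append(self.contigs[t][locus].sequence[s:e])
        return SiteAlignment(taxa=taxa, rows=rows)

    def flank_alignment(self, locus: str, side: str):
        """Aligned flanks (``left`` or ``right``) of one locus, or None."""
        from .metrics import SiteAlignment

        taxa = [t for t in sorted(self.contigs) if locus in self.contigs[t]]
        if len(taxa) < 2:
            return None
        rows = []
        for t in taxa:
            s, e = self.exon_spans[(t, locus)]
            seq = self.contigs[t][locus].sequence
            rows.append(seq[:s] if side == "left" else seq[e:])
        if any(len(r) != len(rows[0]) for r in rows) or len(rows[0]) == 0:
            return None
        return SiteAlignment(taxa=taxa, rows=rows)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """Random open reading frame without stop codons."""
    idx = rng.integers(0, len(CODONS), size=n_codons)
    return "".join(CODONS[i] for i in idx)


def translate(coding: str) -> str:
    return "".join(GENETIC_CODE[coding[i: i + 3]] for i in range(0, len(coding), 3))


def mutate_dna(rng: np.random.Generator, seq: str, rate: float) -> str:
    """i.i.d. per-site substitutions: each site changes to one of the other
    three bases with probability ``rate``."""
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = [b for b in BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def mutate_coding(rng: np.random.Generator, coding: str, rate: float) -> str:
    """Per-site substitutions in a coding sequence, avoiding new stop codons
    and leaving the first and last codon untouched."""
    codons = [coding[i: i + 3] for i in range(0, len(coding), 3)]
    for ci in range(1, len(codons) - 1):
        codon = list(codons[ci])
        for p in range(3):
            if rng.random() < rate:
                alternatives = [b for b in BASES if b != codon[p]]
                codon[p] = alternatives[rng.integers(0, 3)]
        cand = "".join(codon)
        if cand not in STOP_CODONS:
            codons[ci] = cand
    return "".join(codons)


def polymorphic_plan(
    rng: np.random.Generator, seq: str, rate: float, coding: bool = False
) -> list[tuple[int, str]]:
    """Choose the polymorphic sites of one locus: each site is variable with
    probability ``rate`` and gets one derived allele.

    ``rate`` therefore sets the expected SNP density (segregating sites per
    site) of the locus across the sampled taxa.  In coding sequence the
    first and last codon are kept invariant so the locus boundary stays the
    unique optimal alignment boundary.
    """
    lo = 3 if coding else 0
    hi = len(seq) - 3 if coding else len(seq)
    plan = []
    for pos in np.flatnonzero(rng.random(len(seq)) < rate):
        if not lo <= pos < hi:
            continue
        derived = [b for b in BASES if b != seq[pos]][rng.integers(0, 3)]
        plan.append((int(pos), derived))
    return plan


def apply_plan(
    rng: np.random.Generator,
    seq: str,
    plan: list[tuple[int, str]],
    derived_freq: float = 0.5,
    coding: bool = False,
) -> str:
    """One taxon's haplotype: at each planned site the derived allele is
    carried with probability ``derived_freq``.

    In coding sequence a substitution that would create a stop codon is
    reverted for that taxon.
    """
    chars = list(seq)
    for pos, derived in plan:
        if rng.random() >= derived_freq:
            continue
        old = chars[pos]
        chars[pos] = derived
        if coding:
            c0 = pos - pos % 3
            if "".join(chars[c0: c0 + 3]) in STOP_CODONS:
                chars[pos] = old
    return "".join(chars)


def _locus_ids(rng: np.random.Generator, n: int) -> list[str]:
    """Locus ids in the reference.chrom.start.end dot scheme."""
    ids = []
    for _ in range(n):
        chrom = int(rng.integers(1, 26))
        start = int(rng.integers(10_000, 9_000_000))
        end = start + int(rng.integers(200, 6_000))
        ids.append(f"Reffish.{chrom}.{start}.{end}")
    return sorted(set(ids))[:n] if len(set(ids)) >= n else _locus_ids(rng, n)


def simulate_capture(cfg: SimulationConfig) -> SimulatedCapture:
    """Generate reference exons, bait proteins, and per-taxon contigs.

    Each contig is flank + mutated exon + flank.  A ``decisive_fraction`` of
    loci is planted decisive: after random missingness one taxon per group
    is forced present.  The remaining loci each have one group knocked out
    entirely, so the planted decisive set is exactly the set a decisiveness
    filter should return.
    """
    rng = cfg.rng()
    loci = _locus_ids(rng, cfg.n_loci)
    taxa = cfg.taxa
    group_of = cfg.group_of
    by_group: dict[str, list[str]] = {}
    for t in taxa:
        by_group.setdefault(group_of[t], []).append(t)

    n_decisive = int(round(cfg.decisive_fraction * cfg.n_loci))
    decisive = set(loci[:n_decisive])  # locus ids are random; no bias

    reference_exons: dict[str, str] = {}
    bait_proteins: dict[str, str] = {}
    contigs: dict[str, dict[str, LocusSequence]] = {t: {} for t in taxa}
    exon_spans: dict[tuple[str, str], tuple[int, int]] = {}

    for locus in loci:
        lo, hi = cfg.exon_len_range
        n_codons = max(3, int(rng.integers(lo, hi + 1)) // 3)
        exon = random_coding(rng, n_codons)
        reference_exons[locus] = exon
        bait_proteins[locus] = translate(exon)

        present = {t: rng.random() >= cfg.missingness for t in taxa}
        if locus in decisive:
            for g, members in by_group.items():
                if not any(present[t] for t in members):
                    present[members[int(rng.integers(0, len(members)))]] = True
        else:
            knocked = cfg.groups[int(rng.integers(0, len(cfg.groups)))]
            for t in by_group[knocked]:
                present[t] = False

        # one ancestral flank pair per locus; polymorphic sites are planned
        # once per locus (their density is the configured rate) and each
        # taxon carries the derived allele with frequency 1/2.  No indel
        # process, so same-locus flanks of equal side are aligned by
        # construction.
        lf = max(0, int(rng.normal(cfg.flank_len_mean, cfg.flank_len_sd)))
        rf = max(0, int(rng.normal(cfg.flank_len_mean, cfg.flank_len_sd)))
        anc_left = random_dna(rng, lf)
        anc_right = random_dna(rng, rf)
        left_plan = polymorphic_plan(rng, anc_left, cfg.flank_rate)
        right_plan = polymorphic_plan(rng, anc_right, cfg.flank_rate)
        coding_plan = polymorphic_plan(rng, exon, cfg.coding_rate, coding=True)

        for taxon in taxa:
            if not present[taxon]:
                continue
            left = apply_plan(rng, anc_left, left_plan)
            right = apply_plan(rng, anc_right, right_plan)
            body = apply_plan(rng, exon, coding_plan, coding=True)
            seq = left + body + right
            contigs[taxon][locus] = LocusSequence(
                locus_id=locus, taxon=taxon, sequence=seq,
                exon_span=(lf, lf + len(body)),
            )
            exon_spans[(taxon, locus)] = (lf, lf + len(body))

    return SimulatedCapture(
        cfg=cfg,
        reference_exons=reference_exons,
        bait_proteins=bait_proteins,
        contigs=contigs,
        exon_spans=exon_spans,
        decisive_truth=decisive,
        group_of=group_of,
    )


def simulate_depth(
    rng: np.random.Generator,
    locus_lengths: Mapping[str, int],
    mean_depth: float = 30.0,
    anomaly_prob: float = 0.0,
    anomaly_len: int = 50,
    anomaly_fold: float = 200.0,
    sample: str = "sim",
) -> tuple[list[DepthProfile], dict[str, tuple[int, int]]]:
    """Poisson-background depth profiles with optional injected plateaus.

    With probability ``anomaly_prob`` a locus gets one plateau of
    ``anomaly_len`` positions at ``anomaly_fold`` x the mean depth.  Returns
    the profiles and a truth table of injected spans.
    """
    profiles = []
    truth: dict[str, tuple[int, int]] = {}
    for locus in sorted(locus_lengths):
        length = locus_lengths[locus]
        depths = rng.poisson(mean_depth, size=length).astype(np.int64)
        depths = np.maximum(depths, 1)  # a captured locus has reads everywhere
        if anomaly_prob > 0 and rng.random() < anomaly_prob and length > anomaly_len:
            start = int(rng.integers(0, length - anomaly_len + 1))
            depths[start: start + anomaly_len] = int(mean_depth * anomaly_fold)
            truth[locus] = (start, start + anomaly_len)
        profiles.append(DepthProfile(locus_id=locus, depths=depths, sample=sample))
    return profiles, truth


def simulate_paralogs(
    rng: np.random.Generator,
    loci: Sequence[str],
    paralog_fraction: float = 0.3,
    taxon: str | None = None,
) -> tuple[dict[str, TargetAnnotation], list[HitRecord], dict[str, str]]:
    """Annotations plus hit tables with a planted fraction of off-target
    best hits.

    Every locus gets a proper target-region annotation and an on-target hit;
    a planted fraction additionally gets a *stronger* hit elsewhere in the
    genome, so its best hit falls outside the target region.  Returns
    (annotations, hits, truth status per locus).
    """
    n_paralog = int(round(paralog_fraction * len(loci)))
    flagged = set(rng.choice(list(loci), size=n_paralog, replace=False)) if n_paralog else set()
    annotations: dict[str, TargetAnnotation] = {}
    hits: list[HitRecord] = []
    truth: dict[str, str] = {}
    for locus in loci:
        chrom = f"chr{int(rng.integers(1, 26))}"
        start = int(rng.integers(1_000, 5_000_000))
        end = start + int(rng.integers(500, 5_000))
        annotations[locus] = TargetAnnotation(
            locus_id=locus, genome_id="Reffish", chrom=chrom, start=start, end=end
        )
        query = locus if taxon is None else f"{locus}|{taxon}"
        on_target = HitRecord(
            query_id=query, subject_id=chrom, percent_identity=98.0,
            align_len=end - start, subject_start=start, subject_end=end,
            bitscore=400.0, evalue=1e-120,
        )
        hits.append(on_target)
        if locus in flagged:
            off_chrom = f"chr{int(rng.integers(26, 40))}"
            off_start = int(rng.integers(1_000, 5_000_000))
            hits.append(
                HitRecord(
                    query_id=query, subject_id=off_chrom, percent_identity=99.5,
                    align_len=end - start, subject_start=off_start,
                    subject_end=off_start + (end - start),
                    bitscore=650.0, evalue=1e-160,
                )
            )
            truth[locus] = "paralog"
        else:
            truth[locus] = "ortholog"
    return annotations, hits, truth


# --- tree-based sequence evolution (for parsimony statistics) -------------

def simulate_alignment_on_tree(
    tree: dendropy.Tree,
    n_sites: int,
    rng: np.random.Generator,
    mutation_prob: float = 0.1,
) -> tuple[list[str], list[str]]:
    """Evolve sites down a tree under a Jukes-Cantor-style model.

    Each edge substitutes each site with probability ``mutation_prob``
    (uniformly to one of the other three bases).  Returns (taxa, rows).
    """
    root_seq = np.array(list(random_dna(rng, n_sites)))
    seqs: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[node] = root_seq.copy()
            continue
        seq = seqs[node.parent_node].copy()
        hits = np.flatnonzero(rng.random(n_sites) < mutation_prob)
        for i in hits:
            alternatives = [b for b in BASES if b != seq[i]]
            seq[i] = alternatives[rng.integers(0, 3)]
        seqs[node] = seq
    taxa, rows = [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        rows.append("".join(seqs[leaf]))
    return taxa, rows


def simulate_homoplasy_free_alignment(
    tree: dendropy.Tree,
    n_sites: int,
    rng: np.random.Generator,
    mutated_fraction: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Alignment where each variable site mutated exactly once on one edge.

    Such sites are homoplasy-free on the generating tree, so CI = 1.
    """
    leaves = list(tree.leaf_node_iter())
    internal_edges = [
        n for n in tree.preorder_node_iter() if n.parent_node is not None
    ]
    cols: dict = {leaf.taxon.label: [] for leaf in leaves}
    for _ in range(n_sites):
        base = BASES[rng.integers(0, 4)]
        states = {leaf.taxon.label: base for leaf in leaves}
        if rng.random() < mutated_fraction:
            edge_node = internal_edges[int(rng.integers(0, len(internal_edges)))]
            derived = [b for b in BASES if b != base][rng.integers(0, 3)]
            for leaf in edge_node.leaf_iter():
                states[leaf.taxon.label] = derived
        for label, b in states.items():
            cols[label].append(b)
    taxa = [leaf.taxon.label for leaf in leaves]
    return taxa, ["".join(cols[t]) for t in taxa]
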