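"""Merging capture projects and selecting phylogenetically decisive loci.

A capture experiment yields, per project, a set of per-taxon locus sequences
sharing a common locus naming scheme.  Projects are merged into a single
loci x taxa matrix, taxa with too few captured loci are dropped (strictly
more than the threshold are kept), and a locus is retained as
*phylogenetically decisive* when every required clade group has at least one
sequenced representative at that locus — so any analysis drawing on the
locus can address the relationships among all those groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .io import read_fasta

logger = logging.getLogger(__name__)

#: the eight major ray-finned fish clades used as decisive groups by default
DEFAULT_GROUPS = (
    "Acipenseriformes", "Lepisosteiformes", "Elopomorpha", "Osteoglossomorpha",
    "Otomorpha", "Gobiaria", "Ovalentaria", "Eupercaria",
)

DEFAULT_MIN_LOCI_PER_TAXON = 3000


@dataclass
class CaptureMatrix:
    """Loci x taxa matrix of captured sequences with clade-group labels."""

    cells: dict[str, dict[str, str]] = field(default_factory=dict)  # locus -> taxon -> seq
    group_of: dict[str, str] = field(default_factory=dict)

    @property
    def loci(self) -> list[str]:
        return sorted(self.cells)

    @property
    def taxa(self) -> list[str]:
        return sorted({t for row in self.cells.values() for t in row})

    def loci_of_taxon(self, taxon: str) -> list[str]:
        return [l for l, row in self.cells.items() if taxon in row]

    def presence(self) -> dict[str, set[str]]:
        """locus -> set of taxa with a sequence."""
        return {l: set(row) for l, row in self.cells.items()}


@dataclass
class DecisivenessConfig:
    required_groups: frozenset[str] = frozenset(DEFAULT_GROUPS)
    min_loci_per_taxon: int = DEFAULT_MIN_LOCI_PER_TAXON
    min_taxa_per_group: int = 1

    def __post_init__(self) -> None:
        self.required_groups = frozenset(self.required_groups)
        if not self.required_groups:
            raise ValueError("required_groups must be non-empty")
        if self.min_loci_per_taxon < 0:
            raise ValueError("min_loci_per_taxon must be >= 0")


def merge_projects(
    projects: Sequence[Mapping[str, Mapping[str, str]]],
    group_of: Mapping[str, str] | None = None,
) -> CaptureMatrix:
    """Merge per-project {taxon: {locus: sequence}} maps into one matrix.

    When the same taxon/locus cell occurs in several projects the longer
    sequence wins; an exact length tie with differing sequence keeps the
    first by project order (warned).
    """
    m = CaptureMatrix(group_of=dict(group_of or {}))
    for project in projects:
        for taxon, loci in project.items():
            for locus, seq in loci.items():
                if not seq:
                    continue
                row = m.cells.setdefault(locus, {})
                old = row.get(taxon)
                if old is None:
                    row[taxon] = seq
                elif len(seq) > len(old):
                    logger.info(
                        "duplicate cell %s/%s: keeping longer sequence (%d > %d nt)",
                        locus, taxon, len(seq), len(old),
                    )
                    row[taxon] = seq
                elif len(seq) == len(old) and seq != old:
                    logger.warning(
                        "conflicting equal-length duplicate at %s/%s; keeping first",
                        locus, taxon,
                    )
    return m


def load_project_dir(path: str | Path) -> dict[str, dict[str, str]]:
    """Load one project directory of FASTA files into {taxon: {locus: seq}}.

    Records are keyed ``locus_id|taxon``; a file whose records carry no taxon
    token uses the file stem as the taxon name.
    """
    project: dict[str, dict[str, str]] = {}
    for fasta in sorted(Path(path).glob("*.fasta")) + sorted(Path(path).glob("*.fa")):
        for rec in read_fasta(fasta):
            taxon = rec.taxon or fasta.stem
            project.setdefault(taxon, {})[rec.locus_id] = rec.sequence
    return project


def filter_taxa(m: CaptureMatrix, min_loci_per_taxon: int = DEFAULT_MIN_LOCI_PER_TAXON) -> CaptureMatrix:
    """Keep taxa with strictly more than ``min_loci_per_taxon`` captured loci.

    A taxon at exactly the threshold is dropped.  Loci left with no taxa are
    removed; removing every taxon is an error.
    """
    counts = {t: len(m.loci_of_taxon(t)) for t in m.taxa}
    keep = {t for t, n in counts.items() if n > min_loci_per_taxon}
    if not keep:
        raise ValueError(
            f"no taxon exceeds the {min_loci_per_taxon}-locus capture threshold"
        )
    dropped = sorted(set(counts) - keep)
    if dropped:
        logger.info("dropping %d poorly captured taxa: %s", len(dropped), dropped)
    cells = {}
    for locus, row in m.cells.items():
        kept_row = {t: s for t, s in row.items() if t in keep}
        if kept_row:
            cells[locus] = kept_row
    group_of = {t: g for t, g in m.group_of.items() if t in keep}
    return CaptureMatrix(cells=cells, group_of=group_of)


def decisive_loci(m: CaptureMatrix, cfg: DecisivenessConfig) -> list[str]:
    """Loci at which every required clade group has a sequenced representative.

    Requires a group label for every taxon in the matrix; unknown groups in
    the config are an error.
    """
    unlabelled = sorted(set(m.taxa) - set(m.group_of))
    if unlabelled:
        raise KeyError(f"taxa without a clade-group label: {unlabelled}")
    known = set(m.group_of.values())
    unknown = sorted(set(cfg.required_groups) - known)
    if unknown:
        raise KeyError(f"required groups with no labelled taxa: {unknown}")

    kept = []
    for locus in m.loci:
        present = {}
        for taxon in m.cells[locus]:
            g = m.group_of[taxon]
            present[g] = present.get(g, 0) + 1
        if all(present.get(g, 0) >= cfg.min_taxa_per_group for g in cfg.required_groups):
            kept.append(locus)
    return kept


def select_markers(
    projects: Sequence[Mapping[str, Mapping[str, str]]],
    group_of: Mapping[str, str],
    cfg: DecisivenessConfig | None = None,
) -> tuple[CaptureMatrix, list[str]]:
    """Merge, filter poorly captured taxa, and pick decisive loci in one pass."""
    cfg = cfg or DecisivenessConfig()
    merged = merge_projects(projects, group_of=group_of)
    filtered = filter_taxa(merged, cfg.min_loci_per_taxon)
    return filtered, decisive_loci(filtered, cfg)
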