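"""Paralog screening by best-hit genomic location.

Captured sequences are re-aligned against the reference genome they were
designed from; a sequence whose best hit does not fall inside the annotated
target region is flagged as a potential paralog and excluded from downstream
marker selection.  Queries with no hit at all are retained by default with a
warning — only a demonstrably wrong location is evidence of paralogy.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import HitRecord, TargetAnnotation, parse_header

logger = logging.getLogger(__name__)

ORTHOLOG = "ortholog"
PARALOG = "paralog"
NO_HIT = "no_hit"


@dataclass
class ParalogVerdict:
    locus_id: str
    taxon: str | None
    status: str  # ortholog | paralog | no_hit
    best_hit: HitRecord | None = None

    @property
    def query_id(self) -> str:
        return self.locus_id if self.taxon is None else f"{self.locus_id}|{self.taxon}"


def best_hit(hits: list[HitRecord]) -> HitRecord | None:
    """The best hit of one query: maximal bitscore, ties broken by lower
    e-value, then longer alignment, then smaller subject id."""
    if not hits:
        return None
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("best_hit expects hits of a single query")
    return min(hits, key=lambda h: (-h.bitscore, h.evalue, -h.align_len, h.subject_id))


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def screen(
    hits: Iterable[HitRecord],
    annotations: Mapping[str, TargetAnnotation],
    min_overlap_bp: int = 1,
    drop_no_hit: bool = False,
) -> list[ParalogVerdict]:
    """Classify each query as ortholog / paralog / no_hit.

    A query is an ortholog iff its best hit lands on the annotated chromosome
    and its strand-normalized interval overlaps the annotated target interval
    by at least ``min_overlap_bp``.  Strand is ignored for the overlap test.
    Every locus appearing in the hit set must have an annotation row.
    """
    by_query: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)

    missing = sorted(
        {parse_header(q)[0] for q in by_query} - set(annotations)
    )
    if missing:
        raise KeyError(f"loci without target annotation: {missing}")

    verdicts = []
    for query_id in sorted(by_query):
        locus_id, taxon = parse_header(query_id)
        bh = best_hit(by_query[query_id])
        anno = annotations[locus_id]
        on_target = (
            bh is not None
            and bh.subject_id == anno.chrom
            and _overlap(bh.subject_interval, anno.interval) >= min_overlap_bp
        )
        status = ORTHOLOG if on_target else PARALOG
        verdicts.append(
            ParalogVerdict(locus_id=locus_id, taxon=taxon, status=status, best_hit=bh)
        )

    # queries that produced no hit rows at all are handled by the caller
    # passing them through `screen_no_hits`; rows already in `hits` always
    # have a best hit.
    if drop_no_hit:
        verdicts = [v for v in verdicts if v.status != NO_HIT]
    return verdicts


def screen_no_hits(query_ids: Iterable[str]) -> list[ParalogVerdict]:
    """Verdicts for queries that produced no hits (retained, with a warning)."""
    out = []
    for q in sorted(set(query_ids)):
        locus_id, taxon = parse_header(q)
        logger.warning("query %s has no genome hit; retained as no_hit", q)
        out.append(ParalogVerdict(locus_id=locus_id, taxon=taxon, status=NO_HIT))
    return out


def excluded_loci(verdicts: Iterable[ParalogVerdict], drop_no_hit: bool = False) -> set[str]:
    """Query ids to exclude from further analysis (the paralog set)."""
    drop = {PARALOG} | ({NO_HIT} if drop_no_hit else set())
    return {v.query_id for v in verdicts if v.status in drop}
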