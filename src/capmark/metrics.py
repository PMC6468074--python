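"""Marker summary statistics: length, GC, p-distance, and parsimony CI/RI.

The consistency index CI = M/S and retention index RI = (G-S)/(G-M) measure
homoplasy of an alignment on a tree, where per site S is the observed number
of parsimony steps (Fitch small parsimony), M is the minimum conceivable
number of steps (distinct observed states minus one, tree-free), and G is
the maximum (steps on a star tree: non-missing taxa minus the count of the
most frequent state).  CI = 1 means every site is homoplasy-free on the
tree; RI = 0 means the tree explains character covariation no better than a
star tree.

Gaps and N are treated as missing: they are excluded from p-distance
comparisons and from Fitch state sets (a leaf with missing data carries the
full state set at no cost).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .io import LocusSequence

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")
MISSING = frozenset("N-?")


@dataclass
class SiteAlignment:
    """Aligned multi-taxon DNA sequences (equal-length, gapped)."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows are not aligned (unequal lengths)")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def column(self, i: int) -> list[str]:
        return [r[i] for r in self.rows]

    @classmethod
    def from_records(cls, records: Sequence[LocusSequence]) -> "SiteAlignment":
        return cls(
            taxa=[r.taxon or r.locus_id for r in records],
            rows=[r.sequence for r in records],
        )


@dataclass
class ParsimonyScores:
    per_site_observed: list[int]  # S_i, Fitch steps
    per_site_min: list[int]       # M_i
    per_site_max: list[int]       # G_i

    @property
    def S(self) -> int:
        return sum(self.per_site_observed)

    @property
    def M(self) -> int:
        return sum(self.per_site_min)

    @property
    def G(self) -> int:
        return sum(self.per_site_max)

    @property
    def ci(self) -> float:
        if self.S == 0:
            raise ZeroDivisionError("alignment invariant on tree: CI undefined")
        return self.M / self.S

    @property
    def ri(self) -> float | None:
        if self.G == self.M:
            return None
        return (self.G - self.S) / (self.G - self.M)


def p_distance(a: str, b: str) -> float | None:
    """Proportion of differing sites among positions comparable in both rows.

    Positions with a gap or N in either row are excluded; returns None when
    no site is comparable.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    compared = mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in MISSING or y in MISSING:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        return None
    return mismatches / compared


def basic_stats(aln: SiteAlignment) -> tuple[float, float, float]:
    """(mean ungapped length nt, GC fraction, mean pairwise p-distance).

    GC is computed over all unambiguous bases of all rows; pairs with zero
    comparable sites are excluded from the p-distance mean (with a warning).
    """
    lengths = []
    gc = at = 0
    for row in aln.rows:
        bases = [c for c in row if c in BASES]
        lengths.append(len(bases))
        gc += sum(c in "GC" for c in bases)
        at += sum(c in "AT" for c in bases)
    dists = []
    for i, j in itertools.combinations(range(len(aln.rows)), 2):
        d = p_distance(aln.rows[i], aln.rows[j])
        if d is None:
            logger.warning(
                "pair (%s, %s) shares no comparable site; excluded from p-dist",
                aln.taxa[i], aln.taxa[j],
            )
        else:
            dists.append(d)
    mean_pdist = float(np.mean(dists)) if dists else float("nan")
    gc_frac = gc / (gc + at) if gc + at else float("nan")
    return float(np.mean(lengths)), gc_frac, mean_pdist


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a newick tree from a path or a newick string."""
    text = str(source)
    if "(" not in text:  # newick strings contain parentheses; paths do not
        text = Path(text).read_text()
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def fitch_site_length(states: dict[str, str], tree: dendropy.Tree) -> int:
    """Fitch small-parsimony step count of one site on a tree.

    ``states`` maps each leaf taxon label to its base; gap/N/? are missing
    and contribute the full state set at no cost.  The count is invariant to
    the rooting dendropy happens to use.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if leaf_labels != set(states):
        raise ValueError(
            f"tree leaves {sorted(leaf_labels)} != alignment taxa {sorted(states)}"
        )
    steps = 0
    sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label].upper()
            sets[node] = frozenset(s) if s in BASES else BASES
        else:
            child_sets = [sets[c] for c in node.child_nodes()]
            acc = child_sets[0]
            for cs in child_sets[1:]:
                inter = acc & cs
                if inter:
                    acc = inter
                else:
                    acc = acc | cs
                    steps += 1
            sets[node] = acc
    return steps


def _site_min_max(column: Iterable[str]) -> tuple[int, int]:
    observed = [c for c in column if c in BASES]
    if not observed:
        return 0, 0
    counts = {b: observed.count(b) for b in set(observed)}
    m = len(counts) - 1
    g = len(observed) - max(counts.values())
    return m, g


def ci_ri(
    aln: SiteAlignment,
    tree: dendropy.Tree,
    informative_only: bool = False,
) -> ParsimonyScores:
    """Consistency and retention indices of an alignment on a tree.

    All sites are included by default (constant sites contribute zeros, the
    PAUP*-style default); ``informative_only`` restricts the sums to
    parsimony-informative sites (two or more states each in two or more
    taxa).
    """
    S, M, G = [], [], []
    for i in range(aln.n_sites):
        col = aln.column(i)
        m, g = _site_min_max(col)
        if informative_only:
            observed = [c for c in col if c in BASES]
            counts = sorted(
                (observed.count(b) for b in set(observed)), reverse=True
            )
            if len([c for c in counts if c >= 2]) < 2:
                continue
        s = (
            fitch_site_length(dict(zip(aln.taxa, col)), tree)
            if m > 0
            else 0
        )
        S.append(s)
        M.append(m)
        G.append(g)
    return ParsimonyScores(per_site_observed=S, per_site_min=M, per_site_max=G)


def locus_stats_row(
    aln: SiteAlignment, tree: dendropy.Tree | None = None
) -> dict[str, float | None]:
    """One summary row per locus: length, GC, mean p-dist and, with a tree,
    CI and RI."""
    length, gc, pdist = basic_stats(aln)
    row: dict[str, float | None] = {
        "mean_ungapped_len": length, "gc": gc, "mean_pdist": pdist,
        "ci": None, "ri": None,
    }
    if tree is not None:
        scores = ci_ri(aln, tree)
        try:
            row["ci"] = scores.ci
        except ZeroDivisionError:
            row["ci"] = None
        row["ri"] = scores.ri
    return row
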