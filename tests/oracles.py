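"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different formulations than the library: the local
alignment oracle is a top-down recursion that enumerates gap lengths
explicitly (validated at tiny sizes against a pure op-sequence enumeration),
the Fitch oracle enumerates all internal-node labelings, and the RC50 and
decisiveness oracles are naive loops.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

BASES = "ACGT"


def sw_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Best local-alignment score, affine gaps in the BLAST convention
    (a gap of length L costs gap_open + L*gap_extend).

    H(i, j) is the best score of a local alignment whose last column aligns
    a[i-1] with b[j-1]; gaps are enumerated by explicit length rather than
    by an incremental gap state.
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def H(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return float("-inf")
        s = float(_BLOSUM62[a[i - 1], b[j - 1]])
        best_prev = 0.0
        for pi in range(1, i):
            for pj in range(1, j):
                prev = H(pi, pj)
                if prev == float("-inf"):
                    continue
                # connect (pi, pj) to (i, j): between two substitution
                # columns there is at most one gap block per sequence (two
                # same-sequence blocks would merge, saving one gap open)
                di, dj = i - pi, j - pj
                if di == 1 and dj == 1:
                    cost = 0.0
                elif di == 1:
                    cost = gap_open + (dj - 1) * gap_extend
                elif dj == 1:
                    cost = gap_open + (di - 1) * gap_extend
                else:
                    cost = 2 * gap_open + (di - 1 + dj - 1) * gap_extend
                best_prev = max(best_prev, prev - cost)
        return s + best_prev

    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(best, H(i, j))
    return best


def sw_score_enumeration(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Pure enumeration over all local alignments as op sequences.

    Exponential; only usable for sequences of length <= 4.  Exists to
    validate :func:`sw_score_oracle` itself.
    """
    best = 0.0

    def global_best(x: str, y: str) -> float:
        result = float("-inf")

        def rec(i: int, j: int, score: float, last: str | None) -> None:
            nonlocal result
            if i == len(x) and j == len(y):
                result = max(result, score)
                return
            if i < len(x) and j < len(y):
                rec(i + 1, j + 1, score + float(_BLOSUM62[x[i], y[j]]), "M")
            if i < len(x):
                pen = gap_extend if last == "D" else gap_open + gap_extend
                rec(i + 1, j, score - pen, "D")
            if j < len(y):
                pen = gap_extend if last == "I" else gap_open + gap_extend
                rec(i, j + 1, score - pen, "I")

        rec(0, 0, 0.0, None)
        return result

    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, global_best(a[i1:i2], b[j1:j2]))
    return max(0.0, best)


def fitch_bruteforce(states: dict[str, str], tree) -> int:
    """Minimum substitutions by enumerating all internal-node labelings.

    Leaves with missing states (not in ACGT) cost nothing on their edge.
    """
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = list(tree.leaf_node_iter())
    best = None
    for labeling in itertools.product(BASES, repeat=len(internal)):
        assign = dict(zip(internal, labeling))
        cost = 0
        for node in internal:
            parent = node.parent_node
            if parent is not None:
                cost += assign[node] != assign[parent]
        for leaf in leaves:
            s = states[leaf.taxon.label].upper()
            if s in BASES:
                cost += s != assign[leaf.parent_node]
        if best is None or cost < best:
            best = cost
    return best


def rc50_bruteforce(rows: list[tuple[str, int, int]]) -> int:
    """Naive RC50: sort by coverage desc (ties: bases desc, id asc), walk the
    prefix sums until at least half the total mapped bases is consumed."""
    ordered = sorted(
        rows, key=lambda r: (-(r[2] / r[1]), -r[2], r[0])
    )
    total = sum(r[2] for r in rows)
    acc = 0
    for k, r in enumerate(ordered, start=1):
        acc += r[2]
        if 2 * acc >= total:
            return k
    raise AssertionError("unreachable for positive totals")


def decisive_bruteforce(
    presence: dict[str, set[str]], group_of: dict[str, str], groups: set[str]
) -> set[str]:
    """Loci at which every group has at least one present taxon."""
    out = set()
    for locus, taxa in presence.items():
        covered = {group_of[t] for t in taxa}
        if groups <= covered:
            out.add(locus)
    return out
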