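"""Per-locus read coverage and the RC50 evenness statistic.

Coverage of a locus is the total length of reads mapped to it divided by the
locus length.  RC50 summarizes how evenly reads are spread across loci:
sorting loci by coverage in descending order, RC50 is the number of top loci
that together consume half of all mapped read data.  A perfectly even
capture of n loci gives ceil(n/2); a capture dominated by a few runaway loci
gives a small RC50, so higher is better.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import DepthProfile

COVERAGE_COLUMNS = ["locus_id", "locus_len", "mapped_read_bases", "coverage"]


def locus_coverage(locus_len: int, mapped_read_bases: int) -> float:
    """Mapped read bases divided by locus length."""
    if locus_len <= 0:
        raise ValueError("locus_len must be > 0")
    if mapped_read_bases < 0:
        raise ValueError("mapped_read_bases must be >= 0")
    return mapped_read_bases / locus_len


def coverage_table(
    rows: Iterable[tuple[str, int, int]] | pd.DataFrame,
) -> pd.DataFrame:
    """Build a coverage table from (locus_id, locus_len, mapped_read_bases) rows."""
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(rows, columns=COVERAGE_COLUMNS[:3])
    df["coverage"] = df["mapped_read_bases"] / df["locus_len"]
    if (df["locus_len"] <= 0).any():
        raise ValueError("locus_len must be > 0")
    if (df["mapped_read_bases"] < 0).any():
        raise ValueError("mapped_read_bases must be >= 0")
    return df[COVERAGE_COLUMNS]


def coverage_from_depths(profiles: Sequence[DepthProfile]) -> pd.DataFrame:
    """Coverage table from depth profiles (mapped bases = sum of depths)."""
    return coverage_table(
        [(p.locus_id, len(p), int(p.depths.sum())) for p in profiles]
    )


def rc50(table: pd.DataFrame, unit: str = "bases") -> int:
    """Smallest number of top-coverage loci consuming half the mapped data.

    Rows are sorted by coverage descending (ties by mapped bases descending,
    then locus id); RC50 is the smallest k whose cumulative ``unit`` —
    ``bases`` (mapped read bases, the default) or ``reads`` (a ``reads``
    column must then be present) — reaches half the total (inclusive).
    """
    if unit not in ("bases", "reads"):
        raise ValueError("unit must be 'bases' or 'reads'")
    if table.empty:
        raise ValueError("coverage table is empty")
    col = "mapped_read_bases" if unit == "bases" else "reads"
    total = table[col].sum()
    if total <= 0:
        raise ValueError("no mapped data: RC50 undefined")
    ordered = table.sort_values(
        ["coverage", "mapped_read_bases", "locus_id"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    cum = ordered[col].cumsum().to_numpy()
    return int(np.searchsorted(cum, total / 2.0) + 1)


def rc50_curve(table: pd.DataFrame, unit: str = "bases") -> pd.DataFrame:
    """The sorted cumulative-fraction curve behind RC50, for plotting."""
    col = "mapped_read_bases" if unit == "bases" else "reads"
    ordered = table.sort_values(
        ["coverage", "mapped_read_bases", "locus_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    ordered["cumulative_fraction"] = ordered[col].cumsum() / ordered[col].sum()
    ordered.index = ordered.index + 1
    ordered.index.name = "rank"
    return ordered
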