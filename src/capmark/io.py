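"""Readers and writers for the external formats the pipeline consumes.

Soft-masking (lowercase) is meaningful everywhere in this package, so FASTA
round trips preserve case exactly.  Coordinate conventions: depth tables are
1-based (``samtools depth`` dialect), hit tables are 1-based inclusive with
start > end encoding the minus strand (BLAST outfmt 6), and every span held
in memory is 0-based half-open.  The readers in this module are the only
place those shifts happen.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: columns of a BLAST tabular (outfmt 6) file
HIT_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "align_len", "mismatches",
    "gap_opens", "query_start", "query_end", "subject_start", "subject_end",
    "evalue", "bitscore",
]

_HEADER_RE = re.compile(r"^(?P<locus>[^|\s]+)(?:\|(?P<taxon>\S+))?")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class LocusSequence:
    """One captured locus for one taxon.

    ``sequence`` is DNA over {A,C,G,T,N}; lowercase letters mark soft-masked
    positions.  ``exon_span`` is a 0-based half-open interval within
    ``sequence`` locating the coding region, or ``None`` when the sequence is
    exon-only.
    """

    locus_id: str
    sequence: str
    taxon: str | None = None
    exon_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.exon_span is not None:
            s, e = self.exon_span
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(
                    f"exon_span {self.exon_span} outside sequence of length "
                    f"{len(self.sequence)} for locus {self.locus_id}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def masked_spans(self) -> list[tuple[int, int]]:
        """Maximal runs of lowercase (masked) positions, 0-based half-open."""
        spans: list[tuple[int, int]] = []
        start = None
        for i, c in enumerate(self.sequence):
            if c.islower():
                if start is None:
                    start = i
            elif start is not None:
                spans.append((start, i))
                start = None
        if start is not None:
            spans.append((start, len(self.sequence)))
        return spans

    @property
    def header(self) -> str:
        return self.locus_id if self.taxon is None else f"{self.locus_id}|{self.taxon}"


@dataclass
class DepthProfile:
    """Per-position read depth for one locus of one sample.

    ``depths[i]`` is the depth at 1-based position ``i + 1``; absent rows in
    the source table mean zero depth.
    """

    locus_id: str
    depths: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if (self.depths < 0).any():
            raise ValueError(f"negative depth in profile {self.locus_id}")

    def __len__(self) -> int:
        return len(self.depths)


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular alignment (BLAST outfmt 6-style) hit table."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    subject_start: int  # 1-based inclusive, as printed; start > end = minus strand
    subject_end: int
    bitscore: float
    evalue: float

    @property
    def strand(self) -> str:
        return "-" if self.subject_start > self.subject_end else "+"

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Strand-normalized subject interval, 0-based half-open."""
        lo, hi = sorted((self.subject_start, self.subject_end))
        return lo - 1, hi


@dataclass(frozen=True)
class TargetAnnotation:
    """The annotated true location of a marker in a reference genome."""

    locus_id: str
    genome_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"annotation start > end for {self.locus_id}")

    @property
    def interval(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return self.start - 1, self.end


def parse_header(header: str) -> tuple[str, str | None]:
    """Split a FASTA header token into (locus_id, taxon).

    The dialect is ``locus_id|taxon``; a bare locus_id is accepted.
    """
    m = _HEADER_RE.match(header)
    if m is None or not m.group("locus"):
        raise FormatError(f"unparseable FASTA header: {header!r}")
    return m.group("locus"), m.group("taxon")


def read_fasta(path: str | Path) -> list[LocusSequence]:
    """Read a (possibly soft-masked) FASTA file into LocusSequence records."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        locus_id, taxon = parse_header(rec.id)
        records.append(LocusSequence(locus_id=locus_id, taxon=taxon, sequence=str(rec.seq)))
    if not records:
        logger.warning("no records in FASTA file %s", path)
    return records


def write_fasta(records: Iterable[LocusSequence], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, preserving case; ``width`` wraps sequence lines."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.header, description="") for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seqrecs)


def read_depth_table(
    path: str | Path,
    sample: str = "",
    locus_lengths: dict[str, int] | None = None,
) -> list[DepthProfile]:
    """Read a 3-column (locus_id, pos, depth) TSV into per-locus profiles.

    Positions are 1-based; positions absent from the table get depth 0, up to
    the maximum observed position or the supplied locus length.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["locus_id", "pos", "depth"],
            dtype={"locus_id": str},
        )
    except pd.errors.EmptyDataError:
        return []
    for col in ("pos", "depth"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise FormatError(f"non-integer {col} in {path} at row {row}")
    df["pos"] = df["pos"].astype(int)
    df["depth"] = df["depth"].astype(int)
    profiles = []
    for locus_id, sub in df.groupby("locus_id", sort=True):
        length = max(
            int(sub["pos"].max()),
            (locus_lengths or {}).get(str(locus_id), 0),
        )
        depths = np.zeros(length, dtype=np.int64)
        depths[sub["pos"].to_numpy() - 1] = sub["depth"].to_numpy()
        profiles.append(DepthProfile(locus_id=str(locus_id), depths=depths, sample=sample))
    return profiles


def write_depth_table(
    profiles: Iterable[DepthProfile], path: str | Path, omit_zeros: bool = True
) -> None:
    """Write profiles as samtools-depth-style TSV (zero rows omitted by default)."""
    with open(path, "w") as fh:
        for p in profiles:
            for i, d in enumerate(p.depths):
                if omit_zeros and d == 0:
                    continue
                fh.write(f"{p.locus_id}\t{i + 1}\t{int(d)}\n")


def read_hits_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column BLAST outfmt-6-style TSV of alignment hits."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str, 1: str})
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != len(HIT_COLUMNS):
        raise FormatError(
            f"{path}: expected {len(HIT_COLUMNS)} columns, found {df.shape[1]}"
        )
    df.columns = HIT_COLUMNS
    return [
        HitRecord(
            query_id=row.query_id,
            subject_id=row.subject_id,
            percent_identity=float(row.percent_identity),
            align_len=int(row.align_len),
            subject_start=int(row.subject_start),
            subject_end=int(row.subject_end),
            bitscore=float(row.bitscore),
            evalue=float(row.evalue),
        )
        for row in df.itertuples(index=False)
    ]


def write_hits_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, h.percent_identity, h.align_len,
                        0, 0, 1, h.align_len, h.subject_start, h.subject_end,
                        h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


def read_annotations(path: str | Path) -> dict[str, TargetAnnotation]:
    """Read a 5-column (locus_id, genome_id, chrom, start, end) TSV."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["locus_id", "genome_id", "chrom", "start", "end"],
            dtype={"locus_id": str, "genome_id": str, "chrom": str},
        )
    except pd.errors.EmptyDataError:
        return {}
    if df.shape[1] != 5:
        raise FormatError(f"{path}: expected 5 columns")
    out = {}
    for row in df.itertuples(index=False):
        out[row.locus_id] = TargetAnnotation(
            locus_id=row.locus_id, genome_id=row.genome_id, chrom=row.chrom,
            start=int(row.start), end=int(row.end),
        )
    return out


def write_annotations(annos: Iterable[TargetAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in annos:
            fh.write(f"{a.locus_id}\t{a.genome_id}\t{a.chrom}\t{a.start}\t{a.end}\n")
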