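"""Target identification from assembled contigs.

Each assembled contig is translated in all six reading frames and compared
with the amino-acid sequence of the original bait by local (Smith–Waterman)
alignment under an affine gap model.  The best-scoring contig x frame
combination is called as the putative target; the nucleotide back-projection
of the bait-covered aligned region delineates the exon, and the remaining
contig sequence on either side is flanking sequence.

Gap costs follow the BLAST convention: a gap of length L costs
``gap_open + L * gap_extend``.  Stop codons arising from out-of-frame
translation are scored as the wildcard residue X rather than truncating the
frame, so a contig with an internal frameshift is matched only up to its
best single frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .io import LocusSequence

logger = logging.getLogger(__name__)

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
DEFAULT_MIN_SCORE = 40.0

#: frames are +1,+2,+3 on the forward strand and -1,-2,-3 on the reverse
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass
class ProteinAlignment:
    """A local protein alignment: score plus 0-based half-open spans."""

    score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_blocks: tuple = ()
    frame: int | None = None


@dataclass
class TargetCall:
    """The called target for one bait locus on one contig.

    ``exon_span`` is in nucleotides on the *oriented* (forward after
    reverse-complementing, if the best frame was negative) contig.
    """

    locus_id: str
    contig_id: str
    exon_span: tuple[int, int]
    frame: int
    score: float
    oriented_sequence: str

    @property
    def left_flank_len(self) -> int:
        return self.exon_span[0]

    @property
    def right_flank_len(self) -> int:
        return len(self.oriented_sequence) - self.exon_span[1]

    @property
    def exon_sequence(self) -> str:
        return self.oriented_sequence[self.exon_span[0]:self.exon_span[1]]


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load(matrix)
    # PairwiseAligner charges open_gap_score for the first gap column and
    # extend_gap_score thereafter; shift by one extend to get the BLAST
    # convention open + L*extend.
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


def _sanitize(protein: str, alphabet: str) -> str:
    protein = protein.upper().replace("*", "X")
    bad = set(protein) - set(alphabet)
    if bad:
        raise ValueError(f"residues {sorted(bad)} not in substitution matrix alphabet")
    return protein


def smith_waterman_protein(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ProteinAlignment:
    """Optimal local alignment of two protein sequences with affine gaps.

    Returns the empty alignment (score 0) when either sequence is empty or no
    positively scoring local alignment exists.
    """
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be >= 0")
    al = _aligner(matrix, gap_open, gap_extend)
    alphabet = str(al.substitution_matrix.alphabet)
    a = _sanitize(a, alphabet)
    b = _sanitize(b, alphabet)
    if not a or not b:
        return ProteinAlignment(score=0.0, query_span=(0, 0), subject_span=(0, 0))
    score = al.score(a, b)
    if score <= 0:
        return ProteinAlignment(score=0.0, query_span=(0, 0), subject_span=(0, 0))
    best = al.align(a, b)[0]
    qblocks, sblocks = best.aligned
    return ProteinAlignment(
        score=float(score),
        query_span=(int(qblocks[0][0]), int(qblocks[-1][1])),
        subject_span=(int(sblocks[0][0]), int(sblocks[-1][1])),
        aligned_blocks=(tuple(map(tuple, qblocks)), tuple(map(tuple, sblocks))),
    )


def translate_frames(nucleotide: str) -> list[tuple[int, int, str]]:
    """Translate a nucleotide sequence in all six frames.

    Returns (frame, nucleotide_offset_on_oriented_strand, protein) triples;
    internal stop codons are rendered as X (wildcard).
    """
    out = []
    seq = Seq(nucleotide.upper())
    rc = seq.reverse_complement()
    for frame in FRAMES:
        src = seq if frame > 0 else rc
        off = abs(frame) - 1
        sub = src[off: off + 3 * ((len(src) - off) // 3)]
        protein = str(sub.translate()).replace("*", "X")
        out.append((frame, off, protein))
    return out


def call_target(
    locus_id: str,
    bait_protein: str,
    contigs: list[LocusSequence],
    min_score: float = DEFAULT_MIN_SCORE,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> TargetCall | None:
    """Pick the most similar contig/frame to the bait protein as the target.

    The contig is oriented forward (reverse-complemented when the winning
    frame is negative) and the exon span is the nucleotide back-projection of
    the aligned region.  Returns None when no contig reaches ``min_score``.
    Ties on score are broken deterministically: longer contig first, then
    lexicographically smaller contig id.
    """
    if not contigs:
        raise ValueError("contigs must be non-empty")
    candidates = []  # (score, contig_len, contig_id, frame, offset, aln, contig)
    for contig in contigs:
        cid = contig.locus_id if contig.taxon is None else contig.header
        for frame, off, protein in translate_frames(contig.sequence):
            aln = smith_waterman_protein(
                bait_protein, protein, matrix=matrix,
                gap_open=gap_open, gap_extend=gap_extend,
            )
            if aln.score > 0:
                candidates.append((aln.score, len(contig.sequence), cid, frame, off, aln, contig))
    if not candidates:
        return None
    top = max(c[0] for c in candidates)
    if top < min_score:
        return None
    finalists = [c for c in candidates if c[0] == top]
    if len({c[2] for c in finalists}) > 1:
        logger.warning(
            "tie in best target score for locus %s; deterministic tie-break used",
            locus_id,
        )
    # longer contig wins, then lexicographically smaller contig id, then the
    # frame enumeration order (+1..+3, -1..-3)
    finalists.sort(key=lambda c: (-c[1], c[2]))
    _, _, cid, frame, off, aln, contig = finalists[0]
    oriented = (
        contig.sequence
        if frame > 0
        else str(Seq(contig.sequence).reverse_complement())
    )
    aa_start, aa_end = aln.subject_span
    nt_start = off + 3 * aa_start
    nt_end = off + 3 * aa_end
    return TargetCall(
        locus_id=locus_id,
        contig_id=cid,
        exon_span=(nt_start, nt_end),
        frame=frame,
        score=aln.score,
        oriented_sequence=oriented,
    )


def split_outputs(
    calls: list[TargetCall],
) -> tuple[list[LocusSequence], list[LocusSequence]]:
    """Split target calls into exon-only and exon-plus-flank record lists.

    Both lists carry the same ids in the same order; writing them yields the
    pipeline's two FASTA outputs (coding sequences with and without flanks).
    """
    exon_records: list[LocusSequence] = []
    flanked_records: list[LocusSequence] = []
    for call in calls:
        s, e = call.exon_span
        if not (0 <= s < e <= len(call.oriented_sequence)):
            raise ValueError(
                f"exon span {call.exon_span} outside contig for locus {call.locus_id}"
            )
        exon_records.append(
            LocusSequence(locus_id=call.locus_id, sequence=call.exon_sequence)
        )
        flanked_records.append(
            LocusSequence(
                locus_id=call.locus_id,
                sequence=call.oriented_sequence,
                exon_span=call.exon_span,
            )
        )
    return exon_records, flanked_records
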