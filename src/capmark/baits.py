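"""A-posteriori bait refinement from empirical read depth.

Low-complexity regions that escape a-priori repeat masking soak up a
disproportionate share of sequencing reads.  Given per-position read depth
from a pilot capture, this module finds positions whose depth is at least
``ratio`` (default 100x) times the local background, soft-masks them in the
locus sequence, discards loci left with fewer than 120 unmasked bases,
splits longer loci into unmasked segments, and re-tiles 120-nt baits at 2x
(60-nt step).  Baits designed on whole short loci (>= 100 nt in legacy mode)
are padded to 120 nt with 3' T characters, which bind more weakly than G/C
and so perturb hybridization least.

Background depth for a position is the median of the nearest
``flank_window`` non-anomalous positions on each side (floor 1); detection
iterates to a fixpoint so plateaus wider than the window are still fully
masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import DepthProfile, LocusSequence

logger = logging.getLogger(__name__)

DEFAULT_RATIO = 100.0
DEFAULT_FLANK_WINDOW = 100
BAIT_LEN = 120
TILING = 2
MIN_SHORT = 100


@dataclass
class MaskedLocus:
    """A locus with anomalous regions lowercased and bait-eligible segments.

    ``segments`` are the maximal uppercase runs of at least the minimum bait
    length, sorted and non-overlapping.
    """

    locus_id: str
    sequence: str
    segments: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class Bait:
    locus_id: str
    segment_index: int
    offset: int  # 0-based start within the segment
    sequence: str  # exactly bait_len nt
    pad_len: int = 0

    def __post_init__(self) -> None:
        if self.pad_len:
            pad = self.sequence[-self.pad_len:]
            if set(pad) != {"T"}:
                raise ValueError("padding must be 3' T characters")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 0-based half-open spans."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _local_background(depths: np.ndarray, anomalous: np.ndarray, i: int, window: int) -> float:
    """Background depth at i: the lower of the two per-side medians over the
    nearest `window` non-anomalous positions.

    Taking the minimum of the sides means a position only needs to tower over
    one adjacent region, which lets detection start at the edge of a plateau
    wider than the window and propagate inward.
    """
    left: list[int] = []
    j = i - 1
    while j >= 0 and len(left) < window:
        if not anomalous[j]:
            left.append(depths[j])
        j -= 1
    right: list[int] = []
    j = i + 1
    while j < len(depths) and len(right) < window:
        if not anomalous[j]:
            right.append(depths[j])
        j += 1
    medians = [float(np.median(s)) for s in (left, right) if s]
    if not medians:
        return 1.0
    return min(medians)


def detect_anomalies(
    profile: DepthProfile,
    ratio: float = DEFAULT_RATIO,
    flank_window: int = DEFAULT_FLANK_WINDOW,
    max_iter: int = 50,
) -> list[tuple[int, int]]:
    """Spans (0-based half-open) whose depth is >= ratio x local background.

    The background is the median depth of the ``flank_window`` nearest
    positions on each side, excluding positions already flagged as anomalous,
    floored at 1.  Flagging is iterated until no new position qualifies, so
    anomalous plateaus do not inflate their own background.
    """
    if flank_window < 1:
        raise ValueError("flank_window must be >= 1")
    if ratio <= 1:
        raise ValueError("ratio must be > 1")
    depths = profile.depths
    if len(depths) == 0:
        return []
    anomalous = np.zeros(len(depths), dtype=bool)
    for _ in range(max_iter):
        changed = False
        # only positions that could plausibly exceed ratio x 1 need a look
        for i in np.flatnonzero(~anomalous & (depths >= ratio)):
            bg = max(1.0, _local_background(depths, anomalous, int(i), flank_window))
            if depths[i] >= ratio * bg:
                anomalous[i] = True
                changed = True
        if not changed:
            break
    return _runs(anomalous)


def combine_profiles(profiles: Sequence[DepthProfile], how: str = "max") -> DepthProfile:
    """Combine same-locus profiles from several samples position-wise.

    Default ``max``: a region anomalous in any sample gets masked.
    """
    if not profiles:
        raise ValueError("no profiles to combine")
    ids = {p.locus_id for p in profiles}
    if len(ids) > 1:
        raise ValueError(f"profiles from different loci: {sorted(ids)}")
    length = max(len(p) for p in profiles)
    stack = np.zeros((len(profiles), length), dtype=np.int64)
    for k, p in enumerate(profiles):
        stack[k, : len(p)] = p.depths
    if how == "max":
        combined = stack.max(axis=0)
    elif how == "mean":
        combined = np.floor(stack.mean(axis=0)).astype(np.int64)
    else:
        raise ValueError("how must be 'max' or 'mean'")
    return DepthProfile(locus_id=profiles[0].locus_id, depths=combined, sample="combined")


def _merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def mask_and_segment(
    seq: LocusSequence,
    anomalies: Iterable[tuple[int, int]],
    min_len: int = BAIT_LEN,
) -> MaskedLocus | None:
    """Soft-mask anomalous spans and extract bait-eligible segments.

    Segments are maximal unmasked runs of at least ``min_len`` nt
    (pre-existing lowercase counts as masked).  Returns None — the locus is
    discarded — when no segment reaches ``min_len``.
    """
    spans = _merge_spans(anomalies)
    chars = list(seq.sequence)
    for s, e in spans:
        if not (0 <= s <= e <= len(chars)):
            raise ValueError(f"anomaly span ({s},{e}) outside locus {seq.locus_id}")
        for i in range(s, e):
            chars[i] = chars[i].lower()
    masked_seq = "".join(chars)
    unmasked = np.array([c.isupper() for c in masked_seq], dtype=bool)
    segments = [(s, e) for s, e in _runs(unmasked) if e - s >= min_len]
    if not segments:
        logger.info(
            "locus %s discarded: <%d unmasked nt after masking", seq.locus_id, min_len
        )
        return None
    return MaskedLocus(locus_id=seq.locus_id, sequence=masked_seq, segments=segments)


def tile_baits(
    m: MaskedLocus,
    bait_len: int = BAIT_LEN,
    tiling: int = TILING,
    allow_short: bool = False,
    min_short: int = MIN_SHORT,
) -> list[Bait]:
    """Tile each eligible segment with ``bait_len``-nt baits at ``tiling``x.

    The step is ``bait_len // tiling`` (60 nt for the 2x default); the final
    bait is right-aligned to the segment end when the last regular offset
    would overrun.  With ``allow_short`` (legacy short-locus mode) a span of
    ``min_short``..``bait_len``-1 nt yields a single bait padded to
    ``bait_len`` with 3' T's.
    """
    if tiling < 1 or bait_len < 1:
        raise ValueError("tiling and bait_len must be >= 1")
    step = bait_len // tiling
    baits: list[Bait] = []
    for idx, (seg_start, seg_end) in enumerate(m.segments):
        seg = m.sequence[seg_start:seg_end]
        seg_len = len(seg)
        if seg_len >= bait_len:
            offsets = list(range(0, seg_len - bait_len + 1, step))
            if offsets[-1] + bait_len < seg_len:
                offsets.append(seg_len - bait_len)
            for off in offsets:
                baits.append(
                    Bait(
                        locus_id=m.locus_id, segment_index=idx, offset=off,
                        sequence=seg[off: off + bait_len],
                    )
                )
        elif allow_short and seg_len >= min_short:
            pad = bait_len - seg_len
            baits.append(
                Bait(
                    locus_id=m.locus_id, segment_index=idx, offset=0,
                    sequence=seg + "T" * pad, pad_len=pad,
                )
            )
        else:
            logger.warning(
                "segment %d of locus %s (%d nt) below the %d-nt bait floor; skipped",
                idx, m.locus_id, seg_len,
                min_short if allow_short else bait_len,
            )
    return baits


def refine_locus(
    seq: LocusSequence,
    profile: DepthProfile,
    ratio: float = DEFAULT_RATIO,
    flank_window: int = DEFAULT_FLANK_WINDOW,
    bait_len: int = BAIT_LEN,
    tiling: int = TILING,
    allow_short: bool = False,
) -> tuple[MaskedLocus | None, list[Bait]]:
    """Detect anomalies, mask, and re-tile one locus in a single call."""
    if len(profile) != len(seq.sequence):
        raise ValueError(
            f"depth profile length {len(profile)} != sequence length "
            f"{len(seq.sequence)} for locus {seq.locus_id}"
        )
    anomalies = detect_anomalies(profile, ratio=ratio, flank_window=flank_window)
    min_len = MIN_SHORT if allow_short else bait_len
    masked = mask_and_segment(seq, anomalies, min_len=min_len)
    if masked is None:
        return None, []
    # segments below bait_len are only tile-able in legacy mode
    return masked, tile_baits(
        masked, bait_len=bait_len, tiling=tiling, allow_short=allow_short
    )
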