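"""Mask read-depth anomalies and re-tile 120-nt baits at 2x.

Low-complexity regions that escape a-priori repeat masking show up in pilot
captures as plateaus of extreme read depth (100x or more over their
surroundings).  Refinement soft-masks them, discards loci left with fewer
than 120 unmasked bases, and tiles fresh baits over the surviving segments.
"""

import numpy as np

from capmark import DepthProfile, LocusSequence, refine_locus

rng = np.random.default_rng(8)
length = 500
depths = rng.poisson(30, length) + 1
depths[180:240] = 6000  # a 60-nt low-complexity pile-up at ~200x background

seq = LocusSequence(locus_id="Reffish.20.4037479.4035425",
                    sequence="".join(rng.choice(list("ACGT"), size=length)))
profile = DepthProfile(seq.locus_id, depths)

masked, baits = refine_locus(seq, profile)
print(f"masked spans (lowercase): {masked.sequence[175:245]!r} around the plateau")
print(f"eligible segments: {masked.segments}")
for b in baits:
    print(f"  bait seg{b.segment_index} offset {b.offset:3d} "
          f"({'padded ' + str(b.pad_len) + 'T' if b.pad_len else '120 nt'})")
print(f"{len(baits)} baits; consecutive offsets differ by 60 nt (2x tiling), and")
print("no bait overlaps the masked plateau, so re-captures spend no reads there.")
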