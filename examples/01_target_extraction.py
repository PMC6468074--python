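"""Identify target exons in assembled contigs by translated local alignment.

Builds a small synthetic capture (contigs = flank + diverged exon + flank),
then recovers each locus's exon span by comparing the six-frame contig
translations against the bait protein with Smith-Waterman.
"""

from capmark import call_target, split_outputs
from capmark.simulate import SimulationConfig, simulate_capture

cfg = SimulationConfig(
    seed=11, n_loci=4, taxa_per_group=1, groups=("Gobiaria",),
    flank_len_mean=120.0, flank_len_sd=20.0, exon_len_range=(120, 300),
)
cap = simulate_capture(cfg)
taxon = next(iter(cap.contigs))

calls = []
for locus in cap.loci:
    call = call_target(locus, cap.bait_proteins[locus], [cap.contigs[taxon][locus]])
    calls.append(call)
    truth = cap.exon_spans[(taxon, locus)]
    print(
        f"{locus}: exon {call.exon_span[0]}-{call.exon_span[1]} "
        f"(truth {truth[0]}-{truth[1]}), frame {call.frame:+d}, "
        f"score {call.score:.0f}, flanks {call.left_flank_len}/{call.right_flank_len} nt"
    )

exon_recs, flank_recs = split_outputs(calls)
print(
    f"\n{len(exon_recs)} loci called; the exon-only records average "
    f"{sum(len(r.sequence) for r in exon_recs) / len(exon_recs):.0f} nt and the "
    f"flanked records {sum(len(r.sequence) for r in flank_recs) / len(flank_recs):.0f} nt."
)
print("Each call's span should match the planted truth exactly: the bait-covered")
print("region of the best-scoring frame back-projects to nucleotide coordinates.")
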