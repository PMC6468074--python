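"""Marker summary statistics: length, GC, p-distance, and parsimony CI/RI.

CI = M/S and RI = (G-S)/(G-M) summarize homoplasy of an alignment on a
tree: S is the Fitch parsimony length, M the tree-free minimum number of
steps, G the star-tree maximum.
"""

from capmark import SiteAlignment, basic_stats, ci_ri, read_tree

tree = read_tree("((t1,t2),(t3,t4));")
aln = SiteAlignment(
    taxa=["t1", "t2", "t3", "t4"],
    rows=[
        "ACGTACGTAC",
        "GCGTACGTAT",
        "ACGAACGTCC",
        "GCGAACTTCC",
    ],
)

length, gc, pdist = basic_stats(aln)
print(f"mean ungapped length: {length:.0f} nt, GC {100 * gc:.0f}%, "
      f"mean pairwise p-dist {pdist:.3f}")

scores = ci_ri(aln, tree)
print(f"parsimony steps S={scores.S}, minimum M={scores.M}, maximum G={scores.G}")
print(f"CI = M/S = {scores.ci:.2f}   RI = (G-S)/(G-M) = {scores.ri:.2f}")
print("CI = 1 would mean every variable site fits the tree without homoplasy;")
print("lower CI/RI indicate repeated or reversed substitutions on this topology.")
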