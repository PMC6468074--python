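# Methods

This note documents the models, rules and numerical choices behind
`capmark`, and what the synthetic data generator does and does not emulate.

## Target extraction

Contigs are translated in all six frames; internal stop codons are rendered
as the wildcard residue X rather than truncating the frame, so a contig with
a frameshift is matched only up to its best single frame. Each frame is
compared with the bait's amino-acid sequence by optimal local alignment
(Smith–Waterman) with affine gaps. Defaults are BLOSUM62 with gap open 11
and gap extend 1 — the de-facto standard for protein local alignment — in
the convention where a gap of length L costs `open + L·extend`. The aligner
is Biopython's `PairwiseAligner` (local mode); the test suite checks its
scores against an independent top-down recursion that enumerates gap-block
lengths explicitly, itself validated against a pure enumeration of all
alignments at tiny sizes.

The best contig × frame by score wins; ties are broken deterministically
(longer contig, then lexicographically smaller id, then frame order) with a
warning. The exon is the nucleotide back-projection of the aligned subject
span on the oriented (forward-strand) contig. Because bait coverage, not
codon structure, defines the boundary, the exon span may keep partial
codons at its ends. Calls below `min_score` (default 40 matrix units — a
configurable floor, since short spurious local alignments of unrelated
proteins rarely exceed the low 30s under these penalties) return nothing.

## Paralog screening

For each query, the best hit is the maximal bitscore (ties: lower e-value,
longer alignment, smaller subject id). A query is an ortholog iff that hit
lies on the annotated chromosome and its strand-normalized interval
overlaps the annotated target interval by ≥ `min_overlap_bp` (default 1 —
any overlap counts). Strand is ignored for the overlap test. Queries with
no hit at all are retained by default with a warning: absence of a hit is
not evidence of paralogy, only a demonstrably wrong location is.

## Marker selection

Merging keeps, per locus × taxon cell, the longest sequence across
projects; equal-length conflicts keep the first by project order. The
capture filter keeps taxa with *strictly more* than `min_loci_per_taxon`
loci (default 3,000), so a taxon at exactly the threshold is dropped.
Decisiveness is operationalized as coverage of clade groups: a locus is
decisive iff every required group (default: the eight major ray-finned fish
clades — Acipenseriformes, Lepisosteiformes, Elopomorpha,
Osteoglossomorpha, Otomorpha, Gobiaria, Ovalentaria, Eupercaria) has at
least `min_taxa_per_group` (default 1) sequenced representative. This is a
per-locus set-cover test, not graph-theoretic decisiveness over all
possible trees; it is monotone in added sequences, which the suite asserts.

## Bait refinement

A position is anomalous iff its depth is ≥ `ratio` (default 100, inclusive
boundary for determinism) times the local background, where the background
is the *lower* of the two medians over the nearest `flank_window` (default
100) non-anomalous positions on each side, floored at 1. Flagging iterates
to a fixpoint: positions already flagged are excluded from the windows, so
a plateau wider than the window is eaten from its edges inward rather than
inflating its own background. Taking the per-side minimum (rather than a
pooled median) is what lets detection bootstrap at a plateau edge, where
one side is all background and the other all plateau. Depth profiles from
multiple samples may be combined position-wise before detection (`max` by
default: a region anomalous in any sample is masked).

Anomalous spans are soft-masked (lowercase, merged if overlapping);
segments are the maximal unmasked runs ≥ 120 nt, and a locus with no such
segment is discarded. Tiling places 120-nt baits at offsets 0, 60, 120, …
(2× tiling = step of half a bait), right-aligning the final bait to the
segment end when the last regular offset would overrun — padding is *not*
used inside long segments. 3′ T-padding to 120 nt is reserved for whole
short loci of 100–119 nt in legacy mode, mirroring the original short-locus
bait rule (T pads are chosen because A/T pairs bind more weakly than G/C,
perturbing hybridization least). Interior segment positions (≥ 60 nt from
both ends) are covered by exactly two baits; every uppercase base by at
least one; no bait ever contains a masked character.

## RC50

Coverage of a locus is mapped read bases divided by locus length (equal to
mean per-position depth when both derive from the same mapping). Rows are
sorted by coverage descending (ties: mapped bases descending, then locus
id) and RC50 is the smallest k whose cumulative mapped data reaches half
the total (inclusive ≥). Accounting is in mapped *bases* by default —
consistent with the coverage definition — with a `reads` unit available
when per-locus read counts are supplied. RC50 ∈ [1, n]; an even table gives
⌈n/2⌉; concentrating read mass onto top loci can only lower it.

## Marker statistics

p-distance is mismatches over comparable sites, where positions with a gap
or N in either row are excluded; pairs with zero comparable sites are
excluded from the per-locus mean with a warning. GC is computed over all
unambiguous bases of all rows.

Parsimony statistics use Fitch's small-parsimony count on an arbitrary
rooting (the count is root-invariant). Gap/N/? are missing: such leaves
carry the full state set at no cost. Per site, M = (distinct observed
states − 1) and G = (non-missing taxa − count of the most frequent state);
CI = ΣM/ΣS and RI = (ΣG−ΣS)/(ΣG−ΣM). Constant sites contribute zeros to
all sums and are included by default; `informative_only` restricts the
sums to parsimony-informative sites. CI is undefined (error) for an
alignment invariant on the tree; RI is reported as None when ΣG = ΣM.
Polytomies are handled by sequential intersection over children (the
standard Fitch generalization); the brute-force oracle used in testing
enumerates all internal labelings on binary trees of up to 6 leaves.

## Variability tools

Flank filtering applies, in order: ungapped length < 20 nt (`too_short`);
any gap run > 30 (`long_indel`); p-distance to the per-locus-side
majority consensus > 0.6 (`unalignable`). The 20-nt floor is the one
principled constant; the indel and divergence thresholds are deliberately
permissive defaults, CLI-exposed, since no canonical values exist.
Filtering never alters sequences, only statuses.

Majority consensus: per column the most frequent unambiguous base wins;
ties become the IUPAC code of the tied set; columns where gaps are the
strict majority are omitted; all-missing columns yield N. SNP density is
1000 × (columns with ≥ 2 distinct unambiguous bases) / (consensus
reference length), computed separately for coding and flank partitions.

One-best-SNP export reads a VCF, drops indels and multi-allelic records,
and keeps per locus the SNP with the highest QUAL (ties: lowest
missingness, then smallest position) as a diploid alternate-allele dosage
matrix (0/1/2, NaN for missing). "Best" = highest QUAL is a design choice;
the matrix guarantees ≤ 1 column per locus so ordination does not
double-count linked sites.

## Synthetic data generator

`simulate_capture` emulates a multi-project capture study: per locus a
random stop-free open reading frame (uniform 100–600 nt by default) with an
ancestral flank pair (lengths ~ Normal(800, 150) nt truncated at 0, placing
flank length where pilot captures typically center); each sampled taxon's
contig is flank + coding + flank. Variation is planned per locus: each site
is polymorphic with probability equal to the configured rate (0.035/site
coding, 0.050/site flanks by default, i.e. expected densities of 35 and 50
SNPs per kb), one derived allele per site, carried by each taxon with
frequency 1/2. Substitutions creating stop codons are reverted, and the
first and last exon codon stay invariant so the planted exon boundary is
the unique optimal alignment boundary. Missingness knocks out taxon × locus
cells at random; a configured fraction of loci is planted decisive (one
representative per group forced present), the rest have one whole group
knocked out, making the planted decisive set exactly recoverable.
`simulate_depth` draws Poisson backgrounds (mean 30×, floored at 1) with
injected plateaus at a configured fold (200× by default, matching the
magnitude of low-complexity pile-ups seen in pilot data).
`simulate_paralogs` plants off-target best hits for a configured fraction
of loci. Tree-based generators evolve sites down a newick either with a
per-edge substitution probability or with exactly one mutation per variable
site (guaranteed homoplasy-free, for CI = 1 checks). All generators are
driven by a single numpy `default_rng(seed)`; the same seed yields
byte-identical output.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: indels and alignment uncertainty (generated
same-locus sequences are aligned by construction; real data needs an
aligner and inherits its errors), rate heterogeneity across sites,
tree-structured divergence in the capture generator (allele sharing is
unlinked to any phylogeny, so CI/RI on capture fixtures are lower than on
tree-evolved data), sequencing error, chimeric or fragmented assemblies,
and cross-contamination.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full pipeline exercises every rule in seconds: 8–40 loci per synthetic
study, 8–16 taxa (one or two per clade group), flanks of 150–300 nt in
pipeline runs, 20 seeded end-to-end replicates, 100 replicates for the
flank-vs-coding direction property, and oracle sweeps of 200–1,000 random
instances per kernel. A real study (thousands of loci, ~100 samples) uses
the same code paths; only the input sizes differ.

## Known limitations

- Anomaly detection assumes depth profiles long enough to contain
  background on at least one side of a spike; a locus that is anomalous
  end-to-end has no background and is not flagged (its depth is "uniformly
  high", indistinguishable from a well-captured short locus).
- The decisiveness test is per-locus group coverage, not decisiveness over
  tree space; loci passing it can still be uninformative for particular
  within-group relationships.
- CI/RI assume the supplied tree covers exactly the alignment's taxa;
  subsetting a larger tree is the caller's responsibility (the CLI does
  this per locus).
- `select_best_snp` trusts upstream VCF QUAL values; with capped or missing
  QUALs the tie-breaks (missingness, then position) dominate.
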