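# capmark

Curation of single-copy exon-capture markers and a-posteriori refinement of
hybridization baits, for phylogenomic studies built on target enrichment
(developed with ray-finned fishes in mind, but organism-agnostic).

Exon capture hybridizes synthetic 120-nt RNA/DNA baits to genomic libraries
to enrich chosen coding loci before sequencing. After a pilot capture, a
series of computational questions decide whether the marker set is worth
scaling up: which contig carries each target and where the exon ends and
the flanking sequence begins; which sequences are paralogous contaminants;
which loci are complete enough across clades to be phylogenetically useful;
and which bait regions are silently soaking up sequencing reads and should
be masked before baits are re-synthesized. `capmark` implements that
post-capture pipeline as a Python library with a thin CLI.

## What it computes

- **Target extraction** — each assembled contig is translated in all six
  frames and compared with the bait's amino-acid sequence by local
  (Smith–Waterman) alignment under affine gaps (BLOSUM62, gap open 11,
  extend 1). The bait-covered region of the best frame back-projects to
  nucleotide coordinates: that is the exon; the rest of the contig is
  flanking sequence.
- **Paralog screening** — a sequence whose best genome hit (by bitscore)
  does not overlap its annotated target region is flagged as a potential
  paralog and excluded.
- **Marker selection** — projects are merged (longest sequence wins per
  cell), taxa with too few captured loci are dropped (strictly more than
  the threshold are kept; 3,000 by default), and a locus is kept as
  *phylogenetically decisive* iff every required clade group has at least
  one sequenced representative at it.
- **Bait refinement** — positions whose read depth is ≥ 100× the median of
  the adjacent non-anomalous windows are soft-masked (lowercase); loci with
  < 120 unmasked nt are discarded, longer ones are split into unmasked
  segments, and 120-nt baits are re-tiled at 2× (60-nt step), with 3′
  T-padding for whole short loci of 100–119 nt.
- **Evenness (RC50)** — with loci sorted by read coverage
  (mapped bases / locus length) in descending order, RC50 is the number of
  top loci consuming half of all mapped data. An even capture of *n* loci
  gives ⌈n/2⌉; higher RC50 means more even coverage.
- **Marker statistics** — ungapped length, GC, pairwise p-distance
  (gaps/N excluded), and parsimony consistency/retention indices on a tree:
  CI = M/S and RI = (G−S)/(G−M), with S the Fitch parsimony length, M the
  tree-free minimum steps, and G the star-tree maximum.
- **Variability tools** — flank filtering (< 20 nt, long indel runs,
  unalignable), SNP densities per kb for coding vs flanking partitions,
  majority-rule consensus references, and one-best-SNP-per-locus genotype
  export (highest QUAL) for ordination without linked sites.
- **Synthetic fixtures** — seeded generators for every input format, so the
  entire pipeline runs and is tested without any external data.

## Worked example

`examples/` holds one short script per capability. For instance, bait
refinement on a 500-nt locus with a 60-nt pile-up at ~200× background
(`python examples/03_bait_refinement.py`):

```
eligible segments: [(0, 180), (240, 500)]
  bait seg0 offset   0 (120 nt)
  bait seg0 offset  60 (120 nt)
  bait seg1 offset   0 (120 nt)
  bait seg1 offset  60 (120 nt)
  bait seg1 offset 120 (120 nt)
  bait seg1 offset 140 (120 nt)
6 baits; consecutive offsets differ by 60 nt (2x tiling), and
no bait overlaps the masked plateau, so re-captures spend no reads there.
```

The anomalous span [180, 240) is lowercased, the two surviving segments are
each ≥ 120 nt, and the final bait of each segment is right-aligned to the
segment end. Re-simulating capture after refinement raises RC50
(`python examples/04_evenness_rc50.py`):

```
RC50 with original baits:  5 of 30 loci
RC50 with refined baits:   16 of 29 loci
```

The same operations are available from the shell:

```bash
capmark extract --baits baits.faa --contigs contigs.fasta --out-prefix sample1
capmark paralog --hits hits.tsv --targets targets.tsv --out verdicts.tsv
capmark select --matrix-dir proj1 --matrix-dir proj2 --groups groups.tsv \
               --min-loci 3000 --out decisive.txt
capmark refine --fasta loci.fasta --depth depth.tsv \
               --out-masked masked.fasta --out-baits baits.fasta --report refine.tsv
capmark rc50 --coverage coverage.tsv --out stats.json
capmark stats --aln-dir alignments/ --tree tree.nwk --out stats.tsv
capmark vcf2geno --vcf calls.vcf --out geno.tsv
capmark simulate capture --seed 7 --out-dir fixtures/
```

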