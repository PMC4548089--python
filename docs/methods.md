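# Methods

## Scope and model

`plastcomp` treats a plastome as a circular DNA molecule presented in its
deposited linear orientation, annotated with genes (protein-coding, tRNA,
rRNA) whose exons are half-open intervals on the genome. All internal
coordinates are 0-based half-open; every report writer converts to 1-based
inclusive. Two genomes are compared through a single global alignment; all
mutation events are defined on that alignment, polarized against a
designated reference row (insertion = material present in the other genome,
deletion = material present in the reference).

### Quadripartite structure

The partition is defined by the maximal pair of disjoint, exactly
reverse-complementary segments of length ≥ `min_ir_len` (default 1000 bp).
Detection is seed-and-extend between the sequence and its reverse
complement (20-mer seeds, one extension per diagonal), so it is linear-time
in practice. The longer arc between the two repeat copies is labelled LSC,
the shorter SSC; IRb is the copy that follows the LSC in genome order. The
exact-match definition is deliberate: the two repeats of a plastome are
typically length-identical, and a mismatch-tolerant mode is out of scope.
If a single-copy region would span the sequence origin the detector raises
a documented error directing the caller to `rotate_genome`; rotating
changes coordinates, and we prefer an explicit step over a silent one.

### Alignment

The internal aligner is a global affine-gap Needleman–Wunsch (Gotoh) with
integer scores (defaults: match +1, mismatch −2, gap open −5, gap extend
−2; a length-L gap costs `open + L·extend`). Ties are broken
deterministically: diagonal over gap, gap in the second row over gap in the
first. Columns containing N score 0. Affine penalties make a large indel
(e.g. ~100 bp) align as one gap run rather than fragmenting.

Genome-scale pairs do not fit the full DP, so the aligner chains unique
shared k-mers (k = 32, halving on recursion) into a colinear set of exact
anchors (longest-increasing-subsequence chaining) and runs the exact DP
only between anchors. For two highly similar colinear plastomes the
inter-anchor segments are tens of bases, and the result equals the full DP
(verified in tests by forcing the anchored path on sequences small enough
to also run exactly). A segment that remains too large after anchor
refinement falls back to a unit-cost alignment (edlib) — in practice this
is only reachable for low-identity inputs outside the tool's intended use.

The pipeline equally accepts an externally produced alignment (aligned
FASTA or Clustal), which is the faithful route when reproducing published
counts: manual alignment adjustment cannot be reproduced algorithmically,
so counts on real genome pairs are alignment-sensitive by a few events.

### SSR detection

Microsatellites are maximal exact tandem repeats of a 1–2 bp motif,
reported on the given strand (an A-run and a T-run are distinct motifs).
Thresholds are in repeat units: mono ≥ 8, di ≥ 4 by default; dinucleotide
motifs must not be homopolymers. Overlapping loci (a homopolymer abutting
an alternating tract) are resolved by keeping the longer span. The
thresholds are configurable because published SSR tables sometimes include
loci one unit below a stated floor in one of the two genomes; when two
genomes are paired, a locus below threshold in one genome simply shows an
empty unit count on that side.

### Event calling

Order matters and is fixed: inversions → indels → SNPs.

1. **Micro-inversions.** Mismatch columns separated by at most 5 matching
   columns (no gaps, no Ns) form clusters. A cluster with ≥ 2 mismatches is
   an inversion if some gap-free span containing it (boundaries extended by
   up to 3 matching columns, total span within [3, 50] bp by default) has
   the alternate segment exactly equal to the reverse complement of the
   reference segment. The boundary extension matters because the outermost
   bases of an inverted segment can match their complemented counterparts
   by chance. Consumed columns are excluded from the later stages, so a
   5-bp inversion is one event, not several SNPs. A single mismatch is
   always a SNP: a 1-bp "inversion" is indistinguishable from, and more
   parsimoniously described as, a substitution.
2. **Indels.** One event per maximal gap run in either row. Events are
   left-normalized (VCF convention): an indel inside a repeat is reported
   at the leftmost equivalent position, which also makes called positions
   agree with the generator's ledger. An event is **SSR-type** iff an SSR
   locus of the genome carrying the longer allele overlaps (or touches) the
   event site, its motif length (1–2) divides the event size, and repeating
   that motif reproduces the event sequence; the longer allele necessarily
   meets the reporting threshold because the locus comes from that genome's
   scan. Everything else is non-SSR.
3. **SNPs.** One per remaining column where both rows carry unequal,
   non-gap, non-N bases. Ts iff both bases are purines or both pyrimidines.
   The GC class is AT↔TA, CG↔GC, or GC-changing (every transition is
   GC-changing; the first two classes are the GC-neutral transversions).

Columns containing N in either row are excluded from all calling.

### Summaries

Region percentages pool IRa+IRb into "IR" and are printed to 2 decimals.
Events duplicated by the IR symmetry (same type at mirror-image positions)
are counted once, attributed to the IR — a naive pairwise comparison sees
an IR mutation twice, once per copy. Compartment counts distinguish
exon/intron/intergenic using the reference annotation; intergenic loci are
named `geneA-geneB` by the flanking genes in genome order, wrapping at the
ends of the linearized circle.

### Coding effects

Codons are read on the gene's strand with introns spliced out and
translated with NCBI table 11. Each SNP is scored independently against the
reference codon (other nearby variants held at reference), the counting
convention used by standard MEGA-style tables. SNPs in tRNA/rRNA exons get
no S/N call; by default they are also excluded from the "coding" SNP count
(coding = protein-gene exons), with `coding_includes_rna` covering the
alternative reading, since published gene tables list only protein genes.
Start codons get no special casing: a substitution there is scored by
amino-acid identity. A spliced length not divisible by 3 is truncated with
a warning. The gene → functional-category map (photosynthetic apparatus /
photosynthetic metabolism / gene expression / other) ships as YAML and can
be replaced.

### Nucleotide diversity

Windows slide over **alignment columns**, not reference coordinates, with
window 600 and step 200 by default; the trailing partial window is
dropped. For each window and each pair of rows, sites with a gap or N in
either row are excluded from both numerator and denominator; the window's π
is the mean over pairs of (differing/valid). A window with no valid sites
reports π = 0 and is flagged. The profile's headline mean is the
**per-window mean** (matching the sliding-window framing); a per-site
aggregate is available by setting window = step = alignment length.
Hotspots are maximal runs of adjacent windows with π strictly above the
threshold, merged and labelled with the reference loci they overlap.
Between-genus comparisons run as a 3-row alignment with the same π
definition and the higher threshold (0.015 instead of 0.008).

## Synthetic data: what it emulates and what it does not

`make_genome` builds a genome with the canonical architecture at reduced
scale — defaults LSC 20 kb, IR 4 kb ×2, SSC 5 kb (about a fifth of a real
plastome), 40 genes with real plastome gene names so the category map
applies, ~40% of protein genes with one intron, ~40% on the minus strand,
CDSs that start ATG, end in a stop, and contain no internal stop. Planted
SSR tracts (80% mono with 8–14 units, 20% di with 4–7 units; density 1.2
tracts per kb of single-copy spacer, enough to support slippage-indel
testing) are recorded in metadata with guard bases that make each tract
exactly maximal. Background sequence is run-broken (mono runs ≤ 4,
alternations ≤ 5 bases) so no chance microsatellite reaches the reporting
threshold outside exons.

`mutate` plants the spectrum's events — by default 50 SNPs (Ts fraction
0.5), 10 SSR slippage indels (±1–2 units of a planted tract), 10 non-SSR
indels (size mix dominated by 1–7 bp with occasional 10/21/22/94 bp
events), and one 5-bp micro-inversion — at sites separated by at least
20 bp, in single-copy regions, with indels and inversions kept out of
exons. Sites are chosen so each event is an isolated, unambiguous
difference: indel junctions cannot slide by more than a couple of bases,
and inverted segments differ from their reverse complement at both ends so
the inversion is detectable in principle. Annotation and planted-tract
records are lifted over the indels by exact interval arithmetic. The
per-type ledger positions use the same left-normalized convention as the
caller. All randomness flows from the spectrum's single seed.

What this does **not** emulate, and hence what passing recovery tests do
not show about real data: rate heterogeneity along the genome (real
mutations cluster; the generator spaces them), mutations inside the IR
(real IR mutations appear in both copies via copy correction; the
generator avoids the IR entirely, so the IR-deduplication path is
exercised only by targeted unit tests), compound/interrupted
microsatellites, events closer than the spacing floor (a "hard mode" with
spacing 0 can be configured but exact recovery is then not guaranteed),
and alignment ambiguity from manual curation. Recovery at
precision = recall = 1 demonstrates internal consistency of the calling
cascade under clean conditions, not accuracy on arbitrarily diverged pairs.

## Numerical and formatting choices

- Integer alignment scores; traceback by recomputation with a fixed
  preference order, so alignments are bit-reproducible.
- π written with 5 decimals, percentages with 2; report rows sorted by
  position — repeated runs produce byte-identical outputs.
- Degenerate inputs: empty event lists summarize to zero counts with empty
  percentage maps and a logged note; FASTA without annotation yields a
  feature-less genome on which coding analyses are unavailable; IUPAC
  ambiguity codes other than N are degraded to N on input with a count.
- Recovery matching tolerance is ±2 bp by reference position, greedy in
  position order. With no calls for a type, precision is reported as 1.0
  with an explicit `no_calls` flag rather than NaN.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
33-kb pairs (20 seeds for round-trip recovery), 2-kb random sequences for
the SSR oracle, ≤ 8-base pairs for exhaustive aligner checks, and 1000
random SNPs for the S/N oracle — a few seconds end to end on one CPU.
Applying the pipeline to real ~150-kb plastome pairs from GenBank flat
files uses the identical code path (anchored alignment keeps it fast) and
is covered by a dedicated acceptance test that activates when the
accession files are placed under `data/accessions/`.

## Known limitations

- IR detection is exact-match only and reports an error rather than a
  rotated result when a single-copy region spans the deposited origin.
- The internal aligner is pairwise; 3-row analyses require an external
  alignment.
- Multi-nucleotide substitution events are not modelled: adjacent
  substituted columns are separate SNPs unless consumed by an inversion,
  matching the per-site counting style of published tables.
- SSR classification of an indel depends on the scan thresholds; an indel
  in a repeat just below threshold is non-SSR by definition here.
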