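# Methods

This note records the models, conventions and numerical choices behind
`plastovar`, and what the synthetic material does and does not
demonstrate.

## Coordinates and the quadripartite model

All internal coordinates are 0-based half-open; every human-facing
table is 1-based inclusive (GenBank convention). The genome is treated
as circular but stored linearised at the published origin; intervals
that wrap the origin are represented as circular intervals with
explicit linear pieces.

The quadripartite structure is defined purely from sequence: the
partition induced by the longest pair of exact reverse-complement
repeats whose copies do not overlap on the circle. Plastome IRs are
near-perfect in practice, and exactness keeps the detector
deterministic: there are no mismatch or scoring parameters. Detection
binary-searches the repeat length with a polynomial rolling hash
(modulus 2^61−1, base 131) over the doubled sequence, verifying every
hash hit by direct string comparison, so hash collisions cannot produce
a wrong answer. The longer inter-repeat arc is the LSC by definition;
IRb is the copy whose downstream arc is the SSC. Ties (equal arcs,
multiple repeat pairs at the maximal length) break toward the leftmost
start. The default minimum repeat length is 10 kb — well above any
incidental repeat and well below real plastome IRs (~22–26 kb); for
reduced-scale synthetic genomes it must be lowered accordingly (the
CLI exposes `--min-ir`). Per-region tallies pool IRa and IRb into one
"IR" class, since every IR feature exists in both copies.

Position context is exon if the position lies in any exon/tRNA/rRNA
interval, else intron (introns are always derived as inter-exon gaps of
a gene's parts, never read from file), else spacer. Interval features
(an SSR, an indel) are labeled by their start position. Spacer names
are generated from the flanking gene names as "geneA-geneB".

## SSR scanning

Maximal perfect tandem repeats of unit length 1–6 on the forward
strand, with minimum copy numbers 10/5/4/3/3/3 — the parameterisation
in common use for chloroplast surveys. Conventions:

* an interval is attributed to the smallest unit whose perfect
  repetition spans it: motifs that are themselves periodic (AA, ATAT)
  are rejected, so a poly-A run is one mononucleotide locus;
* partial trailing copies are not counted (interval length is always
  unit × copies);
* runs containing N break at the N; repeats spanning the circular
  origin are not reported;
* reported loci never overlap: when runs of different unit lengths
  collide, the earlier-starting (then smaller-unit) run wins and the
  other is trimmed, in unit phase, to its remainder — and kept only if
  the remainder still meets its threshold;
* compound/interrupted repeats are not merged; each perfect run stands
  alone;
* reporting is strand-symmetric: the canonical class is the
  lexicographically smallest rotation over both strands, labeled with
  its complement (A/T, AT/TA, AG/TC …).

## Variant calling from a fixed alignment

The alignment is an input, not computed internally — indel counts in
particular depend materially on the aligner, so the tool records its
thresholds in the summary header and leaves alignment provenance to the
user. One taxon (default: the first) is the coordinate reference; at
columns where the reference is gapped, events take the coordinate of
the preceding reference base.

Every variable column belongs to exactly one event type. Inversions are
searched first; the columns they absorb are excluded from SNP calling;
columns containing any gap belong to indel events and never to SNPs.

**SNPs.** A site is a gap-free, N-free column with ≥2 alleles. Each
variant allele receives a directed class from the majority allele to
itself, collapsed with its reverse complement into the six
non-strand-specific types. Majority ties resolve toward the reference
allele — the polarisation is a reproducible majority-rule proxy, not an
ancestral-state reconstruction, and multi-allelic sites contribute one
substitution per variant allele (so substitutions can exceed sites).
The first two classes (A→G/T→C, G→A/C→T) are the transitions.

**Indels.** Maximal runs of columns sharing one gap pattern are single
events; adjacent columns with different patterns split. Polarity is
insertion when the sequence-bearing taxa are the minority, deletion
when the gap-bearing taxa are, and unresolved on an even split (counted
once either way). An event is an SSR-indel when its sequence is a whole
number of copies of a primitive unit of ≤2 bp (configurable) and the
longer allele carries a perfect run of that unit, covering the event
site, whose total copy number meets the scan threshold for that unit —
the slippage signature. Everything else is an NR-indel. This threshold
criterion means copy-number changes at sub-threshold runs (e.g. A9 ↔
A8) classify as NR: a deliberate, reproducible line that a manual
curator might draw elsewhere.

**Small inversions.** For each cluster of nearby mismatching gap-free
columns, windows of 2–6 bp containing the cluster are tested: the taxa
must split into exactly two groups whose segments are exact reverse
complements, and the immediate flanks — identical in all taxa — must
contain an exact inverted repeat of ≥3 bp ending at the window
boundaries (the longest such repeat ≤20 bp is reported as the stem).
The hairpin capability is thus established by the exact
reverse-complement stem test rather than free-energy folding: the
stems involved are exact repeats, and an exact test is deterministic
and dependency-free. The smaller taxon group is reported as inverted
(tie → the group not containing the reference). A caveat follows from
the definition: a lone substitution to the complementary base inside a
palindromic context with a chance stem is *formally indistinguishable*
from a 2 bp inversion; the caller attributes such a column to the
inversion, and the simulator avoids planting substitutions at such
sites (below).

## Nucleotide diversity and hotspots

π is the average proportion of pairwise differences across sequences,
per window, using only columns gap-free and N-free in all taxa within
the window (complete deletion per window, matching the behaviour of the
standard sliding-window tool); no Jukes–Cantor correction is applied.
Windows are 600 columns advancing by 100 (both configurable; an 800 bp
window is available by flag), defined over alignment columns with
midpoints projected to reference coordinates; the trailing partial
window is dropped for constant-width comparability. Windows with zero
usable sites carry undefined π and are excluded from the mean — an
undefined π is signalled, never reported as zero. Consecutive windows
with π above the threshold (default 0.01) merge into one hotspot,
annotated with every overlapping gene and spacer name.

## The synthetic quartet generator

The generator emulates the study design the pipeline targets: four
closely related plastomes, one of which serves as reference. The
ancestor is a random sequence at a target GC (default 38.5%, the
Poaceae plastome value) with LSC/IR/SSC fractions matching real
proportions, genes (some with introns, IR genes mirrored across the
copies) spread evenly through each region, and SSR loci planted with
flanking bases that cannot extend the run. Background composition is
drawn as an exact-count shuffle — separately for the single-copy
regions and the (duplicated) IR — and compensated for the A/T-rich
planted repeats, so assembled GC hits its target without sampling
noise. Accidental background repeats that meet scan thresholds are
broken by single-base edits (mirrored into the other IR copy where
needed), and chance reverse-complementarity at the region junctions is
broken so that the planted IR is exactly the longest repeat pair.

Each taxon then receives its event plan:

* substitutions drawn per six-class plan, with the ancestral base
  chosen to admit the class; IR substitutions are applied to both
  copies (complemented) and recorded once, occupying two alignment
  sites; triallelic sites place two derived alleles on two taxa;
* SSR slippage events change a planted locus's copy number by ±1–2
  units (insertions extend the run's end; deletions remove whole
  units);
* NR-indels insert freshly drawn, or delete ancestral,
  non-slippage-classifiable sequence (the guard mirrors the indel
  classifier exactly, so planted NR events can never classify as SSR);
* inversions install a cassette — stem, segment, reverse-complement
  stem — into the ancestor and flip the segment in the carrier taxon;
  the segment's ends are chosen to mismatch after flipping, and the
  bases just outside the cassette are adjusted so the detected stem
  length equals the planted one.

All events sit ≥10 bp apart (and away from planted repeats), so the
true alignment is built by construction and no aligner is involved.
Two further placement rules keep planted truth unambiguous:
substitutions are rejected at sites where they would mimic a small
inversion (see above) or create a threshold repeat; and background
(non-hotspot) substitutions keep a 60 bp spacing, with exclusion pads
around inversions and indels ≥20 bp, so that no 600 bp window of
background crosses the 0.01 hotspot threshold — planted hotspots are
then provably the only hotspots. Real plastome mutation is not spaced
like this; the spacing is an emulation device that makes hotspot counts
a deterministic property of the plan.

The truth ledger records every event with its alignment columns and
replays onto the ancestor to reproduce each genome bit-exactly; same
config and seed give byte-identical output.

Two canned configurations exist. The desk-scale default (20 kb, 60
substitutions at 40:20 Ts:Tv, 12 SSR-indels, 15 NR-indels, 3
inversions) drives the recovery tests. The full-scale emulation
(~140.9 kb ancestor; the reference measures 140,755 bp with
LSC/IR/SSC of 82,686/22,783/12,503 bp after its planned deletions)
plants 633 substitution sites — 615 biallelic (9 of them IR-mirrored,
hence 18 IR alignment sites) plus 18 triallelic — for 651 substitutions
in the 179/166/92/92/92/30 class spectrum (345 transitions, 306
transversions, Tv/Ts 0.89), distributed 518/18/97 over LSC/IR/SSC; 43
slippage indels (39 at A/T runs, 3 at C/G runs, 1 dinucleotide) whose
copy-number targets make the four genomes scan at 41/45/41/38 SSR loci;
94 NR-indels from a size mixture concentrated at 1 and 5 bp with a long
tail to 165 bp (the largest a reference deletion); and nine 2–6 bp
inversions with 3–20 bp stems, eight private to the most divergent
taxon. Substitution clusters in four spacers (rps16-trnQ, trnG-trnM,
rbcL-psaI in the LSC; rps15-ndhF in the SSC) make exactly those four
regions emerge as π hotspots. Hotspot spacers are 500 bp so that one
600 bp window at the 100 bp grid always covers a whole cluster.

**What passing on this material shows — and what it does not.** Exact
recovery demonstrates that the callers are correct on isolated,
unambiguous, truth-aligned events. It does not exercise aligner
artefacts (gap placement ambiguity, indel realignment), nested or
overlapping events, repeat-mediated misalignment, IR
expansion/contraction, or base ambiguity codes — all present in real
data. Alignment-dependent counts on real genomes are therefore
expected to vary at the percent level with aligner choice and version.

## Problem sizes and determinism

The test suite runs the desk-scale quartet (shared fixture), ~100
random small-genome (6–9 kb) configurations for the invariant sweep,
and one full-scale emulation for the worked ratio; the acceptance
script runs one full-scale emulation plus one desk-scale recovery.
These sizes keep any single run under a minute on one CPU while
preserving every structural property of the full-size problem (the
full-scale emulation *is* full-size). All randomness flows from a
single integer seed through NumPy's PCG64; derived seeds stay below
2^31.

## Known limitations

* Gene counting is read from annotations, not recomputed; whether
  IR-duplicated genes are deduplicated by name or locus follows the
  input annotation.
* The pipeline assumes a 4-letter alphabet plus N; other ambiguity
  codes are rejected at parse time.
* SSRs spanning the circular origin are not detected (published
  origins sit in the LSC, far from repeat-dense regions).
* Indel left-normalisation across equivalent gap placements is out of
  scope: the input alignment is taken as ground truth.
* The inversion caller requires segment and flanks gap-free in all
  taxa; inversions overlapping indels are not called.
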