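# plastovar

Comparative variation analysis of chloroplast genomes (plastomes), built
for studies that compare a small set of closely related plastomes — for
example the four *Sorghum* species whose complete chloroplast genomes
differ by a few hundred substitutions, a hundred-odd indels and a
handful of tiny inversions — and need those differences partitioned,
classified and mapped reproducibly.

## What it computes

Land-plant plastomes are circular ~120–160 kb molecules with a
quadripartite organisation: a large and a small single-copy region (LSC,
SSC) separated by two identical inverted repeats (IRb, IRa). Given
plastome records (GenBank flat file or FASTA) and a pre-computed
multiple sequence alignment, `plastovar` runs:

1. **Quadripartite partitioning** — the LSC/IRb/SSC/IRa structure is the
   partition induced by the longest pair of exact reverse-complement
   repeats (circular search, no mismatches); every position gets a
   region label (LSC/SSC/IR) and an annotation context
   (exon/intron/spacer).
2. **Microsatellite (SSR) scanning** — maximal perfect tandem repeats of
   1–6 bp units with the standard chloroplast thresholds (≥10 copies for
   mononucleotides; 5/4/3/3/3 for longer units), each interval
   attributed to the smallest spanning unit and collapsed over rotation
   and strand into canonical families (A/T, AT/TA, …).
3. **Variant calling from the alignment**, partitioning every variable
   column into exactly one of:
   * **SNP sites** — gap-free columns with ≥2 alleles; each variant
     allele is classed into one of the six non-strand-specific directed
     substitution types (A→G/T→C, G→A/C→T, A→C/T→G, C→A/G→T, A→T/T→A,
     G→C/C→G), directed from the majority allele (ties → reference);
     transition/transversion totals and the Tv/Ts ratio follow.
   * **Indel events** — maximal column runs with an identical gap
     pattern, with insertion/deletion polarity by majority state, split
     into microsatellite-related (SSR-indel: the sequence is whole
     copies of a ≤2 bp unit inside a threshold-passing run) and
     non-repeat (NR-indel).
   * **Small inversions** — 2–6 bp segments carried in
     reverse-complement orientation by a taxon subset, accepted only
     when flanked by an exact inverted repeat of 3–20 bp (the hairpin
     stem that mediates such flips).
4. **Sliding-window nucleotide diversity** — π (mean pairwise difference
   proportion, complete deletion per window, no distance correction)
   over 600 bp windows stepping 100 bp; consecutive windows with
   π > 0.01 merge into mutational hotspots named by the reference
   annotation (e.g. *rps16-trnQ*).

A synthetic-data module generates full plastome quartets with planted
structure, annotations, SSRs and substitution/indel/inversion events,
together with the true alignment and a machine-readable truth ledger —
so the entire pipeline is testable end-to-end without downloading
anything.

## Worked example

Simulate a 20 kb quartet and run the full pipeline on it:

```bash
plastovar simulate --seed 42 --length 20000 --out-dir sim
plastovar run \
  --genomes sim/taxonA.fasta,sim/taxonB.fasta,sim/taxonC.fasta,sim/taxonD.fasta \
  --alignment sim/alignment.fasta --reference taxonA \
  --min-ir 1000 --out-dir out
```

`out/summary.json` then contains (abridged):

```
genomes.taxonA:  length 20000, lsc 11748, ir 3238, ssc 1776, gc 38.6%, 17 SSRs
variants.snp:    60 sites (44 LSC, 16 SSC), 40 transitions, 20 transversions
variants.indel:  27 total = 12 SSR-indels + 15 NR-indels
variants.inversions: 3 (lengths 4/6/2 bp, stems 8/14/12 bp)
diversity:       mean_pi 0.00179
```

meaning: the detector recovered the planted quadripartite structure
exactly; sixty substitution sites split 40:20 into transitions and
transversions; twelve of the 27 indels are microsatellite slippage
events; and the three planted hairpin-flanked inversions were found
with their exact stem lengths. Per-event tables are in `out/*.tsv`,
hotspot intervals in `out/hotspots.bed`.

The same pipeline functions are available as a library
(`plastovar.find_quadripartite`, `scan_ssrs`, `call_variants`,
`sliding_profile`, `simulate_quartet`, …); the command-line interface is
a thin wrapper over them.

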