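"""SNP, indel and small-inversion calling from a multiple alignment.

The input is a fixed multiple sequence alignment (computed externally,
e.g. with MAFFT) of a set of plastomes; one taxon is the coordinate
reference.  Three mutually exclusive event types are called, so that
every variable alignment column is attributed to exactly one of them:

* **SNP sites** — gap-free, N-free columns with >= 2 alleles.  Each
  variant allele is assigned one of six non-strand-specific directed
  substitution classes (a directed change pooled with its
  reverse-complement counterpart, e.g. A->G with T->C).  Direction runs
  from the majority allele (ties resolved toward the reference allele)
  to the minority allele.  The two purine<->purine / pyrimidine<->
  pyrimidine classes are transitions; the other four are transversions.
* **Indel events** — maximal runs of columns sharing an identical gap
  pattern across taxa.  Events whose inserted/deleted sequence is a
  whole number of copies of a short unit sitting inside a
  threshold-passing repeat run are microsatellite-related (SSR-indel);
  the rest are NR-indels.
* **Small inversions** — 2-6 bp segments carried in reverse-complement
  orientation by a taxon subset, flanked by an inverted repeat of 3-20
  bp that lets the region fold into a hairpin (stem-loop).  Columns
  explained by an inversion are removed from the SNP list.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

from .io import (
    PlastomeRecord,
    QuadripartiteStructure,
    classify_position,
    revcomp,
)
from .ssr import DEFAULT_THRESHOLDS, _is_primitive

__all__ = [
    "AlignmentSet",
    "SNPSite",
    "IndelEvent",
    "InversionEvent",
    "SUBSTITUTION_CLASSES",
    "TRANSITION_CLASSES",
    "load_alignment",
    "call_snps",
    "call_indels",
    "call_inversions",
    "call_variants",
    "snp_summary",
]

GAP = "-"

#: the six non-strand-specific directed substitution classes, in the
#: conventional order (two transitions first, then four transversions)
SUBSTITUTION_CLASSES = (
    "A→G/T→C",
    "G→A/C→T",
    "A→C/T→G",
    "C→A/G→T",
    "A→T/T→A",
    "G→C/C→G",
)
TRANSITION_CLASSES = frozenset(SUBSTITUTION_CLASSES[:2])

_CLASS_OF_PAIR: dict[tuple[str, str], str] = {}
for _label in SUBSTITUTION_CLASSES:
    _first, _second = _label.split("/")
    for _part in (_first, _second):
        _a, _b = _part.split("→")
        _CLASS_OF_PAIR[(_a, _b)] = _label


def substitution_class(ancestral: str, derived: str) -> str:
    """Six-class label for a directed base change (strand-collapsed)."""
    try:
        return _CLASS_OF_PAIR[(ancestral, derived)]
    except KeyError:
        raise ValueError(f"not a substitution: {ancestral}->{derived}") from None


@dataclass
class AlignmentSet:
    """A loaded multiple alignment with per-taxon coordinate maps."""

    taxa: list[str]
    rows: list[str]
    reference_taxon: str

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if self.reference_taxon not in self.taxa:
            raise ValueError(
                f"reference taxon {self.reference_taxon!r} not among {self.taxa}"
            )
        self.matrix = np.array(
            [np.frombuffer(r.encode(), dtype=np.uint8) for r in self.rows]
        )
        # column -> ungapped coordinate (position of the base at that column;
        # for gap columns, the number of bases before the column)
        self.column_maps = []
        for r in range(len(self.rows)):
            nongap = self.matrix[r] != ord(GAP)
            cum = np.cumsum(nongap) - 1
            self.column_maps.append(np.where(nongap, cum, np.maximum(cum, 0)))
        self._nongap_mask = self.matrix != ord(GAP)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_index(self) -> int:
        return self.taxa.index(self.reference_taxon)

    def ungapped(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)].replace(GAP, "")

    def ref_position(self, column: int) -> int:
        """Ungapped reference coordinate of a column.

        For columns where the reference is gapped, this is the
        coordinate of the preceding reference base (0 at a leading gap).
        """
        return int(self.column_maps[self.reference_index][column])


def load_alignment(path, reference_taxon: str | None = None) -> AlignmentSet:
    """Ingest an aligned FASTA.  The first taxon is the default reference."""
    aln = AlignIO.read(path, "fasta")
    taxa = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    return AlignmentSet(taxa=taxa, rows=rows, reference_taxon=reference_taxon or taxa[0])


@dataclass(frozen=True)
class SNPSite:
    column: int
    ref_position: int
    alleles: tuple[str, ...]  # per taxon, in AlignmentSet order
    majority_allele: str
    classes: tuple[str, ...]  # one per variant allele
    is_transition: bool  # all classes at the site are transitions
    region: str = "?"


@dataclass(frozen=True)
class IndelEvent:
    column_start: int
    column_end: int  # exclusive
    ref_position: int
    length: int
    affected_sequence: str
    taxa_with_gap: tuple[str, ...]
    polarity: str  # insertion | deletion | unresolved
    classification: str  # SSR-indel | NR-indel
    ssr_motif: str | None = None
    region: str = "?"
    context: str = "?"

    @property
    def is_private(self) -> bool:
        return len(self.taxa_with_gap) == 1 or self.n_taxa - len(self.taxa_with_gap) == 1

    n_taxa: int = 0


@dataclass(frozen=True)
class InversionEvent:
    column_start: int
    column_end: int  # exclusive
    ref_start: int
    ref_end: int
    length: int
    flank_repeat_length: int
    inverted_taxa: tuple[str, ...]
    segment_reference: str
    segment_inverted: str
    stem_loop: bool = True
    region: str = "?"
    location: str = "?"


# ---------------------------------------------------------------------------
# SNPs


def _majority_allele(counts: dict[str, int], ref_allele: str) -> str:
    top = max(counts.values())
    tied = sorted(a for a, c in counts.items() if c == top)
    if ref_allele in tied:
        return ref_allele
    return tied[0]


def call_snps(
    aln: AlignmentSet,
    structure: QuadripartiteStructure | None = None,
    exclude_columns: set[int] | frozenset[int] = frozenset(),
) -> list[SNPSite]:
    """SNP sites: gap-free, N-free columns with >= 2 alleles.

    Per variant allele, a directed six-class label runs from the
    majority allele (ties broken toward the reference) to the minority
    allele.  ``exclude_columns`` removes columns already attributed to
    another event type (inversions).
    """
    M = aln.matrix
    gapfree = (M != ord(GAP)).all(axis=0) & (M != ord("N")).all(axis=0)
    variable = (M != M[0]).any(axis=0)
    cols = np.flatnonzero(gapfree & variable)
    if not gapfree.any():
        warnings.warn("alignment has no gap-free columns; no SNPs callable")
    ref_idx = aln.reference_index
    sites: list[SNPSite] = []
    for col in cols:
        col = int(col)
        if col in exclude_columns:
            continue
        alleles = tuple(chr(b) for b in M[:, col])
        counts: dict[str, int] = {}
        for a in alleles:
            counts[a] = counts.get(a, 0) + 1
        if len(counts) < 2:
            continue
        maj = _majority_allele(counts, alleles[ref_idx])
        classes = []
        for allele, cnt in sorted(counts.items()):
            if allele != maj:
                classes.extend([substitution_class(maj, allele)] * 1)
        ref_pos = aln.ref_position(col)
        region = structure.region_of(ref_pos) if structure else "?"
        sites.append(
            SNPSite(
                column=col,
                ref_position=ref_pos,
                alleles=alleles,
                majority_allele=maj,
                classes=tuple(classes),
                is_transition=all(c in TRANSITION_CLASSES for c in classes),
                region=region,
            )
        )
    return sites


def snp_summary(sites: list[SNPSite], aln: AlignmentSet) -> dict:
    """Class counts, Ts/Tv totals and ratio, per-region and pairwise counts."""
    per_class = {c: 0 for c in SUBSTITUTION_CLASSES}
    per_region: dict[str, int] = {}
    for s in sites:
        for c in s.classes:
            per_class[c] += 1
        per_region[s.region] = per_region.get(s.region, 0) + 1
    ts = sum(per_class[c] for c in SUBSTITUTION_CLASSES[:2])
    tv = sum(per_class[c] for c in SUBSTITUTION_CLASSES[2:])
    pairwise = {}
    cols = [s.column for s in sites]
    M = aln.matrix
    for i, j in itertools.combinations(range(aln.n_taxa), 2):
        if cols:
            diff = int((M[i, cols] != M[j, cols]).sum())
        else:
            diff = 0
        pairwise[f"{aln.taxa[i]}|{aln.taxa[j]}"] = diff
    return {
        "n_sites": len(sites),
        "n_substitutions": ts + tv,
        "per_class": per_class,
        "transitions": ts,
        "transversions": tv,
        "tv_ts_ratio": round(tv / ts, 2) if ts else float("nan"),
        "per_region": per_region,
        "pairwise": pairwise,
    }


# ---------------------------------------------------------------------------
# indels


def _tandem_copies_around(seq: str, unit: str, start: int, end: int) -> int:
    """Total copies of ``unit`` in the maximal tandem run covering [start, end)."""
    u = len(unit)
    left = start
    while left - u >= 0 and seq[left - u : left] == unit:
        left -= u
    right = end
    while right + u <= len(seq) and seq[right : right + u] == unit:
        right += u
    # the run must be in phase with the event interval
    if (end - start) % u != 0:
        return 0
    for k in range(left, right, u):
        if seq[k : k + u] != unit:
            return 0
    return (right - left) // u


def call_indels(
    aln: AlignmentSet,
    ssr_thresholds: dict[int, int] | None = None,
    max_ssr_unit: int = 2,
    structure: QuadripartiteStructure | None = None,
    record: PlastomeRecord | None = None,
) -> list[IndelEvent]:
    """Indel events: maximal column runs with an identical gap pattern.

    Polarity is called by majority state (minority bearing sequence =>
    insertion; minority bearing gaps => deletion; even split =>
    unresolved).  An event is an SSR-indel when its sequence is a whole
    number of copies of a unit of <= ``max_ssr_unit`` bp and the longer
    allele carries a perfect tandem run of that unit, covering the
    event, whose total copy number meets the SSR scan threshold.
    """
    thresholds = dict(ssr_thresholds or DEFAULT_THRESHOLDS)
    M = aln.matrix
    k, L = M.shape
    gaps = M == ord(GAP)
    any_gap = gaps.any(axis=0)
    events: list[IndelEvent] = []
    ungapped_cache: dict[int, str] = {}

    col = 0
    while col < L:
        if not any_gap[col]:
            col += 1
            continue
        pattern = gaps[:, col]
        if pattern.all():  # all-gap column: no taxon carries sequence here
            col += 1
            continue
        end = col + 1
        while end < L and any_gap[end] and (gaps[:, end] == pattern).all():
            end += 1
        gap_idx = np.flatnonzero(pattern)
        seq_idx = np.flatnonzero(~pattern)
        # affected sequence from the reference if it carries sequence here
        ref_idx = aln.reference_index
        donor = ref_idx if not pattern[ref_idx] else int(seq_idx[0])
        affected = aln.rows[donor][col:end]
        length = end - col
        n_gap, n_seq = len(gap_idx), len(seq_idx)
        if n_seq < n_gap:
            polarity = "insertion"
        elif n_gap < n_seq:
            polarity = "deletion"
        else:
            polarity = "unresolved"
        classification, motif = "NR-indel", None
        for u in range(1, max_ssr_unit + 1):
            if length % u:
                continue
            unit = affected[:u]
            if not _is_primitive(unit) or affected != unit * (length // u):
                continue
            if donor not in ungapped_cache:
                ungapped_cache[donor] = aln.rows[donor].replace(GAP, "")
            useq = ungapped_cache[donor]
            p = int(aln.column_maps[donor][col])
            copies = _tandem_copies_around(useq, unit, p, p + length)
            if copies >= thresholds[u]:
                classification, motif = "SSR-indel", unit
                break
        ref_pos = aln.ref_position(col)
        region = context = "?"
        if structure is not None:
            region = structure.region_of(ref_pos)
            if record is not None:
                region, context = classify_position(record, structure, ref_pos)
        events.append(
            IndelEvent(
                column_start=col,
                column_end=end,
                ref_position=ref_pos,
                length=length,
                affected_sequence=affected,
                taxa_with_gap=tuple(aln.taxa[i] for i in gap_idx),
                polarity=polarity,
                classification=classification,
                ssr_motif=motif,
                region=region,
                context=context,
                n_taxa=k,
            )
        )
        col = end
    return events


# ---------------------------------------------------------------------------
# inversions


def call_inversions(
    aln: AlignmentSet,
    min_len: int = 2,
    max_len: int = 6,
    min_flank: int = 3,
    max_flank: int = 20,
    structure: QuadripartiteStructure | None = None,
) -> tuple[list[InversionEvent], set[int]]:
    """Small inversions with inverted-repeat flanks.

    Returns the events plus the set of alignment columns they absorb
    (those columns must be removed from the SNP list).  A candidate is a
    window of ``min_len``..``max_len`` gap-free columns covering a
    cluster of mismatching columns, such that the taxa split into
    exactly two groups whose segments are reverse complements, and the
    immediate flanks — identical across all taxa — contain an inverted
    repeat of >= ``min_flank`` bp ending exactly at the window
    boundaries.  The smaller taxon group is reported as inverted; a tie
    goes to the group not containing the reference.  The stem test is an
    exact reverse-complement comparison, which is what lets the region
    fold into a hairpin.
    """
    M = aln.matrix
    k, L = M.shape
    gapfree = (M != ord(GAP)).all(axis=0) & (M != ord("N")).all(axis=0)
    variable = (M != M[0]).any(axis=0)
    var_cols = np.flatnonzero(gapfree & variable)
    events: list[InversionEvent] = []
    absorbed: set[int] = set()
    ref_idx = aln.reference_index

    def flank_repeat(start: int, end: int) -> int:
        """Longest f in [min_flank, max_flank] with an inverted repeat
        abutting the window; 0 if none."""
        for f in range(max_flank, min_flank - 1, -1):
            if start - f < 0 or end + f > L:
                continue
            cols = list(range(start - f, start)) + list(range(end, end + f))
            sub = M[:, cols]
            if (sub == ord(GAP)).any() or (sub != sub[0]).any():
                continue
            left = aln.rows[0][start - f : start]
            right = aln.rows[0][end : end + f]
            if left == revcomp(right):
                return f
        return 0

    used = np.zeros(L, dtype=bool)
    i = 0
    n_var = len(var_cols)
    while i < n_var:
        first = int(var_cols[i])
        j = i
        while j + 1 < n_var and int(var_cols[j + 1]) <= first + max_len - 1:
            j += 1
        last = int(var_cols[j])
        span = last - first + 1
        found = None
        for width in range(max(span, min_len), max_len + 1):
            for start in range(max(0, last - width + 1), first + 1):
                end = start + width
                if end > L or not gapfree[start:end].all() or used[start:end].any():
                    continue
                groups: dict[str, list[int]] = {}
                for r in range(k):
                    groups.setdefault(aln.rows[r][start:end], []).append(r)
                if len(groups) != 2:
                    continue
                (seg_a, rows_a), (seg_b, rows_b) = groups.items()
                if seg_b != revcomp(seg_a) or seg_a == seg_b:
                    continue
                f = flank_repeat(start, end)
                if not f:
                    continue
                if len(rows_a) < len(rows_b):
                    inv_rows, inv_seg, base_seg = rows_a, seg_a, seg_b
                elif len(rows_b) < len(rows_a):
                    inv_rows, inv_seg, base_seg = rows_b, seg_b, seg_a
                elif ref_idx in rows_a:
                    inv_rows, inv_seg, base_seg = rows_b, seg_b, seg_a
                else:
                    inv_rows, inv_seg, base_seg = rows_a, seg_a, seg_b
                found = (start, end, f, inv_rows, inv_seg, base_seg)
                break
            if found:
                break
        if found:
            start, end, f, inv_rows, inv_seg, base_seg = found
            ref_start = aln.ref_position(start)
            region = structure.region_of(ref_start) if structure else "?"
            events.append(
                InversionEvent(
                    column_start=start,
                    column_end=end,
                    ref_start=ref_start,
                    ref_end=ref_start + (end - start),
                    length=end - start,
                    flank_repeat_length=f,
                    inverted_taxa=tuple(aln.taxa[r] for r in sorted(inv_rows)),
                    segment_reference=base_seg,
                    segment_inverted=inv_seg,
                    region=region,
                )
            )
            used[start:end] = True
            absorbed.update(range(start, end))
        i = j + 1
    return events, absorbed


# ---------------------------------------------------------------------------
# orchestration


def call_variants(
    aln: AlignmentSet,
    structure: QuadripartiteStructure | None = None,
    record: PlastomeRecord | None = None,
    ssr_thresholds: dict[int, int] | None = None,
    min_inv: int = 2,
    max_inv: int = 6,
    min_flank: int = 3,
    max_flank: int = 20,
) -> tuple[list[SNPSite], list[IndelEvent], list[InversionEvent]]:
    """Partition variable columns into SNPs, indels and inversions.

    Inversions are called first; columns they absorb are excluded from
    SNP calling, so each variable column belongs to exactly one event.
    """
    inversions, absorbed = call_inversions(
        aln, min_inv, max_inv, min_flank, max_flank, structure=structure
    )
    snps = call_snps(aln, structure=structure, exclude_columns=absorbed)
    indels = call_indels(
        aln, ssr_thresholds=ssr_thresholds, structure=structure, record=record
    )
    return snps, indels, inversions


def snp_table(sites: list[SNPSite], aln: AlignmentSet) -> pd.DataFrame:
    rows = [
        {
            "column": s.column,
            "ref_position_1based": s.ref_position + 1,
            "alleles": "".join(s.alleles),
            "majority": s.majority_allele,
            "classes": ";".join(s.classes),
            "is_transition": s.is_transition,
            "region": s.region,
        }
        for s in sites
    ]
    cols = ["column", "ref_position_1based", "alleles", "majority", "classes", "is_transition", "region"]
    return pd.DataFrame(rows, columns=cols)


def indel_table(events: list[IndelEvent]) -> pd.DataFrame:
    rows = [
        {
            "ref_start_1based": e.ref_position + 1,
            "length": e.length,
            "polarity": e.polarity,
            "classification": e.classification,
            "ssr_motif": e.ssr_motif or "",
            "taxa_with_gap": ",".join(e.taxa_with_gap),
            "region": e.region,
            "context": e.context,
        }
        for e in events
    ]
    cols = ["ref_start_1based", "length", "polarity", "classification", "ssr_motif", "taxa_with_gap", "region", "context"]
    return pd.DataFrame(rows, columns=cols)


def inversion_table(events: list[InversionEvent], taxa: list[str]) -> pd.DataFrame:
    rows = []
    for e in events:
        row = {
            "location": e.location,
            "ref_start_1based": e.ref_start + 1,
            "inversion_length": e.length,
            "inverted_repeat_length": e.flank_repeat_length,
            "region": e.region,
        }
        for t in taxa:
            row[t] = "yes" if t in e.inverted_taxa else "no"
        rows.append(row)
    cols = ["location", "ref_start_1based", "inversion_length", "inverted_repeat_length", "region"] + list(taxa)
    return pd.DataFrame(rows, columns=cols)
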