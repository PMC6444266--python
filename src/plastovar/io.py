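"""Plastome records, quadripartite structure and coordinate services.

A land-plant chloroplast genome (plastome) is a circular molecule of
roughly 120-160 kb organised into four regions: a large single-copy
region (LSC) and a small single-copy region (SSC) separated by two
identical inverted repeats (IRb and IRa).  This module reads plastome
records from GenBank flat files or FASTA, locates the quadripartite
structure from the sequence alone (longest pair of exact
reverse-complement repeats), and labels arbitrary genome positions by
region (LSC/SSC/IR) and annotation context (exon/intron/spacer).

Coordinates are 0-based half-open internally; every human-facing report
uses 1-based inclusive coordinates, following GenBank convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FeatureAnnotation",
    "PlastomeRecord",
    "CircularInterval",
    "QuadripartiteStructure",
    "PlastomeParseError",
    "NoInvertedRepeatError",
    "revcomp",
    "complement",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "find_quadripartite",
    "classify_position",
    "gc_content",
    "gc_percent",
    "derive_spacers",
    "region_report",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGTN")

#: feature kinds treated as coding context when classifying positions
EXONIC_KINDS = frozenset({"gene-exon", "tRNA", "rRNA"})
FEATURE_KINDS = frozenset({"gene-exon", "intron", "tRNA", "rRNA", "spacer"})


class PlastomeParseError(ValueError):
    """Raised for malformed or unusable input records."""


class NoInvertedRepeatError(ValueError):
    """Raised when no inverted-repeat pair of the required length exists."""


def complement(seq: str) -> str:
    """Base-wise complement without reversal (A<->T, C<->G, N->N)."""
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated interval: an exon, intron, tRNA, rRNA or spacer.

    Intervals are 0-based half-open.  Spacer features are always derived
    from gene annotations (see :func:`derive_spacers`), never read from
    file.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: int = 1

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(
                f"feature {self.name!r}: start {self.start} must be < end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PlastomeRecord:
    """One plastome: identifier, sequence over {A,C,G,T,N}, features."""

    id: str
    sequence: str
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise PlastomeParseError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(only A, C, G, T, N are accepted)"
            )
        for f in self.features:
            if f.start < 0 or f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.name!r} [{f.start},{f.end}) outside genome "
                    f"[0,{len(self.sequence)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CircularInterval:
    """An interval on a circular genome, possibly wrapping the origin."""

    start: int
    length: int
    genome_length: int

    def contains(self, pos: int) -> bool:
        return (pos - self.start) % self.genome_length < self.length

    @property
    def end(self) -> int:
        """Exclusive end, reduced modulo the genome length."""
        return (self.start + self.length) % self.genome_length

    def pieces(self) -> list[tuple[int, int]]:
        """Linear [start, end) pieces; two pieces when wrapping the origin."""
        n = self.genome_length
        if self.start + self.length <= n:
            return [(self.start, self.start + self.length)]
        return [(self.start, n), (0, (self.start + self.length) - n)]

    def extract(self, sequence: str) -> str:
        return "".join(sequence[a:b] for a, b in self.pieces())


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC/IRb/SSC/IRa partition of a circular plastome.

    The four intervals tile the genome:
    ``lsc_length + ssc_length + 2 * ir_length == genome length``.
    """

    lsc: CircularInterval
    irb: CircularInterval
    ssc: CircularInterval
    ira: CircularInterval

    @property
    def ir_length(self) -> int:
        return self.irb.length

    @property
    def lsc_length(self) -> int:
        return self.lsc.length

    @property
    def ssc_length(self) -> int:
        return self.ssc.length

    def region_of(self, pos: int) -> str:
        """Region label at a position: 'LSC', 'SSC' or 'IR' (both copies)."""
        if self.lsc.contains(pos):
            return "LSC"
        if self.ssc.contains(pos):
            return "SSC"
        return "IR"


# ---------------------------------------------------------------------------
# readers / writers


def _features_from_seqrecord(rec) -> list[FeatureAnnotation]:
    kind_map = {"CDS": "gene-exon", "tRNA": "tRNA", "rRNA": "rRNA"}
    out: list[FeatureAnnotation] = []
    for feat in rec.features:
        kind = kind_map.get(feat.type)
        if kind is None:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or ["?"])[0]
        strand = -1 if feat.location.strand == -1 else 1
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        exons = [(int(p.start), int(p.end)) for p in parts]
        for a, b in exons:
            out.append(FeatureAnnotation(name, kind, a, b, strand))
        # introns are the inter-exon gaps of the same feature
        for (_, a_end), (b_start, _) in zip(exons, exons[1:]):
            if b_start > a_end:
                out.append(FeatureAnnotation(name, "intron", a_end, b_start, strand))
    out.sort(key=lambda f: (f.start, f.end))
    return out


def read_genbank(path) -> PlastomeRecord:
    """Read one plastome from a GenBank flat file or FASTA.

    FASTA input yields an empty feature list.  join()/complement()
    locations are decomposed into exon intervals; inter-exon gaps of the
    same gene become derived introns.
    """
    with open(path) as fh:
        head = fh.read(1024)
    stripped = head.lstrip()
    if not stripped:
        raise PlastomeParseError(f"{path}: empty file")
    fmt = "fasta" if stripped.startswith(">") else "genbank"
    try:
        rec = SeqIO.read(path, fmt)
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise PlastomeParseError(f"{path}: malformed {fmt} record: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq:
        raise PlastomeParseError(f"{path}: record {rec.id!r} has an empty sequence")
    features = _features_from_seqrecord(rec) if fmt == "genbank" else []
    return PlastomeRecord(id=rec.id, sequence=seq, features=features)


def read_fasta(path) -> PlastomeRecord:
    """Read a single-record FASTA (convenience wrapper)."""
    return read_genbank(path)


def write_fasta(record: PlastomeRecord, path, width: int = 70) -> None:
    """Write a record as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n")
        for i in range(0, record.length, width):
            fh.write(record.sequence[i : i + width] + "\n")


def write_fasta_many(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for record in records:
            fh.write(f">{record.id}\n")
            for i in range(0, record.length, width):
                fh.write(record.sequence[i : i + width] + "\n")


def read_fasta_many(path) -> list[PlastomeRecord]:
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        out.append(PlastomeRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not out:
        raise PlastomeParseError(f"{path}: no FASTA records found")
    return out


# ---------------------------------------------------------------------------
# quadripartite detection

_HASH_MOD = (1 << 61) - 1
_HASH_BASE = 131


def _prefix_hashes(s: str) -> list[int]:
    h = [0] * (len(s) + 1)
    acc = 0
    for i, c in enumerate(s):
        acc = (acc * _HASH_BASE + ord(c)) % _HASH_MOD
        h[i + 1] = acc
    return h


def _window_hash(pref: list[int], powers: list[int], i: int, length: int) -> int:
    return (pref[i + length] - pref[i] * powers[length]) % _HASH_MOD


def _circularly_disjoint(i: int, j: int, length: int, n: int) -> bool:
    return (j - i) % n >= length and (i - j) % n >= length


def find_quadripartite(record: PlastomeRecord, min_ir: int = 10_000) -> QuadripartiteStructure:
    """Locate LSC/IRb/SSC/IRa from the sequence alone.

    The structure is induced by the longest pair of exact
    reverse-complement repeats of length >= ``min_ir`` whose two copies
    do not overlap on the circle.  The longer inter-repeat arc is the
    LSC; IRb is the repeat copy immediately preceding the SSC in genome
    order.  The genome is treated as circular, so repeats spanning the
    linearisation origin are found.

    Raises :class:`NoInvertedRepeatError` when no qualifying repeat pair
    exists (the genome is reported as non-quadripartite).
    """
    seq = record.sequence
    n = len(seq)
    if min_ir < 1:
        raise ValueError("min_ir must be positive")
    if n < 2 * min_ir + 2:
        raise NoInvertedRepeatError(
            f"{record.id}: genome of {n} bp cannot hold two non-overlapping "
            f"inverted repeats of {min_ir} bp"
        )
    doubled = seq + seq
    rc_doubled = revcomp(seq) + revcomp(seq)  # revcomp of each circular window lives here
    pref_d = _prefix_hashes(doubled)
    pref_r = _prefix_hashes(rc_doubled)
    max_len = n // 2
    powers = [1] * (max_len + 1)
    for k in range(1, max_len + 1):
        powers[k] = (powers[k - 1] * _HASH_BASE) % _HASH_MOD

    def pairs_at(length: int, first_only: bool) -> list[tuple[int, int]]:
        # revcomp(window starting at j) == rc_doubled[2n - j - length : 2n - j]
        buckets: dict[int, list[int]] = {}
        for i in range(n):
            buckets.setdefault(_window_hash(pref_d, powers, i, length), []).append(i)
        found: list[tuple[int, int]] = []
        for j in range(n):
            q = 2 * n - j - length
            cands = buckets.get(_window_hash(pref_r, powers, q, length))
            if not cands:
                continue
            target = rc_doubled[q : q + length]
            for i in cands[:64]:
                if not _circularly_disjoint(i, j, length, n):
                    continue
                if doubled[i : i + length] == target:
                    found.append((i, j) if i < j else (j, i))
                    if first_only:
                        return found
        return found

    if not pairs_at(min_ir, first_only=True):
        raise NoInvertedRepeatError(
            f"{record.id}: no inverted repeat found at length >= {min_ir} bp"
        )
    lo, hi = min_ir, max_len  # lo always feasible
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if pairs_at(mid, first_only=True):
            lo = mid
        else:
            hi = mid - 1
    best = lo
    s1, s2 = min(set(pairs_at(best, first_only=False)))

    arc_a = (s2 - (s1 + best)) % n  # arc from end of copy1 to start of copy2
    arc_b = (s1 - (s2 + best)) % n  # arc from end of copy2 back to copy1
    if arc_a == 0 or arc_b == 0:
        raise NoInvertedRepeatError(
            f"{record.id}: inverted-repeat copies are adjacent; genome is not quadripartite"
        )
    ci = lambda start, length: CircularInterval(start % n, length, n)
    if arc_a >= arc_b:
        # copy1 -> LSC -> copy2 -> SSC; LSC precedes copy2, so copy2 is IRb
        lsc, irb = ci(s1 + best, arc_a), ci(s2, best)
        ssc, ira = ci(s2 + best, arc_b), ci(s1, best)
    else:
        lsc, irb = ci(s2 + best, arc_b), ci(s1, best)
        ssc, ira = ci(s1 + best, arc_a), ci(s2, best)
    return QuadripartiteStructure(lsc=lsc, irb=irb, ssc=ssc, ira=ira)


# ---------------------------------------------------------------------------
# labeling services


def classify_position(
    record: PlastomeRecord, structure: QuadripartiteStructure, position: int
) -> tuple[str, str]:
    """Label a genome position by (region, context).

    Region is LSC, SSC or IR (both IR copies pooled).  Context is
    ``exon`` inside any exon/tRNA/rRNA interval, ``intron`` inside a
    derived intron, otherwise ``spacer``.  Interval features (an SSR, an
    indel) are labeled by their start position.
    """
    if not 0 <= position < record.length:
        raise ValueError(f"position {position} outside genome [0,{record.length})")
    region = structure.region_of(position)
    context = "spacer"
    for f in record.features:
        if f.start <= position < f.end:
            if f.kind in EXONIC_KINDS:
                return region, "exon"
            if f.kind == "intron":
                context = "intron"
    return region, context


def gc_content(record: PlastomeRecord) -> float:
    """G+C fraction over non-N bases."""
    seq = record.sequence
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError(f"record {record.id!r}: no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / denom


def gc_percent(record: PlastomeRecord) -> float:
    """GC content as a percentage rounded to one decimal (report form)."""
    return round(100.0 * gc_content(record), 1)


def gene_spans(record: PlastomeRecord) -> list[tuple[str, int, int]]:
    """(name, start, end) span of each annotated gene, in genome order.

    A gene's span is the hull of all its exon/intron/tRNA/rRNA pieces;
    contiguous pieces sharing a name are pooled.
    """
    by_name: dict[tuple[str, int], list[FeatureAnnotation]] = {}
    # a gene duplicated in the two IR copies appears as two distant
    # clusters sharing a name; split clusters separated by > 5 kb
    pieces = sorted(
        (f for f in record.features if f.kind != "spacer"), key=lambda f: f.start
    )
    clusters: list[tuple[str, int, int]] = []
    for f in pieces:
        if clusters and clusters[-1][0] == f.name and f.start - clusters[-1][2] <= 5000:
            name, a, b = clusters[-1]
            clusters[-1] = (name, a, max(b, f.end))
        else:
            clusters.append((f.name, f.start, f.end))
    clusters.sort(key=lambda t: t[1])
    return clusters


def derive_spacers(record: PlastomeRecord) -> list[FeatureAnnotation]:
    """Intergenic spacers between consecutive gene spans, named geneA-geneB."""
    spans = gene_spans(record)
    out = []
    for (name_a, _, end_a), (name_b, start_b, _) in zip(spans, spans[1:]):
        if start_b > end_a:
            out.append(
                FeatureAnnotation(f"{name_a}-{name_b}", "spacer", end_a, start_b, 1)
            )
    return out


def region_report(structure: QuadripartiteStructure) -> pd.DataFrame:
    """Region table with 1-based inclusive coordinates."""
    rows = []
    for label, interval in (
        ("LSC", structure.lsc),
        ("IRb", structure.irb),
        ("SSC", structure.ssc),
        ("IRa", structure.ira),
    ):
        for a, b in interval.pieces():
            rows.append({"region": label, "start_1based": a + 1, "end_1based": b, "length": b - a})
    return pd.DataFrame(rows, columns=["region", "start_1based", "end_1based", "length"])
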