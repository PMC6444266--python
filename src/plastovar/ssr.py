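"""Microsatellite (SSR) detection and stratified summaries.

Finds maximal perfect tandem repeats of 1-6 bp units on the forward
strand, using the MISA-style minimum copy-number thresholds that are
standard for chloroplast surveys: 10 copies for mononucleotides, 5 for
dinucleotides, 4 for trinucleotides and 3 for tetra-, penta- and
hexanucleotides.  Each genomic interval is reported once and attributed
to the smallest unit length whose perfect repetition spans it (a run of
12 A's is one mononucleotide SSR, never an AA x 6).  Reporting is
strand-symmetric: each motif is collapsed over rotations and strand
into a canonical class, so A and T runs both belong to the A/T family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PlastomeRecord, QuadripartiteStructure, classify_position, revcomp, complement

__all__ = ["SSRLocus", "DEFAULT_THRESHOLDS", "scan_ssrs", "summarize_ssrs", "canonical_class"]

#: minimum copies per unit length (unit length -> copies)
DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRLocus:
    """One detected microsatellite locus."""

    motif: str
    unit_length: int
    copy_number: int
    start: int
    end: int
    canonical_class: str
    region: str = "?"
    context: str = "?"

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repetition of a shorter unit."""
    u = len(motif)
    for p in range(1, u):
        if u % p == 0 and motif == motif[:p] * (u // p):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Strand- and rotation-collapsed motif family label, e.g. 'A/T', 'AT/TA'.

    The representative is the lexicographically smallest rotation over
    both strands; the label pairs it with its base-wise complement.
    """
    rots = {motif[i:] + motif[:i] for i in range(len(motif))}
    rc = revcomp(motif)
    rots |= {rc[i:] + rc[:i] for i in range(len(rc))}
    rep = min(rots)
    return f"{rep}/{complement(rep)}"


def _validate_thresholds(thresholds: dict[int, int]) -> dict[int, int]:
    for u in range(1, 7):
        if u not in thresholds:
            raise ValueError(f"SSR thresholds must cover unit lengths 1-6; missing {u}")
        if thresholds[u] < 1:
            raise ValueError(f"threshold for unit length {u} must be >= 1")
    return thresholds


def scan_ssrs(
    record: PlastomeRecord,
    thresholds: dict[int, int] | None = None,
    structure: QuadripartiteStructure | None = None,
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting the copy thresholds.

    Loci are sorted by start and never overlap: where candidate runs of
    different unit lengths collide, the earlier-starting (then
    smaller-unit) run wins.  Runs containing N are broken at the N;
    repeats spanning the circular origin are not reported.  When
    ``structure`` is given, region/context labels are attached via
    :func:`plastovar.io.classify_position` at each locus start.
    """
    thresholds = _validate_thresholds(dict(thresholds or DEFAULT_THRESHOLDS))
    seq = record.sequence
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_acgt = (arr != ord("N"))

    candidates: list[tuple[int, int, int, int, str]] = []  # start, unit, end, copies, motif
    for u in range(1, 7):
        if n < u * thresholds[u]:
            continue
        eq = (arr[:-u] == arr[u:]) & is_acgt[:-u] & is_acgt[u:]
        # maximal runs of consecutive True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive, in eq coordinates
        for a, b in zip(starts, ends):
            span = (b - a) + u  # length of the perfect tandem stretch
            copies = span // u
            if copies < thresholds[u]:
                continue
            motif = seq[a : a + u]
            if not _is_primitive(motif):
                continue
            candidates.append((int(a), u, int(a) + u * copies, copies, motif))

    candidates.sort(key=lambda c: (c[0], c[1]))
    loci: list[SSRLocus] = []
    last_end = -1
    for start, u, end, copies, motif in candidates:
        if start < last_end:
            # trim the run to its part beyond the previous locus (keeping
            # unit phase); drop it if the remainder falls below threshold
            k = -((start - last_end) // u)  # ceil((last_end - start) / u)
            start += k * u
            motif = seq[start : start + u]
            copies -= k
            if copies < thresholds[u] or start >= end:
                continue
        region = context = "?"
        if structure is not None:
            region, context = classify_position(record, structure, start)
        loci.append(
            SSRLocus(
                motif=motif,
                unit_length=u,
                copy_number=copies,
                start=start,
                end=end,
                canonical_class=canonical_class(motif),
                region=region,
                context=context,
            )
        )
        last_end = end
    return loci


_UNIT_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


def loci_table(loci_by_genome: dict[str, list[SSRLocus]]) -> pd.DataFrame:
    """Tidy per-locus table (1-based inclusive coordinates)."""
    rows = []
    for genome_id, loci in loci_by_genome.items():
        for l in loci:
            rows.append(
                {
                    "genome_id": genome_id,
                    "start_1based": l.start + 1,
                    "end_1based": l.end,
                    "motif": l.motif,
                    "canonical_class": l.canonical_class,
                    "unit_length": l.unit_length,
                    "copy_number": l.copy_number,
                    "region": l.region,
                    "context": l.context,
                }
            )
    cols = [
        "genome_id", "start_1based", "end_1based", "motif", "canonical_class",
        "unit_length", "copy_number", "region", "context",
    ]
    return pd.DataFrame(rows, columns=cols)


def summarize_ssrs(loci_by_genome: dict[str, list[SSRLocus]]) -> dict[str, pd.DataFrame]:
    """Per-genome and pooled SSR counts by unit length, class, region, context.

    Returns a dict of DataFrames: ``by_unit``, ``by_class``, ``by_region``,
    ``by_context`` (genomes as columns plus a ``pooled`` column) and
    ``proportions`` (pooled percentages to two decimals).
    """
    table = loci_table(loci_by_genome)
    genomes = list(loci_by_genome)

    def pivot(key: str, mapper=None) -> pd.DataFrame:
        if table.empty:
            return pd.DataFrame(0, index=pd.Index([], name=key), columns=genomes + ["pooled"])
        col = table[key].map(mapper) if mapper else table[key]
        counts = pd.crosstab(col, table["genome_id"]).reindex(columns=genomes, fill_value=0)
        counts["pooled"] = counts.sum(axis=1)
        counts.index.name = key
        return counts

    out = {
        "by_unit": pivot("unit_length", _UNIT_NAMES.get),
        "by_class": pivot("canonical_class"),
        "by_region": pivot("region"),
        "by_context": pivot("context"),
    }
    total = len(table)
    props = []
    for name, df in out.items():
        for label, row in df.iterrows():
            pct = round(100.0 * row["pooled"] / total, 2) if total else 0.0
            props.append({"table": name, "label": label, "count": int(row["pooled"]), "percent": pct})
    out["proportions"] = pd.DataFrame(props, columns=["table", "label", "count", "percent"])
    return out
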