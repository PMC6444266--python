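"""Sliding-window nucleotide diversity (π) and mutational hotspots.

π is the average proportion of pairwise differences between sequences,
computed per window over alignment columns that are gap-free and N-free
in all taxa (complete deletion within each window, matching the DnaSP
convention; no Jukes-Cantor correction).  Windows advance by a fixed
step over alignment columns; each window's midpoint is projected onto
ungapped reference coordinates.  Consecutive windows whose π exceeds a
threshold merge into a mutational hotspot, which is then annotated with
the reference genes and intergenic spacers it overlaps.

Defaults follow common chloroplast practice: 600 bp windows, 100 bp
step, hotspot threshold π > 0.01.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PlastomeRecord, QuadripartiteStructure, derive_spacers, gene_spans
from .variation import AlignmentSet, GAP

__all__ = [
    "DiversityProfile",
    "Hotspot",
    "UndefinedDiversityError",
    "nucleotide_diversity",
    "sliding_profile",
]


class UndefinedDiversityError(ValueError):
    """Raised when no usable (gap-free, N-free) sites exist."""


def nucleotide_diversity(rows: list[str]) -> tuple[float, int]:
    """π over a set of aligned segments, with the usable-site count.

    Only columns gap-free and N-free in all rows are used.  With k rows
    and L usable sites,
    ``pi = 2 / (k (k-1)) * sum over pairs of (differences / L)``.
    Raises :class:`UndefinedDiversityError` when L = 0 — an undefined π
    is signalled, never reported as zero.
    """
    k = len(rows)
    if k < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    M = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    usable = (M != ord(GAP)).all(axis=0) & (M != ord("N")).all(axis=0)
    L = int(usable.sum())
    if L == 0:
        raise UndefinedDiversityError("no usable sites (all columns have gaps or N)")
    sub = M[:, usable]
    total = 0
    for i in range(k):
        for j in range(i + 1, k):
            total += int((sub[i] != sub[j]).sum())
    pi = 2.0 / (k * (k - 1)) * (total / L)
    return pi, L


@dataclass(frozen=True)
class Hotspot:
    ref_start: int  # 0-based half-open, reference coordinates
    ref_end: int
    peak_pi: float
    window_indices: tuple[int, ...]
    features: tuple[str, ...]  # overlapping gene / spacer names


@dataclass
class DiversityProfile:
    window_length: int
    step: int
    windows: pd.DataFrame  # window_index, col_start, midpoint_ref, usable_sites, pi
    mean_pi: float
    hotspots: list[Hotspot] = field(default_factory=list)


def _pairdiff_per_column(aln: AlignmentSet) -> tuple[np.ndarray, np.ndarray]:
    """Per column: number of differing taxon pairs, and usability mask."""
    M = aln.matrix
    k, L = M.shape
    usable = (M != ord(GAP)).all(axis=0) & (M != ord("N")).all(axis=0)
    npairs_same = np.zeros(L, dtype=np.int64)
    for base in b"ACGT":
        cnt = (M == base).sum(axis=0)
        npairs_same += cnt * (cnt - 1) // 2
    total_pairs = k * (k - 1) // 2
    d = np.where(usable, total_pairs - npairs_same, 0)
    return d, usable


def sliding_profile(
    aln: AlignmentSet,
    window: int = 600,
    step: int = 100,
    threshold: float = 0.01,
    record: PlastomeRecord | None = None,
    structure: QuadripartiteStructure | None = None,
) -> DiversityProfile:
    """Windowed π over the alignment with hotspot calling.

    Windows are defined over alignment columns; the trailing partial
    window is dropped.  Windows with no usable site carry NaN π and are
    excluded from ``mean_pi``.  Consecutive windows with π above
    ``threshold`` merge into one hotspot; when ``record`` is given,
    hotspots are annotated with overlapping gene and spacer names.
    """
    L = aln.n_columns
    if window > L:
        warnings.warn(
            f"window ({window}) exceeds alignment length ({L}); "
            "using a single whole-alignment window"
        )
        window = L
    k = aln.n_taxa
    total_pairs = k * (k - 1) // 2
    d, usable = _pairdiff_per_column(aln)
    cum_d = np.concatenate(([0], np.cumsum(d)))
    cum_u = np.concatenate(([0], np.cumsum(usable.astype(np.int64))))
    n_windows = (L - window) // step + 1
    ref_map = aln.column_maps[aln.reference_index]
    rows = []
    for w in range(n_windows):
        a = w * step
        b = a + window
        sites = int(cum_u[b] - cum_u[a])
        if sites:
            pi = (cum_d[b] - cum_d[a]) / (total_pairs * sites)
        else:
            pi = math.nan
        mid_col = a + window // 2
        rows.append(
            {
                "window_index": w,
                "col_start": a,
                "col_end": b,
                "midpoint_ref_1based": int(ref_map[min(mid_col, L - 1)]) + 1,
                "usable_sites": sites,
                "pi": pi,
            }
        )
    windows = pd.DataFrame(
        rows, columns=["window_index", "col_start", "col_end", "midpoint_ref_1based", "usable_sites", "pi"]
    )
    defined = windows["pi"].dropna()
    mean_pi = float(defined.mean()) if len(defined) else math.nan

    # hotspot merging over consecutive above-threshold windows
    hotspots: list[Hotspot] = []
    annot: list[tuple[str, int, int]] = []
    if record is not None:
        annot = list(gene_spans(record)) + [
            (f.name, f.start, f.end) for f in derive_spacers(record)
        ]
    run: list[int] = []
    for _, row in windows.iterrows():
        hot = (not math.isnan(row["pi"])) and row["pi"] > threshold
        if hot:
            run.append(int(row["window_index"]))
        if run and (not hot or row["window_index"] == n_windows - 1):
            first, last = run[0], run[-1]
            col_a = int(windows.loc[first, "col_start"])
            col_b = int(windows.loc[last, "col_end"])
            ref_a = int(ref_map[col_a])
            ref_b = int(ref_map[min(col_b - 1, L - 1)]) + 1
            peak = float(windows.loc[first : last, "pi"].max())
            feats = tuple(
                name for name, fa, fb in annot if fa < ref_b and ref_a < fb
            )
            hotspots.append(
                Hotspot(
                    ref_start=ref_a,
                    ref_end=ref_b,
                    peak_pi=peak,
                    window_indices=tuple(run),
                    features=feats,
                )
            )
            run = []
    return DiversityProfile(
        window_length=window, step=step, windows=windows, mean_pi=mean_pi, hotspots=hotspots
    )


def hotspots_bed(profile: DiversityProfile) -> pd.DataFrame:
    """Hotspot intervals as BED-style rows (0-based half-open)."""
    rows = [
        {
            "chrom": "reference",
            "start": h.ref_start,
            "end": h.ref_end,
            "name": ";".join(h.features) or "hotspot",
            "peak_pi": round(h.peak_pi, 5),
        }
        for h in profile.hotspots
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "peak_pi"])
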