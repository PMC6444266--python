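"""End-to-end pipeline orchestration and summary reporting.

Runs partition -> SSR scan -> variant calling -> diversity profiling
over a set of plastomes (plus, optionally, a pre-computed multiple
alignment), writes every per-module table (TSV/BED) and a single
summary JSON whose headline numbers are all traceable to a module
output row.  Threshold provenance is recorded in the summary header so
that alignment- and threshold-sensitive counts can be interpreted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from .diversity import hotspots_bed, sliding_profile
from .ssr import DEFAULT_THRESHOLDS, loci_table, scan_ssrs, summarize_ssrs
from .variation import (
    call_variants,
    indel_table,
    inversion_table,
    load_alignment,
    snp_summary,
    snp_table,
)

log = logging.getLogger("plastovar")

__all__ = ["RunConfig", "run_pipeline", "describe_position"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow standard plastome practice."""

    genome_paths: list[str] = field(default_factory=list)
    alignment_path: str | None = None
    reference: str | None = None
    out_dir: str = "plastovar_out"
    min_ir: int = 10_000
    ssr_thresholds: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    window: int = 600
    step: int = 100
    pi_threshold: float = 0.01
    min_inv: int = 2
    max_inv: int = 6
    min_flank: int = 3
    max_flank: int = 20
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Flat key=value config file; CLI overrides take precedence."""
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key == "genome_paths":
                values[key] = [v for v in val.split(",") if v]
            elif key == "ssr_thresholds":
                values[key] = {
                    int(k): int(v) for k, v in (pair.split(":") for pair in val.split(","))
                }
            elif key in ("min_ir", "window", "step", "min_inv", "max_inv", "min_flank", "max_flank"):
                values[key] = int(val)
            elif key == "pi_threshold":
                values[key] = float(val)
            else:
                values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def describe_position(record: pio.PlastomeRecord, pos: int) -> str:
    """Human-facing location name: gene, 'gene intron' or 'geneA-geneB'."""
    for f in record.features:
        if f.start <= pos < f.end:
            return f"{f.name} intron" if f.kind == "intron" else f.name
    for sp in pio.derive_spacers(record):
        if sp.start <= pos < sp.end:
            return sp.name
    return "intergenic"


def _write(df, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig, genomes=None, alignment=None) -> dict:
    """Execute the full pipeline and write the report bundle.

    ``genomes`` (dict id -> PlastomeRecord) and ``alignment`` (an
    AlignmentSet) may be passed directly — the simulator produces them
    in memory — otherwise they are read from the configured paths.
    Returns the summary dict (also written as ``summary.json``).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if genomes is None:
        genomes = {}
        for path in config.genome_paths:
            rec = pio.read_genbank(path)
            genomes[rec.id] = rec
    if not genomes:
        raise ValueError("no input genomes")

    summary: dict = {
        "parameters": {
            "min_ir": config.min_ir,
            "ssr_thresholds": {str(k): v for k, v in config.ssr_thresholds.items()},
            "window": config.window,
            "step": config.step,
            "pi_threshold": config.pi_threshold,
            "inversion_length": [config.min_inv, config.max_inv],
            "inversion_flank": [config.min_flank, config.max_flank],
            "note": "alignment is an external input; variant counts depend on the aligner",
        },
        "genomes": {},
    }

    structures = {}
    loci_by_genome = {}
    for gid, rec in genomes.items():
        log.info("partitioning %s (%d bp)", gid, rec.length)
        try:
            structure = pio.find_quadripartite(rec, min_ir=config.min_ir)
            structures[gid] = structure
            _write(pio.region_report(structure), out / f"regions_{gid}.tsv")
            region_info = {
                "lsc_length": structure.lsc_length,
                "ir_length": structure.ir_length,
                "ssc_length": structure.ssc_length,
            }
        except pio.NoInvertedRepeatError as exc:
            log.warning("%s: %s", gid, exc)
            region_info = {"error": str(exc)}
        loci = scan_ssrs(rec, config.ssr_thresholds, structure=structures.get(gid))
        loci_by_genome[gid] = loci
        summary["genomes"][gid] = {
            "length": rec.length,
            "gc_percent": pio.gc_percent(rec),
            "n_ssrs": len(loci),
            **region_info,
        }

    _write(loci_table(loci_by_genome), out / "ssr_loci.tsv")
    ssr_tables = summarize_ssrs(loci_by_genome)
    _write(ssr_tables["proportions"], out / "ssr_summary.tsv")
    summary["ssr"] = {
        "per_genome": {g: len(l) for g, l in loci_by_genome.items()},
        "pooled_total": sum(len(l) for l in loci_by_genome.values()),
        "proportions": ssr_tables["proportions"].to_dict(orient="records"),
    }

    if alignment is None and config.alignment_path:
        alignment = load_alignment(config.alignment_path, config.reference)
    if alignment is None:
        summary["variants"] = None
        summary["diversity"] = None
    else:
        ref_id = alignment.reference_taxon
        ref_record = genomes.get(ref_id)
        structure = structures.get(ref_id)
        log.info("calling variants against reference %s", ref_id)
        snps, indels, inversions = call_variants(
            alignment,
            structure=structure,
            record=ref_record,
            ssr_thresholds=config.ssr_thresholds,
            min_inv=config.min_inv,
            max_inv=config.max_inv,
            min_flank=config.min_flank,
            max_flank=config.max_flank,
        )
        _write(snp_table(snps, alignment), out / "snps.tsv")
        _write(indel_table(indels), out / "indels.tsv")
        inv_df = inversion_table(inversions, list(alignment.taxa))
        if ref_record is not None:
            inv_df["location"] = [
                describe_position(ref_record, e.ref_start) for e in inversions
            ]
        _write(inv_df, out / "inversions.tsv")

        ssn = snp_summary(snps, alignment)
        n_ssr_indels = sum(e.classification == "SSR-indel" for e in indels)
        largest_nr = max(
            (e.length for e in indels if e.classification == "NR-indel"), default=0
        )
        summary["variants"] = {
            "reference": ref_id,
            "snp": ssn,
            "indel": {
                "total": len(indels),
                "ssr_indels": n_ssr_indels,
                "nr_indels": len(indels) - n_ssr_indels,
                "largest_nr_indel_bp": largest_nr,
                "private": sum(e.is_private for e in indels),
            },
            "inversions": {
                "total": len(inversions),
                "lengths": [e.length for e in inversions],
                "flank_lengths": [e.flank_repeat_length for e in inversions],
            },
        }

        profile = sliding_profile(
            alignment,
            window=config.window,
            step=config.step,
            threshold=config.pi_threshold,
            record=ref_record,
            structure=structure,
        )
        _write(
            profile.windows[["window_index", "midpoint_ref_1based", "usable_sites", "pi"]],
            out / "diversity.tsv",
        )
        _write(hotspots_bed(profile), out / "hotspots.bed")
        summary["diversity"] = {
            "window": profile.window_length,
            "step": profile.step,
            "n_windows": len(profile.windows),
            "mean_pi": round(profile.mean_pi, 5),
            "max_pi": round(float(profile.windows["pi"].max()), 5),
            "hotspots": [
                {
                    "start_1based": h.ref_start + 1,
                    "end_1based": h.ref_end,
                    "peak_pi": round(h.peak_pi, 5),
                    "features": list(h.features),
                }
                for h in profile.hotspots
            ],
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
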