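"""Synthetic plastome quartets with a machine-readable truth ledger.

The generator builds an ancestral plastome with a planted quadripartite
structure (LSC + IRb + SSC + IRa, IRa being the exact reverse
complement of IRb), gene/intron annotations, and microsatellite loci,
then derives four taxa by applying a per-taxon event plan: substitutions
drawn from the six strand-collapsed classes, microsatellite slippage
events (copy-number changes of planted SSRs), non-repeat indels, and
small inversions wrapped in freshly planted inverted-repeat flanks.

Because every event is placed at least ``min_event_gap`` bases from
every other event and from planted repeats, the true multiple alignment
is unambiguous and is emitted by construction — no aligner is involved.
A :class:`TruthLedger` records every event together with the alignment
columns it occupies, so each pipeline stage can be scored for exact
recovery.

Background sequence is scrubbed of accidental microsatellites (any run
meeting the scan thresholds that was not deliberately planted is broken
by a single-base edit, mirrored into the opposite IR copy when needed),
and substitution/indel sites are rejected when applying them would
create a new threshold-passing repeat.  Passing recovery tests on this
material therefore demonstrates correctness of the callers on isolated,
unambiguous events; it does not exercise aligner artefacts, nested
events, or repeat-mediated ambiguity found in real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import (
    CircularInterval,
    FeatureAnnotation,
    PlastomeRecord,
    QuadripartiteStructure,
    complement,
    revcomp,
)
from .ssr import DEFAULT_THRESHOLDS, scan_ssrs
from .variation import SUBSTITUTION_CLASSES, _tandem_copies_around

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "QuartetResult",
    "SSRPlan",
    "SNPPlan",
    "MultiSNPPlan",
    "SSRIndelPlan",
    "NRIndelPlan",
    "InversionPlan",
    "HotspotPlan",
    "generate_ancestor",
    "evolve_quartet",
    "simulate_quartet",
    "default_config",
    "sorghum_like_config",
    "replay_taxon",
]

_BASES = "ACGT"

# ancestral bases admissible for each substitution class, mapped to the
# derived base they imply
_CLASS_ANC: dict[str, dict[str, str]] = {}
for _label in SUBSTITUTION_CLASSES:
    _m = {}
    for _part in _label.split("/"):
        _a, _b = _part.split("→")
        _m[_a] = _b
    _CLASS_ANC[_label] = _m


@dataclass(frozen=True)
class SSRPlan:
    motif: str
    copies: int
    region: str  # LSC | SSC | IR


@dataclass(frozen=True)
class SNPPlan:
    taxon: str
    sub_class: str
    where: str = "LSC"  # LSC | SSC | IR | hot:<i>


@dataclass(frozen=True)
class MultiSNPPlan:
    """One site carrying two derived alleles on two taxa (triallelic)."""

    taxon1: str
    class1: str
    taxon2: str
    class2: str
    where: str = "LSC"


@dataclass(frozen=True)
class SSRIndelPlan:
    taxon: str
    delta: int  # signed unit-copy change
    target_motif: str | None = None  # restrict to loci of this motif
    target_copies: int | None = None  # restrict to loci of this copy number


@dataclass(frozen=True)
class NRIndelPlan:
    taxa: tuple[str, ...]
    length: int
    polarity: str  # "ins" | "del"
    region: str | None = None  # LSC | SSC | None (drawn ~ region size)


@dataclass(frozen=True)
class InversionPlan:
    taxon: str
    length: int  # 2..6
    flank: int  # 3..20
    region: str = "LSC"


@dataclass(frozen=True)
class HotspotPlan:
    gene_a: str
    gene_b: str
    region: str = "LSC"
    # a 500 bp spacer fits inside one 600 bp window at any 100 bp grid
    # offset, so a planted substitution cluster always registers whole
    width: int = 500


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 20_000
    lsc_frac: float = 0.5874
    ir_frac: float = 0.1619
    gc: float = 0.385
    n_genes: int = 15
    gene_names: list[str] | None = None
    taxa: tuple[str, ...] = ("taxonA", "taxonB", "taxonC", "taxonD")
    ssr_plan: list[SSRPlan] = field(default_factory=list)
    snp_plan: list[SNPPlan] = field(default_factory=list)
    multi_snp_plan: list[MultiSNPPlan] = field(default_factory=list)
    ssr_indel_plan: list[SSRIndelPlan] = field(default_factory=list)
    nr_indel_plan: list[NRIndelPlan] = field(default_factory=list)
    inversion_plan: list[InversionPlan] = field(default_factory=list)
    hotspot_plan: list[HotspotPlan] = field(default_factory=list)
    min_event_gap: int = 10
    # background (non-hotspot) substitutions keep this spacing, so that a
    # 600 bp window of background never crosses the 0.01 hotspot
    # threshold by chance: planted hotspots stay the only hotspots
    background_snp_spacing: int = 60
    thresholds: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    @property
    def reference(self) -> str:
        return self.taxa[0]

    def region_lengths(self) -> tuple[int, int, int]:
        n = self.genome_length
        ir = round(self.ir_frac * n)
        lsc = round(self.lsc_frac * n)
        ssc = n - lsc - 2 * ir
        if ssc <= 0 or lsc <= ssc:
            raise ValueError(
                f"region fractions invalid: lsc={lsc}, ir={ir}, ssc={ssc} "
                "(need ssc > 0 and lsc > ssc)"
            )
        return lsc, ir, ssc


# ---------------------------------------------------------------------------
# placement bookkeeping


class _Placer:
    """Tracks reserved intervals; finds free positions with a minimum gap."""

    def __init__(self, gap: int):
        self.gap = gap
        self.reserved: list[tuple[int, int]] = []

    def is_free(self, start: int, end: int) -> bool:
        g = self.gap
        return all(end + g <= a or b + g <= start for a, b in self.reserved)

    def reserve(self, start: int, end: int) -> None:
        self.reserved.append((start, end))

    def unreserve(self, start: int, end: int) -> None:
        self.reserved.remove((start, end))

    def find(self, rng, lo: int, hi: int, length: int, accept=None, tries: int = 3000) -> int:
        """A free start position in [lo, hi - length]; raises on overflow."""
        if hi - lo < length:
            raise ValueError("plan overflows region capacity")
        for _ in range(tries):
            s = int(rng.integers(lo, hi - length + 1))
            if self.is_free(s, s + length) and (accept is None or accept(s)):
                self.reserve(s, s + length)
                return s
        raise ValueError(
            f"could not place an event of length {length} in [{lo},{hi}) "
            f"after {tries} tries (plan overflows region capacity)"
        )


def _has_threshold_ssr(seq: str, thresholds: dict[int, int]) -> bool:
    return bool(scan_ssrs(PlastomeRecord(id="_probe", sequence=seq), thresholds))


# ---------------------------------------------------------------------------
# ancestor


@dataclass
class AncestorBundle:
    record: PlastomeRecord
    structure: QuadripartiteStructure
    ssr_loci: list[dict]  # planted loci incl. IR mirrors and sub-threshold runs
    hotspot_intervals: list[tuple[int, int]]
    placer: _Placer
    config: SimulationConfig


def _mirror_ir_position(pos: int, irb: tuple[int, int], ira: tuple[int, int]) -> int:
    """IRa position carrying the complement of an IRb position."""
    return ira[0] + (irb[1] - 1 - pos)


def generate_ancestor(config: SimulationConfig) -> AncestorBundle:
    """Build the ancestral plastome: structure, genes, planted SSRs.

    The sequence is random at the target GC; IRa is the exact reverse
    complement of IRb.  Gene features (some with introns, IR genes
    mirrored between the copies) are laid out in all regions, and SSR
    loci from the plan are inserted with non-repeat flanking bases.
    Accidental repeat runs in the background are broken by single-base
    edits so that the scan finds exactly the planted loci.
    """
    rng = np.random.default_rng(config.seed)
    lsc, ir, ssc = config.region_lengths()
    n = config.genome_length
    irb_iv = (lsc, lsc + ir)
    ssc_iv = (lsc + ir, lsc + ir + ssc)
    ira_iv = (lsc + ir + ssc, n)
    region_iv = {"LSC": (0, lsc), "IR": irb_iv, "SSC": ssc_iv}

    # compensate the background GC for the planted repeat loci (mostly
    # A/T-rich), so the assembled genome hits the configured GC target
    planted_len = planted_gc = 0
    for sp in config.ssr_plan:
        copies_len = len(sp.motif) * sp.copies * (2 if sp.region == "IR" else 1)
        planted_len += copies_len
        planted_gc += copies_len * sum(b in "GC" for b in sp.motif) / len(sp.motif)
    gc = (config.gc * n - planted_gc) / max(1, n - planted_len)
    gc = min(max(gc, 0.0), 1.0)
    # exact-composition shuffles (single-copy and IR separately, since the
    # IR is duplicated): no binomial noise on the GC target
    def _exact_draw(m: int) -> list[str]:
        n_g = n_c = round(gc * m / 2)
        n_a = (m - n_g - n_c + 1) // 2
        pool = np.array(list("G" * n_g + "C" * n_c + "A" * n_a + "T" * (m - n_g - n_c - n_a)))
        return list(rng.permutation(pool))

    bg_lsc = _exact_draw(lsc)
    bg_ir = _exact_draw(ir)
    bg_ssc = _exact_draw(ssc)
    seq = bg_lsc + bg_ir + bg_ssc + ["N"] * ir
    placer = _Placer(config.min_event_gap)

    # --- genes: quotas proportional to region length, hotspot pairs first
    names = list(config.gene_names or [f"gene{i:02d}" for i in range(1, config.n_genes + 1)])
    features: list[FeatureAnnotation] = []
    hotspot_intervals: list[tuple[int, int]] = []
    single_total = lsc + ir + ssc
    quota = {
        r: max(1, round(config.n_genes * (region_iv[r][1] - region_iv[r][0]) / single_total))
        for r in ("LSC", "IR", "SSC")
    }

    def place_gene(name: str, cursor: int, limit: int, with_intron: bool) -> int:
        max_len = min(550, limit - cursor)
        if max_len < 250:
            raise ValueError("plan overflows region capacity: gene layout")
        glen = int(rng.integers(250, max_len + 1))
        kind = "tRNA" if name.startswith("trn") else ("rRNA" if name.startswith("rrn") else "gene-exon")
        strand = 1 if rng.integers(2) else -1
        if with_intron and kind == "gene-exon":
            e1, intron = int(glen * 0.4), int(glen * 0.25)
            features.append(FeatureAnnotation(name, kind, cursor, cursor + e1, strand))
            features.append(FeatureAnnotation(name, "intron", cursor + e1, cursor + e1 + intron, strand))
            features.append(FeatureAnnotation(name, kind, cursor + e1 + intron, cursor + glen, strand))
        else:
            features.append(FeatureAnnotation(name, kind, cursor, cursor + glen, strand))
        return cursor + glen

    hotspot_names = {h.gene_a for h in config.hotspot_plan} | {h.gene_b for h in config.hotspot_plan}
    name_iter = iter(nm for nm in names if nm not in hotspot_names)
    gene_counter = 0
    for region in ("LSC", "IR", "SSC"):
        lo, hi = region_iv[region]
        cursor = lo + 80
        for hp in [h for h in config.hotspot_plan if h.region == region]:
            cursor = place_gene(hp.gene_a, cursor, hi - 80, False)
            hotspot_intervals.append((cursor + 5, cursor + 5 + hp.width))
            cursor += hp.width + 10
            cursor = place_gene(hp.gene_b, cursor, hi - 80, False)
            cursor += int(rng.integers(150, 401))
            quota[region] = max(0, quota[region] - 2)
        # spread the remaining genes over the whole region so that derived
        # intergenic spacers stay at realistic sizes
        for j in range(quota[region]):
            name = next(name_iter, None)
            if name is None:
                break
            stride = (hi - 80 - cursor) // (quota[region] - j)
            if stride < 300:
                break
            slot = cursor
            gene_counter += 1
            end = place_gene(name, slot, min(hi - 80, slot + stride - 40), gene_counter % 3 == 0)
            cursor = max(end + 150, slot + stride)

    # hotspot spacers are reserved for their own substitution clusters
    for a, b in hotspot_intervals:
        placer.reserve(a, b)

    # --- planted SSR loci (flanks broken so runs cannot extend)
    ssr_loci: list[dict] = []
    for plan in config.ssr_plan:
        u = len(plan.motif)
        length = u * plan.copies
        lo, hi = region_iv[plan.region]
        start = placer.find(rng, lo + 40, hi - 40, length)
        seq[start : start + length] = list(plan.motif * plan.copies)
        left = [b for b in _BASES if b != plan.motif[-1]]
        right = [b for b in _BASES if b != plan.motif[0]]
        seq[start - 1] = left[int(rng.integers(len(left)))]
        seq[start + length] = right[int(rng.integers(len(right)))]
        visible = plan.copies >= config.thresholds[u]
        ssr_loci.append(
            {
                "motif": plan.motif,
                "copies": plan.copies,
                "start": start,
                "end": start + length,
                "region": plan.region,
                "visible": visible,
                "mirror_of": None,
            }
        )
        if plan.region == "IR":
            m_end = _mirror_ir_position(start, irb_iv, ira_iv) + 1
            ssr_loci.append(
                {
                    "motif": revcomp(plan.motif),
                    "copies": plan.copies,
                    "start": m_end - length,
                    "end": m_end,
                    "region": "IR",
                    "visible": visible,
                    "mirror_of": start,
                }
            )

    def rebuild_ira() -> None:
        seq[ira_iv[0] : ira_iv[1]] = list(revcomp("".join(seq[irb_iv[0] : irb_iv[1]])))

    rebuild_ira()
    for f in [f for f in features if irb_iv[0] <= f.start < irb_iv[1]]:
        features.append(
            FeatureAnnotation(
                f.name,
                f.kind,
                ira_iv[0] + (irb_iv[1] - f.end),
                ira_iv[0] + (irb_iv[1] - f.start),
                -f.strand,
            )
        )
    features.sort(key=lambda f: (f.start, f.end))

    # --- scrub accidental repeat runs from the background
    planted = [(l["start"] - 2, l["end"] + 2) for l in ssr_loci]
    for _ in range(12):
        rec = PlastomeRecord(id="ancestor", sequence="".join(seq))
        extras = [
            l
            for l in scan_ssrs(rec, config.thresholds)
            if not any(a <= l.start < b or a < l.end <= b for a, b in planted)
        ]
        if not extras:
            break
        for locus in extras:
            mid = (locus.start + locus.end) // 2
            if ira_iv[0] <= mid < ira_iv[1]:  # edit the IRb twin instead
                mid = irb_iv[0] + (ira_iv[1] - 1 - mid)
            cur = seq[mid]
            for b in _BASES:
                if b != cur and b != seq[mid - 1] and b != seq[mid + 1]:
                    seq[mid] = b
                    break
        rebuild_ira()
    else:
        raise RuntimeError("failed to scrub accidental SSRs from background")

    # the detected IR must end exactly at the planted junctions: break
    # chance complementarity that would extend the repeat pair by a base
    # (left of IRb pairs with the circular first base; right of IRb with
    # the last SSC base)
    def _break_pair(edit_pos: int, partner_pos: int) -> None:
        if seq[edit_pos] == complement(seq[partner_pos]):
            for b in _BASES:
                if (
                    b != seq[edit_pos]
                    and b != complement(seq[partner_pos])
                    and b != seq[edit_pos - 1]
                    and b != seq[(edit_pos + 1) % n]
                ):
                    seq[edit_pos] = b
                    break

    _break_pair(lsc - 1, 0)
    _break_pair(ssc_iv[1] - 1, ssc_iv[0])

    record = PlastomeRecord(id="ancestor", sequence="".join(seq), features=features)
    structure = QuadripartiteStructure(
        lsc=CircularInterval(0, lsc, n),
        irb=CircularInterval(lsc, ir, n),
        ssc=CircularInterval(lsc + ir, ssc, n),
        ira=CircularInterval(lsc + ir + ssc, ir, n),
    )
    for l in ssr_loci:  # protect planted loci from later event placement
        placer.reserve(l["start"], l["end"])
    return AncestorBundle(
        record=record,
        structure=structure,
        ssr_loci=ssr_loci,
        hotspot_intervals=hotspot_intervals,
        placer=placer,
        config=config,
    )


# ---------------------------------------------------------------------------
# truth ledger


@dataclass
class TruthLedger:
    """Everything planted: events (with alignment columns), SSRs, alignment."""

    taxa: tuple[str, ...]
    ancestor: str
    events: list[dict]
    ssr_loci: list[dict]
    alignment: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict:
        per_class = {c: 0 for c in SUBSTITUTION_CLASSES}
        n_sites = 0
        ssr_indels = nr_indels = inversions = 0
        for e in self.events:
            if e["type"] == "snp":
                cols = 2 if e.get("mirrored") else 1
                n_sites += cols
                per_class[e["class"]] += cols
            elif e["type"] == "multi_snp":
                n_sites += 1
                per_class[e["class1"]] += 1
                per_class[e["class2"]] += 1
            elif e["type"] == "ssr_indel":
                ssr_indels += 1
            elif e["type"] == "nr_indel":
                nr_indels += 1
            elif e["type"] == "inversion":
                inversions += 1
        ts = sum(per_class[c] for c in SUBSTITUTION_CLASSES[:2])
        tv = sum(per_class[c] for c in SUBSTITUTION_CLASSES[2:])
        return {
            "snp_sites": n_sites,
            "per_class": per_class,
            "transitions": ts,
            "transversions": tv,
            "ssr_indels": ssr_indels,
            "nr_indels": nr_indels,
            "indels": ssr_indels + nr_indels,
            "inversions": inversions,
        }

    def shift_to_taxon(self, taxon: str, pos: int) -> int:
        """Map an ancestor coordinate to the taxon's own coordinates."""
        shift = 0
        for e in self.events:
            if e["type"] == "ssr_indel" and taxon in e["taxa"] and e["pos"] < pos:
                shift += e["delta"] * len(e["motif"])
            elif e["type"] == "nr_indel" and taxon in e["taxa"] and e["pos"] < pos:
                shift += e["length"] if e["polarity"] == "ins" else -e["length"]
        return pos + shift

    def expected_ssrs(self, taxon: str, thresholds: dict[int, int]) -> set[tuple[int, str, int]]:
        """(start_in_taxon, motif, copies) of every scannable locus of a taxon."""
        out = set()
        for l in self.ssr_loci:
            copies = l["copies"]
            for e in self.events:
                if (
                    e["type"] == "ssr_indel"
                    and taxon in e["taxa"]
                    and e.get("locus_start") == l["start"]
                ):
                    copies += e["delta"]
            if copies >= thresholds[len(l["motif"])]:
                out.add((self.shift_to_taxon(taxon, l["start"]), l["motif"], copies))
        return out

    def to_json(self, path) -> None:
        payload = {
            "taxa": list(self.taxa),
            "ancestor": self.ancestor,
            "events": self.events,
            "ssr_loci": self.ssr_loci,
            "alignment": self.alignment,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            taxa=tuple(d["taxa"]),
            ancestor=d["ancestor"],
            events=d["events"],
            ssr_loci=d["ssr_loci"],
            alignment=d["alignment"],
        )


@dataclass
class QuartetResult:
    config: SimulationConfig
    ancestor: AncestorBundle
    genomes: dict[str, PlastomeRecord]
    alignment: dict[str, str]
    ledger: TruthLedger

    @property
    def reference(self) -> PlastomeRecord:
        return self.genomes[self.config.reference]


# ---------------------------------------------------------------------------
# quartet evolution


def _snp_guard(seq: list[str], pos: int, new_base: str, thresholds) -> bool:
    """True if substituting would NOT create a threshold repeat locally."""
    lo, hi = max(0, pos - 12), min(len(seq), pos + 13)
    window = seq[lo:pos] + [new_base] + seq[pos + 1 : hi]
    return not _has_threshold_ssr("".join(window), thresholds)


def _snp_mimics_inversion(seq: list[str], pos: int, new_base: str,
                          max_len: int = 6, min_flank: int = 3, max_flank: int = 20) -> bool:
    """True if the lone substitution would be indistinguishable from a
    small inversion (reverse-complement segment with a hairpin stem).

    A substitution to the complementary base inside a locally palindromic
    context, with a chance inverted repeat abutting it, satisfies the
    inversion test exactly; such sites are rejected so that planted SNP
    and inversion counts stay separable.
    """
    n = len(seq)
    for width in range(2, max_len + 1):
        for start in range(max(0, pos - width + 1), pos + 1):
            end = start + width
            if end > n:
                continue
            seg_anc = "".join(seq[start:end])
            seg_alt = seg_anc[: pos - start] + new_base + seg_anc[pos - start + 1 :]
            if seg_alt != revcomp(seg_anc):
                continue
            for f in range(min_flank, max_flank + 1):
                if start - f < 0 or end + f > n:
                    break
                left = "".join(seq[start - f : start])
                right = "".join(seq[end : end + f])
                if left == revcomp(right):
                    return True
    return False


def _classifies_as_ssr(longer_allele: str, start: int, length: int, thresholds) -> bool:
    """Mirror of the indel classifier: would this event be an SSR-indel?"""
    content = longer_allele[start : start + length]
    for u in (1, 2):
        if length % u:
            continue
        unit = content[:u]
        if content != unit * (length // u):
            continue
        if _tandem_copies_around(longer_allele, unit, start, start + length) >= thresholds[u]:
            return True
    return False


def evolve_quartet(bundle: AncestorBundle) -> QuartetResult:
    """Apply the per-taxon event plans and emit the true alignment."""
    config = bundle.config
    rng = np.random.default_rng(config.seed + 1)
    anc = list(bundle.record.sequence)
    n = len(anc)
    taxa = config.taxa
    thresholds = config.thresholds
    placer = bundle.placer
    lsc, ir, ssc = config.region_lengths()
    irb_iv = (lsc, lsc + ir)
    ira_iv = (lsc + ir + ssc, n)
    region_iv = {"LSC": (0, lsc), "IR": irb_iv, "SSC": (lsc + ir, lsc + ir + ssc)}
    hot_placers = {i: _Placer(config.min_event_gap) for i in range(len(bundle.hotspot_intervals))}
    snp_spacer = _Placer(config.background_snp_spacing)

    def find_site(where: str, length: int, accept=None) -> int:
        if where.startswith("hot:"):
            idx = int(where.split(":")[1])
            a, b = bundle.hotspot_intervals[idx]
            return hot_placers[idx].find(rng, a + 5, b - 5 - length, length, accept)
        lo, hi = region_iv[where]
        margin = max(40, length + config.min_event_gap)
        return placer.find(rng, lo + margin, hi - margin, length, accept)

    events: list[dict] = []
    subs: dict[str, dict[int, str]] = {t: {} for t in taxa}
    inv_segments: dict[str, list[tuple[int, int]]] = {t: [] for t in taxa}
    deletions: dict[str, list[tuple[int, int]]] = {t: [] for t in taxa}
    insertions: dict[int, tuple[tuple[str, ...], str]] = {}  # pos -> (taxa, seq)

    # --- inversions first: they install flank cassettes into the ancestor
    for plan in config.inversion_plan:
        if plan.region == "IR":
            raise ValueError("inversions in the IR are not supported by the generator")
        if not 2 <= plan.length <= 6:
            raise ValueError("inversion length must be 2-6 bp")
        total = plan.length + 2 * plan.flank
        for _ in range(80):
            pos = find_site(plan.region, total)
            flank = "".join(rng.choice(list(_BASES), size=plan.flank))
            seg = list(rng.choice(list(_BASES), size=plan.length))
            seg[0] = seg[-1] = "A"  # first/last columns mismatch after inversion
            seg = "".join(seg)
            cassette = flank + seg + revcomp(flank)
            context = "".join(anc[pos - 8 : pos]) + cassette + "".join(anc[pos + total : pos + total + 8])
            if _has_threshold_ssr(context, thresholds):
                placer.unreserve(pos, pos + total)
                continue
            anc[pos : pos + total] = list(cassette)
            # the detected stem must end exactly at the planted flank
            if plan.flank < 20 and anc[pos - 1] == complement(anc[pos + total]):
                for b in _BASES:
                    if b != anc[pos + total] and b != complement(anc[pos - 1]) and b != anc[pos + total + 1]:
                        anc[pos + total] = b
                        break
            break
        else:
            raise ValueError("could not place inversion cassette")
        seg_start = pos + plan.flank
        inv_segments[plan.taxon].append((seg_start, seg_start + plan.length))
        # inversion columns contribute to windowed diversity; keep
        # background substitutions away so only planted hotspots can
        # cross the hotspot threshold
        snp_spacer.reserve(seg_start - 150, seg_start + plan.length + 150)
        events.append(
            {
                "type": "inversion",
                "taxa": [plan.taxon],
                "pos": seg_start,
                "length": plan.length,
                "flank": plan.flank,
                "segment": seg,
                "region": plan.region,
            }
        )

    # --- substitutions (placed last: indel and inversion sites carry
    # 60 bp exclusion pads that must exist before substitutions draw)
    def place_snp(taxon: str, sub_class: str, where: str, partner=None) -> None:
        anc_map = _CLASS_ANC[sub_class]
        allowed = set(anc_map)
        if partner is not None:
            allowed &= set(_CLASS_ANC[partner[1]])
            if not allowed:
                raise ValueError(f"incompatible class pair {sub_class} / {partner[1]}")

        def accept(s: int) -> bool:
            if anc[s] not in allowed:
                return False
            if not where.startswith("hot:") and not snp_spacer.is_free(s, s + 1):
                return False
            if not _snp_guard(anc, s, anc_map[anc[s]], thresholds):
                return False
            if partner is None and _snp_mimics_inversion(anc, s, anc_map[anc[s]]):
                return False
            if partner is not None:
                d2 = _CLASS_ANC[partner[1]][anc[s]]
                if d2 == anc_map[anc[s]] or not _snp_guard(anc, s, d2, thresholds):
                    return False
            return True

        pos = find_site(where, 1, accept)
        if not where.startswith("hot:"):
            snp_spacer.reserve(pos, pos + 1)
        base = anc[pos]
        subs[taxon][pos] = anc_map[base]
        if partner is not None:
            p_taxon, p_class = partner
            subs[p_taxon][pos] = _CLASS_ANC[p_class][base]
            events.append(
                {
                    "type": "multi_snp",
                    "taxa": [taxon, p_taxon],
                    "pos": pos,
                    "anc": base,
                    "derived1": anc_map[base],
                    "derived2": _CLASS_ANC[p_class][base],
                    "class1": sub_class,
                    "class2": p_class,
                    "where": where,
                }
            )
            return
        ev = {
            "type": "snp",
            "taxa": [taxon],
            "pos": pos,
            "anc": base,
            "derived": anc_map[base],
            "class": sub_class,
            "where": where,
            "mirrored": False,
        }
        if where == "IR":
            mpos = _mirror_ir_position(pos, irb_iv, ira_iv)
            placer.reserve(mpos, mpos + 1)
            snp_spacer.reserve(mpos, mpos + 1)
            subs[taxon][mpos] = complement(anc_map[base])
            ev["mirrored"] = True
            ev["mirror_pos"] = mpos
        events.append(ev)

    # --- SSR slippage events, each on its own planted single-copy locus
    used_loci: set[int] = set()
    for plan in config.ssr_indel_plan:
        locus = next(
            (
                l
                for l in bundle.ssr_loci
                if l["start"] not in used_loci
                and l["mirror_of"] is None
                and l["region"] != "IR"
                and (plan.target_motif is None or l["motif"] == plan.target_motif)
                and (plan.target_copies is None or l["copies"] == plan.target_copies)
                and l["copies"] + plan.delta >= 2
            ),
            None,
        )
        if locus is None:
            raise ValueError(f"no available SSR locus for slippage plan {plan}")
        used_loci.add(locus["start"])
        u = len(locus["motif"])
        length = u * abs(plan.delta)
        if plan.delta < 0:
            deletions[plan.taxon].append((locus["end"] - length, locus["end"]))
            pos = locus["end"] - length
        else:
            insertions[locus["end"]] = ((plan.taxon,), locus["motif"] * plan.delta)
            pos = locus["end"]
        events.append(
            {
                "type": "ssr_indel",
                "taxa": [plan.taxon],
                "pos": pos,
                "length": length,
                "motif": locus["motif"],
                "delta": plan.delta,
                "locus_start": locus["start"],
                "region": locus["region"],
                "polarity": "ins" if plan.delta > 0 else "del",
            }
        )

    # --- non-repeat indels
    for plan in config.nr_indel_plan:
        region = plan.region or str(rng.choice(["LSC", "SSC"], p=[0.85, 0.15]))
        if plan.polarity == "del":

            def accept_del(s: int, L=plan.length) -> bool:
                junction = "".join(anc[max(0, s - 10) : s]) + "".join(anc[s + L : s + L + 10])
                if _has_threshold_ssr(junction, thresholds):
                    return False
                # the surviving allele is the ancestor: the event must not
                # sit in a repeat run that would classify it as an SSR-indel
                lo = max(0, s - 40)
                window = "".join(anc[lo : s + L + 40])
                return not _classifies_as_ssr(window, s - lo, L, thresholds)

            pos = find_site(region, plan.length, accept_del)
            if plan.length >= 20:  # long gaps shrink windows' usable sites
                snp_spacer.reserve(pos - 150, pos + plan.length + 150)
            for t in plan.taxa:
                deletions[t].append((pos, pos + plan.length))
            events.append(
                {
                    "type": "nr_indel",
                    "taxa": list(plan.taxa),
                    "pos": pos,
                    "length": plan.length,
                    "sequence": "".join(anc[pos : pos + plan.length]),
                    "polarity": "del",
                }
            )
        else:
            for _ in range(80):
                pos = find_site(region, 1)
                ins = "".join(rng.choice(list(_BASES), size=plan.length))
                # the longer allele carries the insertion: check it neither
                # scans as a new SSR nor classifies the event as SSR-related
                lo = max(0, pos - 40)
                virtual = "".join(anc[lo:pos]) + ins + "".join(anc[pos : pos + 40])
                if _has_threshold_ssr(virtual, thresholds) or _classifies_as_ssr(
                    virtual, pos - lo, plan.length, thresholds
                ):
                    placer.unreserve(pos, pos + 1)
                    continue
                break
            else:
                raise ValueError("could not place NR insertion")
            insertions[pos] = (tuple(plan.taxa), ins)
            if plan.length >= 20:
                snp_spacer.reserve(pos - 150, pos + 150)
            events.append(
                {
                    "type": "nr_indel",
                    "taxa": list(plan.taxa),
                    "pos": pos,
                    "length": plan.length,
                    "sequence": ins,
                    "polarity": "ins",
                }
            )

    for plan in config.snp_plan:
        place_snp(plan.taxon, plan.sub_class, plan.where)
    for plan in config.multi_snp_plan:
        place_snp(plan.taxon1, plan.class1, plan.where, partner=(plan.taxon2, plan.class2))

    # --- weave the true alignment (events are isolated, so no realignment)
    anc_str = "".join(anc)
    rows = {t: list(anc_str) for t in taxa}
    for t in taxa:
        for p, b in subs[t].items():
            rows[t][p] = b
        for a, b in inv_segments[t]:
            rows[t][a:b] = list(revcomp(anc_str[a:b]))
        for a, b in deletions[t]:
            rows[t][a:b] = ["-"] * (b - a)

    ins_positions = sorted(insertions)
    aln_parts: dict[str, list[str]] = {t: [] for t in taxa}
    a2c = np.zeros(n, dtype=np.int64)  # ancestor position -> alignment column
    ins_columns: dict[int, tuple[int, int]] = {}
    col = prev = 0
    for pos in ins_positions + [n]:
        width = pos - prev
        for t in taxa:
            aln_parts[t].append("".join(rows[t][prev:pos]))
        a2c[prev:pos] = np.arange(col, col + width)
        col += width
        if pos < n:
            ins_taxa, ins_seq = insertions[pos]
            ins_columns[pos] = (col, col + len(ins_seq))
            for t in taxa:
                aln_parts[t].append(ins_seq if t in ins_taxa else "-" * len(ins_seq))
            col += len(ins_seq)
        prev = pos
    alignment = {t: "".join(parts) for t, parts in aln_parts.items()}

    for e in events:  # annotate events with their alignment columns
        if e["type"] in ("snp", "multi_snp"):
            e["columns"] = [int(a2c[e["pos"]])]
            if e.get("mirrored"):
                e["columns"].append(int(a2c[e["mirror_pos"]]))
        elif e["type"] == "inversion":
            e["columns"] = [int(a2c[e["pos"]]), int(a2c[e["pos"] + e["length"] - 1]) + 1]
        elif e["polarity"] == "del":
            e["columns"] = [int(a2c[e["pos"]]), int(a2c[e["pos"] + e["length"] - 1]) + 1]
        else:
            e["columns"] = list(ins_columns[e["pos"]])

    ledger = TruthLedger(
        taxa=taxa,
        ancestor=anc_str,
        events=events,
        ssr_loci=bundle.ssr_loci,
        alignment=alignment,
    )

    # reference features remapped through the reference's own indels
    ref = config.reference
    ref_features: list[FeatureAnnotation] = []
    for f in bundle.record.features:
        a = ledger.shift_to_taxon(ref, f.start)
        b = ledger.shift_to_taxon(ref, f.end)
        if a < b:
            ref_features.append(FeatureAnnotation(f.name, f.kind, a, b, f.strand))
    genomes = {
        t: PlastomeRecord(
            id=t,
            sequence=alignment[t].replace("-", ""),
            features=ref_features if t == ref else [],
        )
        for t in taxa
    }
    return QuartetResult(
        config=config,
        ancestor=bundle,
        genomes=genomes,
        alignment=alignment,
        ledger=ledger,
    )


def simulate_quartet(config: SimulationConfig) -> QuartetResult:
    """Generate the ancestor and evolve the quartet in one call."""
    return evolve_quartet(generate_ancestor(config))


def replay_taxon(ledger: TruthLedger, taxon: str) -> str:
    """Rebuild a taxon's genome by applying its ledger events to the ancestor."""
    anc = ledger.ancestor
    rows: list[str] = list(anc)
    cuts: list[tuple[int, int]] = []
    inserts: list[tuple[int, str]] = []
    for e in ledger.events:
        if e["type"] == "snp" and taxon in e["taxa"]:
            rows[e["pos"]] = e["derived"]
            if e.get("mirrored"):
                rows[e["mirror_pos"]] = complement(e["derived"])
        elif e["type"] == "multi_snp":
            if taxon == e["taxa"][0]:
                rows[e["pos"]] = e["derived1"]
            elif taxon == e["taxa"][1]:
                rows[e["pos"]] = e["derived2"]
        elif e["type"] == "inversion" and taxon in e["taxa"]:
            a, b = e["pos"], e["pos"] + e["length"]
            rows[a:b] = list(revcomp(anc[a:b]))
        elif e["type"] in ("ssr_indel", "nr_indel") and taxon in e["taxa"]:
            if e["polarity"] == "del":
                cuts.append((e["pos"], e["pos"] + e["length"]))
            else:
                inserts.append((e["pos"], e.get("sequence") or e["motif"] * e["delta"]))
    for a, b in cuts:
        rows[a:b] = [""] * (b - a)
    for pos, s in sorted(inserts, reverse=True):
        rows[pos:pos] = [s]
    return "".join(rows)


def evaluate_recovery(ledger: TruthLedger, snps, indels, inversions) -> dict:
    """Recall and precision of called events against the truth ledger.

    Events are matched by alignment column and payload: a substitution
    matches when the called site at its column carries the planted
    class; an indel when its column interval, gap-bearing taxa and
    SSR/NR classification agree; an inversion when its column interval,
    inverted taxa and stem length agree.
    """
    called_snps = {s.column: s for s in snps}
    true_cols = []
    hit = 0
    for e in ledger.events:
        if e["type"] == "snp":
            for col in e["columns"]:
                true_cols.append(col)
                s = called_snps.get(col)
                if s is not None and e["class"] in s.classes:
                    hit += 1
        elif e["type"] == "multi_snp":
            col = e["columns"][0]
            true_cols.append(col)
            s = called_snps.get(col)
            if s is not None and sorted(s.classes) == sorted([e["class1"], e["class2"]]):
                hit += 1
    snp_recall = hit / len(true_cols) if true_cols else 1.0
    snp_precision = hit / len(called_snps) if called_snps else 1.0

    want_class = {"ssr_indel": "SSR-indel", "nr_indel": "NR-indel"}
    true_indels = {
        (e["columns"][0], e["columns"][1], tuple(sorted(e["taxa"])), want_class[e["type"]])
        for e in ledger.events
        if e["type"] in want_class
    }
    called_indels = {
        (
            e.column_start,
            e.column_end,
            tuple(sorted(e.taxa_with_gap if e.polarity != "insertion" else
                         set(ledger.taxa) - set(e.taxa_with_gap))),
            e.classification,
        )
        for e in indels
    }
    ind_hit = len(true_indels & called_indels)

    true_invs = {
        (e["columns"][0], e["columns"][1], tuple(sorted(e["taxa"])), e["flank"])
        for e in ledger.events
        if e["type"] == "inversion"
    }
    called_invs = {
        (e.column_start, e.column_end, tuple(sorted(e.inverted_taxa)), e.flank_repeat_length)
        for e in inversions
    }
    inv_hit = len(true_invs & called_invs)

    def rp(h, t, c):
        return {
            "recall": h / t if t else 1.0,
            "precision": h / c if c else 1.0,
        }

    return {
        "snp": {"recall": snp_recall, "precision": snp_precision},
        "indel": rp(ind_hit, len(true_indels), len(called_indels)),
        "inversion": rp(inv_hit, len(true_invs), len(called_invs)),
    }


# ---------------------------------------------------------------------------
# canned configurations


def default_config(seed: int = 0, genome_length: int = 20_000) -> SimulationConfig:
    """Desk-scale quartet: 60 substitutions (40 Ts : 20 Tv), 12 SSR
    slippage events, 15 NR-indels and 3 small inversions across three
    derived taxa, on a 20 kb quadripartite genome."""
    A, B, C, D = "taxonA", "taxonB", "taxonC", "taxonD"
    ssr_plan = [
        SSRPlan("A", 12, "LSC"),
        SSRPlan("T", 11, "LSC"),
        SSRPlan("A", 10, "SSC"),
        SSRPlan("C", 10, "LSC"),
        SSRPlan("A", 11, "LSC"),
        SSRPlan("T", 12, "LSC"),
        SSRPlan("A", 13, "LSC"),
        SSRPlan("T", 10, "SSC"),
        SSRPlan("AT", 6, "LSC"),
        SSRPlan("AG", 5, "LSC"),
        SSRPlan("AAT", 5, "LSC"),
        SSRPlan("AATC", 4, "LSC"),
        SSRPlan("AAAT", 3, "LSC"),
        SSRPlan("A", 10, "LSC"),
        SSRPlan("A", 11, "SSC"),
        SSRPlan("A", 10, "IR"),
    ]
    K = SUBSTITUTION_CLASSES
    snp_plan: list[SNPPlan] = []

    def add_snps(taxon, counts):
        i = 0
        for label, k in counts.items():
            for _ in range(k):
                snp_plan.append(SNPPlan(taxon, label, "LSC" if i % 4 else "SSC"))
                i += 1

    add_snps(B, {K[0]: 4, K[1]: 3, K[2]: 1, K[3]: 1, K[4]: 1})
    add_snps(C, {K[0]: 7, K[1]: 6, K[2]: 2, K[3]: 2, K[4]: 2, K[5]: 1})
    add_snps(D, {K[0]: 10, K[1]: 10, K[2]: 3, K[3]: 3, K[4]: 2, K[5]: 2})
    # slippage targets are mono/dinucleotide runs, as observed in plastomes
    ssr_indel_plan = (
        [SSRIndelPlan(B, +1, "A"), SSRIndelPlan(B, -1, "T")]
        + [SSRIndelPlan(C, -1, "A"), SSRIndelPlan(C, +1, "T"), SSRIndelPlan(C, +2, "AT"), SSRIndelPlan(C, +1, "A")]
        + [
            SSRIndelPlan(D, +1, "A"),
            SSRIndelPlan(D, -2, "A"),
            SSRIndelPlan(D, -1, "T"),
            SSRIndelPlan(D, +1, "C"),
            SSRIndelPlan(D, -1, "AG"),
            SSRIndelPlan(D, -1, "A"),
        ]
    )
    nr_indel_plan = (
        [NRIndelPlan((B,), l, p) for l, p in ((1, "del"), (5, "ins"), (2, "del"))]
        + [NRIndelPlan((C,), l, p) for l, p in ((1, "ins"), (1, "del"), (5, "del"), (4, "ins"), (8, "del"))]
        + [
            NRIndelPlan((D,), l, p)
            for l, p in ((1, "del"), (5, "ins"), (5, "del"), (3, "ins"), (2, "del"), (6, "ins"), (30, "del"))
        ]
    )
    inversion_plan = [
        InversionPlan(C, 4, 8, "LSC"),
        InversionPlan(D, 6, 14, "LSC"),
        InversionPlan(D, 2, 12, "LSC"),
    ]
    return SimulationConfig(
        seed=seed,
        genome_length=genome_length,
        ssr_plan=ssr_plan,
        snp_plan=snp_plan,
        ssr_indel_plan=ssr_indel_plan,
        nr_indel_plan=nr_indel_plan,
        inversion_plan=inversion_plan,
    )


def sorghum_like_config(seed: int = 0) -> SimulationConfig:
    """Full-scale quartet emulating a four-taxon Sorghum-style plastome set.

    ~140.8 kb genomes at 38.5% GC with realistic region proportions; 633
    substitution sites (615 biallelic + 18 triallelic, 9 of the
    biallelic ones mirrored across the two IR copies), giving 651
    substitutions split 345 transitions : 306 transversions and a
    518/18/97 LSC/IR/SSC site distribution; 43 SSR slippage indels (39
    at A/T mononucleotide runs, 3 at C/G runs, 1 dinucleotide) and 94
    NR-indels with sizes 1-165 bp (the largest a deletion in the
    reference taxon); nine 2-6 bp inversions with 3-20 bp hairpin
    stems, eight private to the most divergent taxon; substitutions
    clustered in four spacers (rps16-trnQ, trnG-trnM, rbcL-psaI,
    rps15-ndhF) so they emerge as diversity hotspots.
    """
    SUD, PRO, BIC, TIM = "S_sudanense", "S_propinquum", "S_bicolor", "S_timorense"
    K = SUBSTITUTION_CLASSES
    gene_names = [
        "rpoC", "rpoC1", "ndhA", "atpF", "rpl16", "petB", "clpP", "ycf3",
        "trnK", "matK", "psbA", "rps16", "trnQ", "trnG", "trnM", "rbcL",
        "psaI", "rps15", "ndhF", "ccsA", "rpl32", "petA", "psbJ", "psbM",
        "petN", "trnT", "trnE", "rpl33", "rps18", "rps12", "rps7", "ndhB",
        "rpl23", "rpl2", "rps19", "trnH", "trnI", "trnL", "trnN", "rrn16",
        "rrn23", "rrn5", "psbB", "psbC", "psbD", "atpA", "atpB", "ndhC",
        "ndhD", "ndhE",
    ]
    hotspot_plan = [
        HotspotPlan("rps16", "trnQ", "LSC"),
        HotspotPlan("trnG", "trnM", "LSC"),
        HotspotPlan("rbcL", "psaI", "LSC"),
        HotspotPlan("rps15", "ndhF", "SSC"),
    ]
    # 37 scan-visible single-copy loci + 2 IR loci (scanned in both
    # copies => 41 loci per genome) + sub-threshold A/T runs available
    # for upward slippage
    ssr_plan = (
        [SSRPlan("A", 10, "LSC") for _ in range(10)]
        + [SSRPlan("T", 10, "LSC") for _ in range(5)]
        + [SSRPlan("A", 10, "SSC"), SSRPlan("T", 10, "SSC")]
        + [SSRPlan("A", 11, "LSC"), SSRPlan("A", 12, "LSC"), SSRPlan("A", 13, "LSC")]
        + [SSRPlan("T", 12, "LSC"), SSRPlan("T", 11, "LSC")]
        + [SSRPlan("C", 10, "LSC"), SSRPlan("C", 10, "SSC"), SSRPlan("G", 10, "LSC")]
        + [SSRPlan("AT", 5, "LSC"), SSRPlan("TA", 5, "LSC"), SSRPlan("AG", 5, "LSC")]
        + [SSRPlan("AT", 6, "SSC"), SSRPlan("CT", 5, "LSC"), SSRPlan("AT", 5, "LSC")]
        + [SSRPlan("AAT", 4, "LSC"), SSRPlan("ATC", 4, "LSC")]
        + [SSRPlan("AAAT", 3, "LSC"), SSRPlan("AATT", 3, "LSC"), SSRPlan("ATCC", 3, "LSC")]
        + [SSRPlan("AAAG", 3, "SSC")]
        + [SSRPlan("A", 10, "IR"), SSRPlan("TTTA", 3, "IR")]
        + [SSRPlan("A", 9, "LSC") for _ in range(15)]
        + [SSRPlan("A", 9, "SSC") for _ in range(3)]
        + [SSRPlan("T", 9, "LSC") for _ in range(5)]
    )

    snp_plan: list[SNPPlan] = []
    multi_snp_plan: list[MultiSNPPlan] = []

    def singles(taxon, counts, n_ssc):
        i = 0
        for label, k in counts.items():
            for _ in range(k):
                snp_plan.append(SNPPlan(taxon, label, "SSC" if i < n_ssc else "LSC"))
                i += 1

    # hotspot clusters: 15 divergent-taxon substitutions per spacer,
    # alternating one transition and one transversion class
    for h in range(4):
        for j in range(15):
            snp_plan.append(SNPPlan(TIM, K[0] if (h * 15 + j) % 2 == 0 else K[3], f"hot:{h}"))
    # IR substitutions (mirrored; each occupies two alignment sites)
    for label, k in {K[0]: 4, K[1]: 3, K[2]: 1, K[3]: 1}.items():
        for _ in range(k):
            snp_plan.append(SNPPlan(TIM, label, "IR"))
    # remaining biallelic singles, tuned so the measured spectrum over all
    # 651 substitutions is 179/166/92/92/92/30
    singles(SUD, {K[0]: 1}, 0)
    singles(BIC, {K[0]: 1, K[1]: 1}, 1)
    singles(PRO, {K[0]: 10, K[1]: 15, K[2]: 10, K[3]: 10, K[4]: 10, K[5]: 5}, 10)
    singles(TIM, {K[0]: 117, K[1]: 138, K[2]: 68, K[3]: 44, K[4]: 82, K[5]: 25}, 71)
    for i in range(18):  # triallelic sites: two derived alleles on two taxa
        if i < 12:
            multi_snp_plan.append(MultiSNPPlan(TIM, K[0], PRO, K[2], "LSC"))
        else:
            multi_snp_plan.append(MultiSNPPlan(TIM, K[1], PRO, K[3], "LSC"))

    # 43 slippage events (39 A/T, 3 C/G, 1 dinucleotide).  Deletions hit
    # threshold-level runs (dropping them below detection in the mutated
    # taxon) and insertions promote sub-threshold runs, so per-genome
    # scan totals come out 41 / 45 / 41 / 38
    ssr_indel_plan = (
        [SSRIndelPlan(PRO, +1, "A", 9) for _ in range(4)]
        + [SSRIndelPlan(TIM, -1, "A", 10) for _ in range(11)]
        + [SSRIndelPlan(TIM, -1, "T", 10) for _ in range(6)]
        + [SSRIndelPlan(TIM, +1, "A", 9) for _ in range(14)]
        + [SSRIndelPlan(TIM, +1, "A", 11), SSRIndelPlan(TIM, +2, "A", 12)]
        + [SSRIndelPlan(TIM, +1, "A", 13), SSRIndelPlan(TIM, +1, "T", 12)]
        + [SSRIndelPlan(TIM, +1, "C", 10) for _ in range(2)]
        + [SSRIndelPlan(TIM, +1, "G", 10)]
        + [SSRIndelPlan(TIM, +1, "AT", 5)]
    )
    # 94 NR-indels; the 165 bp event is a reference (S_sudanense) deletion.
    # Reference-taxon indels are pinned to the LSC so the reference genome
    # measures 140,755 bp with an 82,686 bp LSC
    tim_ins = [152] + [1] * 14 + [5] * 10 + [2] * 4 + [3] * 4 + [4] * 4 + [6] * 3 + [8, 10, 12, 15, 18, 22]
    tim_del = [1] * 14 + [5] * 10 + [2] * 4 + [3] * 4 + [4] * 3 + [6] * 3 + [27, 33, 40, 57]
    nr_indel_plan = (
        [NRIndelPlan((TIM,), l, "ins") for l in tim_ins]
        + [NRIndelPlan((TIM,), l, "del") for l in tim_del]
        + [
            NRIndelPlan((SUD,), 165, "del", "LSC"),
            NRIndelPlan((SUD,), 4, "del", "LSC"),
            NRIndelPlan((SUD,), 1, "ins", "LSC"),
        ]
        + [NRIndelPlan((PRO,), 5, "ins")]
        + [NRIndelPlan((BIC, SUD), 6, "del", "LSC"), NRIndelPlan((BIC, SUD), 2, "del", "LSC")]
    )
    inversion_plan = [
        InversionPlan(TIM, 2, 12, "LSC"),
        InversionPlan(TIM, 2, 6, "LSC"),
        InversionPlan(TIM, 2, 5, "LSC"),
        InversionPlan(TIM, 6, 14, "LSC"),
        InversionPlan(TIM, 6, 8, "LSC"),
        InversionPlan(TIM, 6, 14, "LSC"),
        InversionPlan(TIM, 2, 3, "LSC"),
        InversionPlan(TIM, 4, 8, "LSC"),
        InversionPlan(SUD, 4, 20, "SSC"),
    ]
    # the ancestor is 176 bp longer than the target reference because the
    # reference carries 176 bp of net LSC deletion (165+4+6+2 minus a 1 bp
    # insertion); after its events the reference measures 140,755 bp with
    # LSC/IR/SSC of 82,686 / 22,783 / 12,503 bp
    return SimulationConfig(
        seed=seed,
        genome_length=140_931,
        lsc_frac=82862 / 140931,
        ir_frac=22783 / 140931,
        gc=0.385,
        n_genes=50,
        gene_names=gene_names,
        taxa=(SUD, PRO, BIC, TIM),
        ssr_plan=list(ssr_plan),
        snp_plan=snp_plan,
        multi_snp_plan=multi_snp_plan,
        ssr_indel_plan=ssr_indel_plan,
        nr_indel_plan=nr_indel_plan,
        inversion_plan=inversion_plan,
        hotspot_plan=hotspot_plan,
    )
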