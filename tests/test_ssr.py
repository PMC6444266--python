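"""Microsatellite detection: thresholds, smallest-unit rule, stratification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plastovar.io import PlastomeRecord
from plastovar.ssr import (
    DEFAULT_THRESHOLDS,
    canonical_class,
    scan_ssrs,
    summarize_ssrs,
)

BG = "GCTAGCTCGATCGTAGCATGCTAGCCTGATCGCATGGCAATCCGTACG"  # repeat-free padding


def _scan(seq, **kw):
    return scan_ssrs(PlastomeRecord(id="s", sequence=seq), **kw)


class TestThresholdsAndUnits:
    def test_run_below_threshold_not_reported(self):
        assert _scan(BG + "C" * 9 + BG) == []

    def test_mononucleotide_at_threshold(self):
        loci = _scan(BG + "C" * 10 + BG)
        assert len(loci) == 1
        l = loci[0]
        assert (l.motif, l.copy_number, l.unit_length) == ("C", 10, 1)
        assert l.start == len(BG) and l.end == len(BG) + 10

    def test_dinucleotide_detection_and_class(self):
        loci = _scan(BG + "AG" * 5 + BG)
        assert len(loci) == 1
        assert loci[0].unit_length == 2 and loci[0].copy_number == 5
        assert loci[0].canonical_class == canonical_class("GA")

    def test_at_run_is_dinucleotide_not_mononucleotide(self):
        # AT x 5: no mononucleotide run reaches 10, so the smallest unit
        # spanning the interval is the dinucleotide
        loci = _scan(BG + "ATATATATAT" + BG)
        assert [l.unit_length for l in loci] == [2]

    def test_a_run_is_mononucleotide_not_aa(self):
        loci = _scan(BG + "A" * 12 + BG)
        assert [(l.motif, l.copy_number) for l in loci] == [("A", 12)]

    def test_run_broken_at_n(self):
        assert _scan(BG + "A" * 6 + "N" + "A" * 6 + BG) == []

    def test_missing_threshold_is_config_error(self):
        with pytest.raises(ValueError, match="unit length"):
            _scan(BG + "A" * 12 + BG, thresholds={1: 10, 2: 5})

    @pytest.mark.parametrize(
        "motif,label",
        [("A", "A/T"), ("T", "A/T"), ("AT", "AT/TA"), ("TA", "AT/TA"), ("AG", "AG/TC")],
    )
    def test_canonical_class_collapses_rotation_and_strand(self, motif, label):
        assert canonical_class(motif) == label


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=0, max_size=150))
def test_scan_properties_on_arbitrary_sequences(seq):
    """Reported loci are perfect, maximal, non-overlapping, and complete."""
    if not seq:
        return
    loci = _scan(seq)
    prev_end = -1
    for l in loci:
        assert seq[l.start : l.end] == l.motif * l.copy_number
        assert l.copy_number >= DEFAULT_THRESHOLDS[l.unit_length]
        assert l.start >= prev_end, "loci overlap"
        prev_end = l.end
        # one more full unit on either side must be impossible, unless the
        # run was trimmed against an abutting locus of another unit length
        abuts_previous = any(o.end >= l.start > o.start for o in loci if o is not l)
        if l.start >= l.unit_length and not abuts_previous:
            assert seq[l.start - l.unit_length : l.start] != l.motif
        if l.end + l.unit_length <= len(seq):
            assert seq[l.end : l.end + l.unit_length] != l.motif
    # completeness for mononucleotides: every >= 10 run intersects a locus
    import re

    for m in re.finditer(r"(A{10,}|C{10,}|G{10,}|T{10,})", seq):
        assert any(l.start < m.end() and m.start() < l.end for l in loci)


def test_determinism(quartet):
    rec = quartet.reference
    first = scan_ssrs(rec)
    second = scan_ssrs(rec)
    assert first == second


def test_planted_recovery_all_taxa(quartet):
    """Recall and precision are 1.0 against the generator's ledger."""
    for taxon, rec in quartet.genomes.items():
        found = {(l.start, l.motif, l.copy_number) for l in scan_ssrs(rec)}
        expected = quartet.ledger.expected_ssrs(taxon, DEFAULT_THRESHOLDS)
        assert found == expected, taxon


class TestSummaries:
    def test_empty_input_gives_zero_tables(self):
        tables = summarize_ssrs({"g1": []})
        assert tables["proportions"].empty
        assert (tables["by_unit"].to_numpy() == 0).all() if not tables["by_unit"].empty else True

    def test_single_planted_locus_counts_once(self, quartet, quartet_structure):
        rec = quartet.reference
        loci = scan_ssrs(rec, structure=quartet_structure)
        tables = summarize_ssrs({rec.id: loci})
        by_region = tables["by_region"]
        assert by_region["pooled"].sum() == len(loci)
        by_unit = tables["by_unit"]
        assert by_unit["pooled"].sum() == len(loci)
        # proportions sum to ~100 within each table
        props = tables["proportions"]
        unit_pct = props[props.table == "by_unit"].percent.sum()
        assert unit_pct == pytest.approx(100.0, abs=0.1)

    def test_pooled_counts_add_over_genomes(self, quartet):
        loci = {t: scan_ssrs(r) for t, r in quartet.genomes.items()}
        tables = summarize_ssrs(loci)
        assert tables["by_unit"]["pooled"].sum() == sum(len(v) for v in loci.values())
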