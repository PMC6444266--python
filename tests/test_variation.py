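"""SNP, indel and inversion calling from multiple alignments."""

import itertools

import numpy as np
import pytest

from plastovar.io import revcomp
from plastovar.variation import (
    AlignmentSet,
    SUBSTITUTION_CLASSES,
    TRANSITION_CLASSES,
    call_indels,
    call_inversions,
    call_snps,
    call_variants,
    load_alignment,
    snp_summary,
    substitution_class,
)

TAXA4 = ["t1", "t2", "t3", "t4"]


def _aln(rows, taxa=None, reference=None):
    taxa = taxa or TAXA4[: len(rows)]
    return AlignmentSet(taxa=taxa, rows=rows, reference_taxon=reference or taxa[0])


PAD_L = "GCTAGCTCGATCGTAGCATGCTAGCC"
PAD_R = "TGATCGCATGGCAATCCGTACGGTCA"


class TestLoad:
    def test_ragged_rows_raise(self):
        with pytest.raises(ValueError, match="ragged"):
            _aln(["ACGT", "ACG"])

    def test_absent_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            _aln(["ACGT", "ACGT"], reference="nope")

    def test_column_map_skips_gaps(self):
        aln = _aln(["AC-GT", "ACAGT"])
        # gapped column carries the preceding base's coordinate
        assert list(aln.column_maps[0]) == [0, 1, 1, 2, 3]
        assert aln.ungapped("t1") == "ACGT"

    def test_load_aligned_fasta(self, tmp_path, quartet):
        path = tmp_path / "aln.fasta"
        with open(path, "w") as fh:
            for t, row in quartet.alignment.items():
                fh.write(f">{t}\n{row}\n")
        aln = load_alignment(path, quartet.config.reference)
        for t in quartet.config.taxa:
            assert aln.ungapped(t) == quartet.genomes[t].sequence


class TestSubstitutionClasses:
    def test_twelve_ordered_pairs_map_onto_six_classes(self):
        counts = {}
        for a, b in itertools.permutations("ACGT", 2):
            counts.setdefault(substitution_class(a, b), 0)
            counts[substitution_class(a, b)] += 1
        assert set(counts) == set(SUBSTITUTION_CLASSES)
        assert all(v == 2 for v in counts.values())

    def test_transitions_are_purine_purine_or_pyrimidine_pyrimidine(self):
        assert substitution_class("A", "G") in TRANSITION_CLASSES
        assert substitution_class("T", "C") in TRANSITION_CLASSES
        assert substitution_class("A", "C") not in TRANSITION_CLASSES


class TestSNPs:
    def test_majority_to_minority_direction(self):
        aln = _aln(["AAAA", "AAAA", "AAAA", "AGAA"])
        sites = call_snps(aln)
        assert len(sites) == 1
        s = sites[0]
        assert s.majority_allele == "A" and s.classes == ("A→G/T→C",)
        assert s.is_transition

    def test_strand_complement_column_same_class(self):
        up = call_snps(_aln(["A", "A", "A", "G"]))[0]
        down = call_snps(_aln(["T", "T", "T", "C"]))[0]
        assert up.classes == down.classes

    def test_tie_broken_toward_reference_allele(self):
        sites = call_snps(_aln(["G", "G", "A", "A"]))
        assert sites[0].majority_allele == "G"
        assert sites[0].classes == ("G→A/C→T",)

    def test_gapped_and_n_columns_excluded(self):
        aln = _aln(["A-NA", "AANA", "AGNA", "AGNA"])
        assert call_snps(aln) == []

    def test_summary_conservation(self, quartet, quartet_alignment):
        sites = call_snps(quartet_alignment)
        ssn = snp_summary(sites, quartet_alignment)
        assert ssn["transitions"] + ssn["transversions"] == sum(ssn["per_class"].values())
        assert ssn["n_substitutions"] >= ssn["n_sites"]


def brute_force_gap_segmentation(rows):
    """Independent column-by-column oracle for indel segmentation."""
    L = len(rows[0])
    k = len(rows)
    events = []
    current = None
    for col in range(L):
        pattern = tuple(i for i in range(k) if rows[i][col] == "-")
        if 0 < len(pattern) < k:
            if current and current[2] == pattern and current[1] == col:
                current = (current[0], col + 1, pattern)
                events[-1] = current
            else:
                current = (col, col + 1, pattern)
                events.append(current)
        else:
            current = None
    return [(a, b, pat) for a, b, pat in events]


class TestIndels:
    def test_ssr_indel_at_mononucleotide_run(self):
        ref = PAD_L + "A" * 11 + PAD_R
        alt = PAD_L + "A" * 10 + "-" + PAD_R
        aln = _aln([ref, alt, alt, alt])
        events = call_indels(aln)
        assert len(events) == 1
        e = events[0]
        assert e.classification == "SSR-indel" and e.ssr_motif == "A"
        assert e.length == 1 and e.polarity == "insertion"

    def test_private_nonrepetitive_gap_is_nr(self):
        ref = PAD_L + "ACGTC" + PAD_R
        alt = PAD_L + "-----" + PAD_R
        aln = _aln([ref, ref, ref, alt])
        events = call_indels(aln)
        assert len(events) == 1
        assert events[0].classification == "NR-indel"
        assert events[0].length == 5 and events[0].polarity == "deletion"
        assert events[0].taxa_with_gap == ("t4",) and events[0].is_private

    def test_even_split_polarity_unresolved(self):
        ref = PAD_L + "ACG" + PAD_R
        alt = PAD_L + "---" + PAD_R
        events = call_indels(_aln([ref, ref, alt, alt]))
        assert events[0].polarity == "unresolved"

    def test_adjacent_different_patterns_split(self):
        ref = PAD_L + "ACGT" + PAD_R
        r2 = PAD_L + "--GT" + PAD_R
        r3 = PAD_L + "AC--" + PAD_R
        events = call_indels(_aln([ref, r2, r3, ref]))
        assert len(events) == 2
        assert [e.length for e in events] == [2, 2]

    def test_matches_brute_force_oracle_on_random_alignments(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            L = int(rng.integers(20, 200))
            rows = []
            for _ in range(4):
                row = rng.choice(list("ACGT"), size=L)
                # paint a few gap runs
                for _ in range(int(rng.integers(0, 4))):
                    a = int(rng.integers(0, L))
                    b = min(L, a + int(rng.integers(1, 8)))
                    row[a:b] = "-"
                rows.append("".join(row))
            if all("-" in r for r in rows):  # keep at least one gap-free row
                rows[0] = rows[0].replace("-", "A")
            events = call_indels(_aln(rows))
            got = [
                (e.column_start, e.column_end, tuple(TAXA4.index(t) for t in e.taxa_with_gap))
                for e in events
            ]
            assert got == brute_force_gap_segmentation(rows)


class TestInversions:
    def _constructed(self):
        pre, post = "GGG" + PAD_L, PAD_R + "GGG"
        base = pre + "ACGTT" + "AATG" + "AACGT" + post
        flipped = pre + "ACGTT" + "CATT" + "AACGT" + post
        return _aln([base, base, base, flipped]), len(pre) + 5

    def test_constructed_inversion_detected(self):
        aln, seg_start = self._constructed()
        events, absorbed = call_inversions(aln)
        assert len(events) == 1
        e = events[0]
        assert e.length == 4 and e.flank_repeat_length == 5
        assert e.inverted_taxa == ("t4",)
        assert e.column_start == seg_start
        assert absorbed == set(range(seg_start, seg_start + 4))

    def test_absorbed_columns_removed_from_snps(self):
        aln, _ = self._constructed()
        snps, indels, invs = call_variants(aln)
        assert len(invs) == 1 and snps == [] and indels == []

    def test_non_complementary_difference_stays_snp(self):
        pre, post = "GGG" + PAD_L, PAD_R + "GGG"
        base = pre + "ACGTT" + "AATG" + "AACGT" + post
        other = pre + "ACGTT" + "CATG" + "AACGT" + post  # not a revcomp segment
        aln = _aln([base, base, base, other])
        snps, _, invs = call_variants(aln)
        assert invs == [] and len(snps) == 1

    def test_smaller_group_reported_inverted(self, quartet, quartet_alignment):
        events, _ = call_inversions(quartet_alignment)
        planted = [e for e in quartet.ledger.events if e["type"] == "inversion"]
        assert len(events) == len(planted)
        for ev, led in zip(
            sorted(events, key=lambda e: e.column_start),
            sorted(planted, key=lambda e: e["columns"][0]),
        ):
            assert ev.inverted_taxa == tuple(led["taxa"])
            assert ev.flank_repeat_length == led["flank"]


class TestPartitionAndSymmetry:
    def test_every_variable_column_attributed_once(self, quartet_alignment):
        aln = quartet_alignment
        snps, indels, invs = call_variants(aln)
        claimed = {}
        for s in snps:
            claimed[s.column] = claimed.get(s.column, 0) + 1
        for e in indels:
            for c in range(e.column_start, e.column_end):
                claimed[c] = claimed.get(c, 0) + 1
        for e in invs:
            for c in range(e.column_start, e.column_end):
                claimed[c] = claimed.get(c, 0) + 1
        assert all(v == 1 for v in claimed.values())
        M = aln.matrix
        variable = np.flatnonzero((M != M[0]).any(axis=0))
        # every variable column is claimed (inversion interiors may match)
        for col in variable:
            assert int(col) in claimed

    def test_spectrum_invariant_under_reverse_complement(self, quartet_alignment):
        aln = quartet_alignment
        rc = AlignmentSet(
            taxa=aln.taxa,
            rows=[revcomp(r) for r in aln.rows],
            reference_taxon=aln.reference_taxon,
        )
        s1, i1, v1 = call_variants(aln)
        s2, i2, v2 = call_variants(rc)
        ss1, ss2 = snp_summary(s1, aln), snp_summary(s2, rc)
        assert ss1["per_class"] == ss2["per_class"]
        assert sorted((e.length, e.classification) for e in i1) == sorted(
            (e.length, e.classification) for e in i2
        )
        assert sorted(e.length for e in v1) == sorted(e.length for e in v2)
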