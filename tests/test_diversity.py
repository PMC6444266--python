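"""Nucleotide diversity: the pairwise formula, windows, hotspots."""

import itertools
import math

import numpy as np
import pytest

from plastovar.diversity import (
    UndefinedDiversityError,
    nucleotide_diversity,
    sliding_profile,
)
from plastovar.variation import AlignmentSet


def brute_force_pi(rows):
    """All-pairs oracle: average proportion of differences at usable sites."""
    usable = [
        i
        for i in range(len(rows[0]))
        if all(r[i] not in "-N" for r in rows)
    ]
    if not usable:
        return None
    k = len(rows)
    total = 0.0
    for a, b in itertools.combinations(range(k), 2):
        total += sum(rows[a][i] != rows[b][i] for i in usable) / len(usable)
    return total / (k * (k - 1) / 2)


class TestPointEstimate:
    def test_one_difference_in_ten_sites(self):
        pi, L = nucleotide_diversity(["ACGTACGTAC", "ACGTACGTAT"])
        assert L == 10 and pi == pytest.approx(0.1)

    def test_identical_rows_zero(self):
        pi, _ = nucleotide_diversity(["ACGT"] * 4)
        assert pi == 0.0

    def test_no_usable_sites_is_signalled(self):
        with pytest.raises(UndefinedDiversityError):
            nucleotide_diversity(["A-", "-A"])

    def test_matches_brute_force_on_random_quartets(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            L = int(rng.integers(5, 60))
            rows = ["".join(rng.choice(list("ACGT-"), size=L, p=[0.23, 0.23, 0.23, 0.23, 0.08])) for _ in range(4)]
            expected = brute_force_pi(rows)
            if expected is None:
                with pytest.raises(UndefinedDiversityError):
                    nucleotide_diversity(rows)
            else:
                pi, _ = nucleotide_diversity(rows)
                assert pi == pytest.approx(expected)


def _aln(rows):
    return AlignmentSet(taxa=[f"t{i}" for i in range(len(rows))], rows=rows, reference_taxon="t0")


class TestSlidingProfile:
    def test_identical_sequences_all_zero_no_hotspots(self):
        rng = np.random.default_rng(3)
        row = "".join(rng.choice(list("ACGT"), size=2000))
        profile = sliding_profile(_aln([row] * 4))
        assert (profile.windows.pi == 0).all()
        assert profile.hotspots == [] and profile.mean_pi == 0.0

    def test_window_count_formula(self, quartet_alignment):
        for window, step in ((600, 100), (800, 100), (250, 50)):
            profile = sliding_profile(quartet_alignment, window=window, step=step, threshold=0.5)
            L = quartet_alignment.n_columns
            assert len(profile.windows) == (L - window) // step + 1

    def test_windows_match_brute_force(self, quartet_alignment):
        aln = quartet_alignment
        profile = sliding_profile(aln, window=600, step=100)
        rows = aln.rows
        for _, w in profile.windows.iloc[:25].iterrows():
            sub = [r[int(w.col_start) : int(w.col_end)] for r in rows]
            expected = brute_force_pi(sub)
            assert w.pi == pytest.approx(expected)

    def test_mean_pi_is_mean_of_defined_windows(self, quartet_alignment):
        profile = sliding_profile(quartet_alignment)
        defined = profile.windows.pi.dropna()
        assert profile.mean_pi == pytest.approx(float(np.mean(defined)))

    def test_adding_a_difference_never_decreases_window_pi(self):
        rng = np.random.default_rng(5)
        row = "".join(rng.choice(list("ACGT"), size=700))
        other = row[:350] + ("A" if row[350] != "A" else "C") + row[351:]
        base = sliding_profile(_aln([row, row, row, row]), window=600, step=100)
        bumped = sliding_profile(_aln([row, row, row, other]), window=600, step=100)
        assert (bumped.windows.pi >= base.windows.pi - 1e-12).all()

    def test_planted_block_yields_single_hotspot(self):
        rng = np.random.default_rng(7)
        row = "".join(rng.choice(list("ACGT"), size=4000))
        # one 600 bp block with a private difference every 40 bp: pi there
        # = 15 sites * 3 differing pairs / (6 pairs * 600 sites) = 0.0125
        alt = list(row)
        for pos in range(1700, 2300, 40):
            alt[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[alt[pos]]
        profile = sliding_profile(_aln([row, row, row, "".join(alt)]), threshold=0.01)
        assert len(profile.hotspots) == 1
        h = profile.hotspots[0]
        assert h.ref_start < 1700 + 600 and h.ref_end > 1700
        assert h.peak_pi > 0.01

    def test_oversized_window_collapses_to_single_window(self):
        rng = np.random.default_rng(9)
        row = "".join(rng.choice(list("ACGT"), size=300))
        with pytest.warns(UserWarning, match="window"):
            profile = sliding_profile(_aln([row] * 4), window=600)
        assert len(profile.windows) == 1

    def test_ir_windows_not_more_diverse_than_lsc(self, quartet, quartet_alignment, quartet_structure):
        """Qualitative check: the IR is quieter than the single-copy regions."""
        profile = sliding_profile(quartet_alignment, record=quartet.reference, structure=quartet_structure)
        regions = [
            quartet_structure.region_of(int(m) - 1) for m in profile.windows.midpoint_ref_1based
        ]
        pis = profile.windows.pi
        ir = [p for p, r in zip(pis, regions) if r == "IR" and not math.isnan(p)]
        lsc = [p for p, r in zip(pis, regions) if r == "LSC" and not math.isnan(p)]
        assert np.mean(ir) <= np.mean(lsc)
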