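"""Repeat counting: precise, broad (fault-tolerant) and the naive foil."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrtally.align import align_semiglobal
from ssrtally.panel import LocusDefinition, MotifSpec
from ssrtally.seqio import SequencingRead
from ssrtally.ssr import (
    NO_LEFT_ANCHOR,
    NO_RIGHT_ANCHOR,
    TYPED,
    UNTYPEABLE,
    broad_count,
    extract_region,
    locate_flanks,
    naive_scan,
    precise_count,
    project_region,
    type_read,
)


def broad_count_oracle(region, unit, max_sub_per_unit=1, max_total_sub=4, max_indel_events=2):
    """Independent brute-force enumeration of unit tilings.

    Explores every start offset whose opening window matches within
    tolerance and, recursively, every admissible continuation: a window
    within the substitution tolerance is consumed; only where a later
    window fails may the scan restart at a shift of up to len(unit)-1
    bases either way, if the landing window matches and the skipped
    stretch is the unit with one contiguous indel applied.  No
    memoization — plain exhaustive recursion.
    """
    m, n = len(unit), len(region)

    def ham(i):
        if i < 0 or i + m > n:
            return None
        return sum(a != b for a, b in zip(region[i : i + m], unit))

    def indel_unit(stretch):
        a = abs(len(stretch) - m)
        if len(stretch) < m:
            return any(unit[:k] + unit[k + a :] == stretch for k in range(m - a + 1))
        return any(
            stretch[:k] + stretch[k + a :] == unit for k in range(len(stretch) - a + 1)
        )

    def walk(i, subs, indels):
        d = ham(i)
        if d is None:
            return 0
        if d <= max_sub_per_unit and subs + d <= max_total_sub:
            return 1 + walk(i + m, subs + d, indels)
        best = 0
        if indels < max_indel_events:
            for shift in range(1, m):
                for s in (-shift, shift):
                    j = i + m + s
                    d2 = ham(j)
                    if (
                        d2 is not None
                        and d2 <= max_sub_per_unit
                        and subs + d2 <= max_total_sub
                        and indel_unit(region[i:j])
                    ):
                        best = max(best, 1 + walk(j, subs, indels + 1))
        return best

    if n < m:
        return 0
    starts = [
        i for i in range(n - m + 1) if ham(i) <= min(max_sub_per_unit, max_total_sub)
    ]
    return max((walk(i, 0, 0) for i in starts), default=0)


class TestPreciseCount:
    def test_pure_array(self):
        assert precise_count("ATC" * 8, "ATC") == 8

    def test_empty_region(self):
        assert precise_count("", "ATC") == 0

    def test_no_copy(self):
        assert precise_count("GGGGGG", "ATC") == 0

    def test_substitution_truncates_run(self):
        # SNP in the middle copy: runs of 2 and 2 remain
        region = "ATC" * 2 + "AGC" + "ATC" * 2
        assert precise_count(region, "ATC") == 2

    def test_run_at_interior_offset(self):
        assert precise_count("GG" + "ATC" * 3 + "TT", "ATC") == 3

    def test_interrupted_array_counts_longest_block(self):
        region = "CGCAT" * 3 + "CACAT" + "CGCAT" * 2
        assert precise_count(region, "CGCAT") == 3

    def test_self_similar_motif(self):
        assert precise_count("AGAGA" * 6, "AGAGA") == 6


class TestBroadCount:
    def test_pure_array_matches_precise(self):
        for unit, n in [("AT", 10), ("ATC", 8), ("AGAT", 7), ("AGAGA", 6)]:
            region = unit * n
            assert broad_count(region, unit) == precise_count(region, unit) == n

    def test_substitutions_tolerated_one_per_unit(self):
        region = "ATC" * 2 + "AGC" + "ATC" * 2
        assert broad_count(region, "ATC") == 5

    def test_interrupted_array_counts_all_units(self):
        region = "CGCAT" * 3 + "CACAT" + "CGCAT" * 2
        assert broad_count(region, "CGCAT") == 6

    def test_five_copies_two_substituted(self):
        region = "AAGCC" + "CAGCC" + "CATCC" + "CAGCC" + "CAGCC"
        assert precise_count(region, "CAGCC") == 2
        assert broad_count(region, "CAGCC") == 5

    def test_two_subs_in_one_unit_break_it(self):
        region = "ATC" * 2 + "GGC" + "ATC" * 2
        # middle unit carries 2 substitutions: over the per-unit budget
        assert broad_count(region, "ATC") < 5

    def test_total_substitution_budget(self):
        # six units each carrying one SNP: any tiling of five or more units
        # needs five substitutions, over the regional budget of four
        mutated = "AACG" * 6
        assert broad_count("ATCG" * 6, "ATCG") == 6
        assert broad_count(mutated, "ATCG") == 4

    def test_substitution_budget_knobs(self):
        region = "CGCAT" * 3 + "CACAT" + "CGCAT" * 2
        assert broad_count(region, "CGCAT", max_sub_per_unit=0) == 3
        assert broad_count(region, "CGCAT", max_total_sub=0) == 3
        # a clean array is unaffected by zero substitution budgets
        assert broad_count("CGCAT" * 6, "CGCAT", max_sub_per_unit=0, max_total_sub=0) == 6

    def test_resynchronizes_across_deletion(self):
        region = "ACGTG" + "ACTG" + "ACGTC"  # middle unit lost one base
        assert precise_count(region, "ACGTG") == 1
        assert broad_count(region, "ACGTG") == 3

    def test_resynchronizes_across_insertion(self):
        # one foreign base between units: the stretch holding the insertion
        # still counts as a single unit
        region = "ATC" * 2 + "G" + "ATC" * 3
        assert precise_count(region, "ATC") == 3
        assert broad_count(region, "ATC") == 5

    def test_indel_event_budget(self):
        one_del = "ACGTG" + "ACTG" + "ACGTC"
        assert broad_count(one_del, "ACGTG", max_indel_events=0) == 1
        two_del = "ACGTG" + "ACTG" + "ACGTG" + "ACTG" + "ACGTG"
        assert broad_count(two_del, "ACGTG", max_indel_events=0) == 1
        assert broad_count(two_del, "ACGTG", max_indel_events=1) == 3
        assert broad_count(two_del, "ACGTG", max_indel_events=2) == 5

    def test_leading_junk_gains_no_unit(self):
        # bases before the array must not be counted as an indel-carrying
        # unit: the scan has to open on a matching window
        region = "G" + "ATC" * 4
        assert broad_count(region, "ATC") == 4

    def test_no_overcount_on_self_similar_motif_with_snp(self):
        # a perfect-window match must be consumed, not reinterpreted as a
        # shorter deletion-bearing unit
        region = "AGAGA" * 3 + "AGCGA" + "AGAGA" * 2
        assert broad_count(region, "AGAGA") == 6

    def test_region_shorter_than_motif(self):
        assert broad_count("AT", "ATC") == 0

    def test_run_preceded_by_junk(self):
        region = "GGGGGGGGGG" + "ATC" * 4
        assert broad_count(region, "ATC") >= precise_count(region, "ATC") == 4

    def test_matches_bruteforce_oracle_on_seeded_sample(self):
        rng = np.random.default_rng(20260206)
        units = ["AT", "ATC", "AGAT", "CGCAT", "AGAGA"]
        for _ in range(400):
            unit = units[rng.integers(0, len(units))]
            if rng.random() < 0.5:
                region = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(0, 26)))
            else:
                region = unit * int(rng.integers(1, 7))
                region = "".join(
                    c if rng.random() > 0.15 else "ACGT"[rng.integers(0, 4)] for c in region
                )
            assert broad_count(region, unit) == broad_count_oracle(region, unit), (
                region,
                unit,
            )

    @given(
        st.sampled_from(["AT", "ATC", "AGAT", "AGAGA"]),
        st.text(alphabet="ACGT", max_size=24),
    )
    @settings(deadline=None, max_examples=120)
    def test_invariants(self, unit, region):
        b = broad_count(region, unit)
        p = precise_count(region, unit)
        m = len(unit)
        assert b >= p
        assert p <= len(region) // m
        # each indel event shifts by at most m-1 bases
        assert b * m <= len(region) + 2 * (m - 1)


class TestFlankAnchors:
    def test_exact_read(self, cagcc_locus, seq1):
        anchors = locate_flanks(seq1, cagcc_locus)
        assert anchors.left_end == cagcc_locus.ssr_start
        assert anchors.right_start == cagcc_locus.ssr_end
        assert anchors.left_mismatches == anchors.right_mismatches == 0
        assert extract_region(seq1, anchors) == "CAGCC" * 3

    def test_tolerates_flank_snp(self, cagcc_locus, seq3):
        anchors = locate_flanks(seq3, cagcc_locus)
        assert anchors.right_start == cagcc_locus.ssr_end
        assert anchors.right_mismatches == 1

    def test_read_with_padding(self, cagcc_locus, seq1):
        read = "TTTTTTT" + seq1 + "AAAAAAA"
        anchors = locate_flanks(read, cagcc_locus)
        assert anchors.left_end == 7 + cagcc_locus.ssr_start
        assert extract_region(read, anchors) == "CAGCC" * 3

    def test_missing_left_flank(self, cagcc_locus):
        read = "CAGCC" * 3 + cagcc_locus.flank_right
        assert locate_flanks(read, cagcc_locus) == NO_LEFT_ANCHOR

    def test_missing_right_flank(self, cagcc_locus):
        read = cagcc_locus.flank_left + "CAGCC" * 3
        assert locate_flanks(read, cagcc_locus) == NO_RIGHT_ANCHOR

    def test_mismatch_budget(self, cagcc_locus, seq1):
        # three substitutions in the left anchor exceed max_mismatch=2
        flank = cagcc_locus.flank_left
        mutated = "".join(
            ("T" if c in "AGC" else "G") if i in (0, 7, 14) else c
            for i, c in enumerate(flank)
        )
        read = mutated + seq1[cagcc_locus.ssr_start :]
        assert locate_flanks(read, cagcc_locus) == NO_LEFT_ANCHOR


class TestProjection:
    def test_exact_read_projects_reference_region(self, cagcc_locus, seq1):
        aln = align_semiglobal(seq1, cagcc_locus.ref_seq)
        assert project_region(seq1, cagcc_locus, aln) == "CAGCC" * 3

    def test_flank_indel_does_not_move_boundaries(self, cagcc_locus):
        ref = cagcc_locus.ref_seq
        # delete 2 bases mid left flank
        read = ref[:10] + ref[12:]
        aln = align_semiglobal(read, ref)
        assert project_region(read, cagcc_locus, aln) == "CAGCC" * 3

    def test_insertion_in_region_extends_it(self, cagcc_locus):
        ref = cagcc_locus.ref_seq
        read = ref[: cagcc_locus.ssr_start] + "CAGCC" * 4 + ref[cagcc_locus.ssr_end :]
        aln = align_semiglobal(read, ref)
        assert project_region(read, cagcc_locus, aln) == "CAGCC" * 4

    def test_deletion_in_region_shrinks_it(self, cagcc_locus):
        ref = cagcc_locus.ref_seq
        read = ref[: cagcc_locus.ssr_start] + "CAGCC" * 2 + ref[cagcc_locus.ssr_end :]
        aln = align_semiglobal(read, ref)
        assert project_region(read, cagcc_locus, aln) == "CAGCC" * 2

    def test_alignment_not_covering_region_returns_none(self, cagcc_locus):
        ref = cagcc_locus.ref_seq
        read = ref[:25]  # stops inside the array
        aln = align_semiglobal(read, ref)
        assert project_region(read, cagcc_locus, aln) is None


class TestTypeRead:
    def _read(self, seq):
        return SequencingRead("r", seq, (40,) * len(seq), "forward")

    def test_precise_on_exact_read(self, cagcc_locus, seq1):
        t = type_read(self._read(seq1), cagcc_locus, "precise")
        assert t.status == TYPED and t.repeat_count == 3

    def test_broad_on_exact_read(self, cagcc_locus, seq1):
        t = type_read(self._read(seq1), cagcc_locus, "broad")
        assert t.status == TYPED and t.repeat_count == 3

    def test_ssr_snp_precise_vs_broad(self, cagcc_locus, seq2):
        # one substitution inside the first copy: exact-run counting drops
        # to 2, fault-tolerant counting keeps all 3 units
        assert type_read(self._read(seq2), cagcc_locus, "precise").repeat_count == 2
        assert type_read(self._read(seq2), cagcc_locus, "broad").repeat_count == 3

    def test_flank_snp_naive_overcounts_boundaries_do_not(self, cagcc_locus, seq3):
        # a flank SNP creates a spurious motif copy: the naive whole-read
        # scan sees 4 copies, boundary-based counting still reports 3
        assert naive_scan(seq3, cagcc_locus.motif) == 4
        assert naive_scan(cagcc_locus.ref_seq, cagcc_locus.motif) == 3
        assert type_read(self._read(seq3), cagcc_locus, "precise").repeat_count == 3
        assert type_read(self._read(seq3), cagcc_locus, "broad").repeat_count == 3

    def test_zero_units_is_untypeable(self, cagcc_locus):
        read = self._read(cagcc_locus.flank_left + "GTGTGTG" + cagcc_locus.flank_right)
        t = type_read(read, cagcc_locus, "precise")
        assert t.status == UNTYPEABLE and t.repeat_count == 0

    def test_unknown_algorithm_rejected(self, cagcc_locus, seq1):
        with pytest.raises(ValueError):
            type_read(self._read(seq1), cagcc_locus, "fuzzy")
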