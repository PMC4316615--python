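import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retrochron.io import Sequence, TECopyAnnotation
from retrochron.markers import (
    LocusAlignment,
    Marker,
    State,
    build_marker_matrix,
    count_branch_support,
    marker_from_calls,
    perfect_phylogeny_exists,
    score_presence_absence,
    select_candidate_loci,
    waddell_test,
)
from retrochron.simulate import emit_locus_alignments
from retrochron.trees import read_newick


class TestWaddell:
    @pytest.mark.parametrize("k", range(1, 11))
    def test_conflict_free_closed_form(self, k):
        """For (k,0,0) the test reduces to p = 3^-k exactly."""
        lam, p = waddell_test(k, 0, 0)
        assert lam == pytest.approx(2 * k * math.log(3))
        assert p == pytest.approx(3.0 ** -k, rel=1e-9)

    def test_three_insertions_rule(self):
        # the operational significance threshold: 3 clean markers
        p3 = waddell_test(3, 0, 0)[1]
        p2 = waddell_test(2, 0, 0)[1]
        assert p3 == pytest.approx(1 / 27)
        assert p3 < 0.05
        assert p2 == pytest.approx(1 / 9)
        assert p2 >= 0.05

    def test_null_identical_counts(self):
        assert waddell_test(1, 1, 1) == (0.0, 1.0)

    def test_zero_counts_convention(self):
        assert waddell_test(0, 0, 0) == (0.0, 1.0)

    def test_exact_enumeration_agrees_for_clean_patterns(self):
        # for (k,0,0) the exact multinomial tail equals 3^-k as well
        for k in (1, 2, 3, 4):
            _, p = waddell_test(k, 0, 0, exact=True)
            assert p == pytest.approx(3.0 ** -k, rel=1e-9)

    def test_exact_vs_chi2_mixed_counts(self):
        lam_a, p_chi = waddell_test(5, 1, 0)
        lam_b, p_ex = waddell_test(5, 1, 0, exact=True)
        assert lam_a == lam_b
        assert 0 < p_ex < 1
        # the chi-square approximation should be in the same regime
        assert abs(math.log10(p_ex) - math.log10(p_chi)) < 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 30))
    def test_p_strictly_decreasing_in_clean_k(self, k):
        assert waddell_test(k + 1, 0, 0)[1] < waddell_test(k, 0, 0)[1]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            waddell_test(-1, 0, 0)


def _locus(rows, span, tsd=None, meta=None):
    return LocusAlignment(
        locus_id="L",
        rows=rows,
        element_span=span,
        subfamily="CR1-7",
        orientation="+",
        tsd_columns=tsd,
        taxon_meta=meta or {},
    )


class TestScoring:
    FLANK_L = "ACGTACGTAC"
    FLANK_R = "TTGGCCAATT"
    ELEM = "GGGGCCCCGGGGCCCC"

    def rows(self):
        present = self.FLANK_L + self.ELEM + self.FLANK_R
        absent = self.FLANK_L + "-" * len(self.ELEM) + self.FLANK_R
        return present, absent

    def test_present_and_absent(self):
        present, absent = self.rows()
        calls = score_presence_absence(
            _locus({"t1": present, "t2": absent}, (10, 26))
        )
        assert {c.taxon: c.state for c in calls} == {
            "t1": State.PRESENT, "t2": State.ABSENT,
        }

    def test_different_subfamily_is_ambiguous_subtype(self):
        present, absent = self.rows()
        calls = score_presence_absence(
            _locus(
                {"t1": present, "t2": present, "t3": absent},
                (10, 26),
                meta={"t2": {"subfamily": "CR1-2"}},
            )
        )
        by = {c.taxon: c for c in calls}
        assert by["t2"].state == State.AMBIGUOUS
        assert "subtype_mismatch" in by["t2"].reasons
        assert by["t1"].state == State.PRESENT

    def test_opposite_orientation_is_ambiguous(self):
        present, absent = self.rows()
        calls = score_presence_absence(
            _locus(
                {"t1": present, "t2": present, "t3": absent},
                (10, 26),
                meta={"t2": {"orientation": "-"}},
            )
        )
        by = {c.taxon: c for c in calls}
        assert by["t2"].state == State.AMBIGUOUS
        assert "orientation_mismatch" in by["t2"].reasons

    def test_all_gap_row_is_missing_data_not_error(self):
        present, _ = self.rows()
        calls = score_presence_absence(
            _locus({"t1": present, "t2": "-" * len(present)}, (10, 26))
        )
        by = {c.taxon: c for c in calls}
        assert by["t2"].state == State.AMBIGUOUS
        assert by["t2"].reasons == ["missing_data"]

    def test_partial_element_is_ambiguous(self):
        present, _ = self.rows()
        partial = self.FLANK_L + self.ELEM[:6] + "-" * 10 + self.FLANK_R
        calls = score_presence_absence(
            _locus({"t1": present, "t2": partial}, (10, 26))
        )
        by = {c.taxon: c for c in calls}
        assert by["t2"].state == State.AMBIGUOUS
        assert "partial_element" in by["t2"].reasons

    def test_missing_tsd_placement_is_ambiguous(self):
        present, absent = self.rows()
        # t2 has the element but a deleted left-TSD placement
        damaged = "--" + self.FLANK_L[2:] + self.ELEM + self.FLANK_R
        calls = score_presence_absence(
            _locus(
                {"t1": present, "t2": damaged, "t3": absent},
                (10, 26),
                tsd=([0, 1], [26, 27]),
            )
        )
        by = {c.taxon: c for c in calls}
        assert by["t1"].state == State.PRESENT
        assert by["t2"].state == State.AMBIGUOUS
        assert "tsd_mismatch" in by["t2"].reasons


class TestMatrix:
    def _marker(self, lid, present, absent):
        calls = {t: State.PRESENT for t in present}
        calls.update({t: State.ABSENT for t in absent})
        return Marker(locus_id=lid, calls=calls)

    def test_nested_sets_compatible(self):
        m1 = self._marker("m1", {"A", "B"}, {"C", "D"})
        m2 = self._marker("m2", {"A", "B", "C"}, {"D"})
        assert build_marker_matrix([m1, m2]).conflicts == []

    def test_disjoint_sets_compatible(self):
        m1 = self._marker("m1", {"A", "B"}, {"C", "D"})
        m2 = self._marker("m2", {"C", "D"}, {"A", "B"})
        assert build_marker_matrix([m1, m2]).conflicts == []

    def test_overlapping_sets_conflict(self):
        m1 = self._marker("m1", {"A", "B"}, {"C", "D"})
        m2 = self._marker("m2", {"B", "C"}, {"A", "D"})
        matrix = build_marker_matrix([m1, m2])
        assert matrix.conflicts == [("m1", "m2")]
        assert not perfect_phylogeny_exists(matrix)

    def test_uninformative_markers_dropped(self):
        m1 = self._marker("m1", {"A", "B"}, {"C"})
        m2 = self._marker("m2", {"A", "B", "C"}, set())
        matrix = build_marker_matrix([m1, m2])
        assert [m.locus_id for m in matrix.markers] == ["m1"]


def test_candidate_loci_match_bruteforce_oracle(small_sim):
    """Flank-clean locus selection equals a quadratic interval-overlap scan."""
    taxon = small_sim.taxon_names[0]
    genome = small_sim.genome(taxon)
    annos = small_sim.annotations(taxon)
    flank = 300
    report = select_candidate_loci(annos, genome, flank=flank)
    expected = []
    for a in annos:
        lo, hi = a.start - flank, a.end + flank
        if lo < 0 or hi > len(genome):
            continue
        clash = any(
            o is not a and o.start < hi and lo < o.end
            and not (a.start <= o.start and o.end <= a.end)
            for o in annos
        )
        if not clash:
            expected.append(a)
    assert report.candidates == expected
    assert expected, "oracle should retain some loci"


def test_copy_with_close_neighbor_excluded():
    genome = Sequence("g", "ACGT" * 500)
    annos = [
        TECopyAnnotation("g", 800, 900, "S", "f1", "+"),
        TECopyAnnotation("g", 1000, 1100, "S", "f2", "+"),
    ]
    report = select_candidate_loci(annos, genome, flank=750)
    assert report.candidates == []
    assert report.excluded_flank_te + report.excluded_edge == 2


class TestSimulatedPipeline:
    def _markers(self, sim, flank=300):
        markers = []
        loci = []
        for locus in emit_locus_alignments(sim, flank=flank):
            if not locus.intact or locus.clipped:
                continue
            la = LocusAlignment(
                locus_id=locus.locus_id,
                rows=locus.rows,
                element_span=locus.element_span,
                subfamily=locus.subfamily,
                orientation=locus.orientation,
                tsd_columns=locus.tsd_columns,
            )
            markers.append(marker_from_calls(la, score_presence_absence(la)))
            loci.append(locus)
        return markers, loci

    def test_calls_match_truth_on_intact_loci(self, small_sim):
        markers, loci = self._markers(small_sim)
        assert len(markers) >= 10
        for m, locus in zip(markers, loci):
            for taxon, state in m.calls.items():
                truth = (
                    State.PRESENT if taxon in locus.present_taxa else State.ABSENT
                )
                assert state == truth, (m.locus_id, taxon)

    def test_no_conflicts_without_losses(self, small_sim):
        markers, _ = self._markers(small_sim)
        matrix = build_marker_matrix(markers)
        assert matrix.conflicts == []
        assert perfect_phylogeny_exists(matrix)

    def test_markers_map_to_their_true_branches(self, small_sim):
        markers, loci = self._markers(small_sim)
        matrix = build_marker_matrix(markers)
        report = count_branch_support(matrix, small_sim.config.host_tree)
        assert report.unassigned == []
        truth_branch = {
            f"locus_ins{r.insertion_id}": r.branch
            for r in small_sim.registry.insertions.values()
        }
        supported = {
            lid: b.branch for b in report.branches for lid in b.supporting
        }
        for lid, branch in supported.items():
            assert truth_branch[lid] == branch
        # non-autapomorphic informative markers all land somewhere
        expected = {
            m.locus_id for m in matrix.markers if len(m.present_set) > 1
        }
        assert expected == set(supported)


def test_branch_support_example():
    tree = read_newick("((A,(B,C)BC)ABC,D)Root;")
    def mk(lid, present):
        calls = {t: State.PRESENT if t in present else State.ABSENT
                 for t in "ABCD"}
        return Marker(locus_id=lid, calls=calls)

    markers = [mk("m1", "ABC"), mk("m2", "ABC"), mk("m3", "ABC"),
               mk("m4", "BC"), mk("m5", "A")]
    matrix = build_marker_matrix(markers)
    report = count_branch_support(matrix, read_newick("((A,(B,C)BC)ABC,D)Root;"))
    by = {b.branch: b for b in report.branches}
    assert by["ABC"].k_support == 3
    assert by["ABC"].p_value == pytest.approx(1 / 27)
    assert by["BC"].k_support == 1
    assert report.autapomorphies == ["m5"]
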