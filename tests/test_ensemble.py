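"""Cross-tool aggregation: global groups, locals, best common motif."""

import numpy as np
import pytest

from motifcmp import (
    ComparisonConfig,
    GlobalGroup,
    align_motifs,
    build_report,
    find_global_significant,
    find_local_significant,
    select_best_common,
    top_n,
)

from conftest import make_random_motif, point_mass_motif


def shared_and_unique_fixture(rng=None):
    """Three tools, one shared motif (>=75% across all) plus one unique
    point-mass motif per tool."""
    rng = rng or np.random.default_rng(42)
    shared = make_random_motif(rng, "shared_A", tool="toolA", width=8)
    lists = {"toolA": [shared]}
    for tool, uniq in [("toolB", "CCCCCCCC"), ("toolC", "GGGGGGGG")]:
        copy = make_random_motif(rng, f"shared_{tool[-1]}", tool=tool, width=8)
        copy.counts = shared.counts.copy()
        lists[tool] = [copy]
    lists["toolA"].append(point_mass_motif("uniq_A", "ATATATAT", tool="toolA"))
    lists["toolB"].append(point_mass_motif("uniq_B", "CCCCCCCC", tool="toolB"))
    lists["toolC"].append(point_mass_motif("uniq_C", "GGGGGGGG", tool="toolC"))
    return lists


class TestFindGlobalSignificant:
    def test_identical_motif_in_two_tools_forms_one_group(self):
        rng = np.random.default_rng(0)
        m = make_random_motif(rng, "m", tool="A", width=8)
        twin = make_random_motif(rng, "m2", tool="B", width=8)
        twin.counts = m.counts.copy()
        groups = find_global_significant({"A": [m], "B": [twin]})
        assert len(groups) == 1
        g = groups[0]
        assert g.support == 2
        assert g.members["B"][1] == pytest.approx(100.0)
        assert g.members["A"][1] == pytest.approx(100.0)

    def test_tool_without_counterpart_blocks_anchor(self):
        # toolC's motifs share nothing with the candidate anchor
        rng = np.random.default_rng(1)
        m = make_random_motif(rng, "m", tool="A", width=8)
        twin = make_random_motif(rng, "twin", tool="B", width=8)
        twin.counts = m.counts.copy()
        lists = {
            "A": [m],
            "B": [twin],
            "C": [point_mass_motif("far", "CGCGCGCG", tool="C")],
        }
        # brute-force check the fixture really is below cutoff for C
        assert align_motifs(m, lists["C"][0]).score_percent < 75
        assert find_global_significant(lists) == []

    def test_empty_tool_list_gives_zero_groups(self):
        rng = np.random.default_rng(2)
        lists = {"A": [make_random_motif(rng, "m", tool="A")], "B": []}
        assert find_global_significant(lists) == []

    def test_fewer_than_two_tools_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="two tools"):
            find_global_significant({"A": [make_random_motif(rng, "m")]})

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(4)
        lists = {
            tool: [make_random_motif(rng, f"{tool}{i}", tool=tool) for i in range(3)]
            for tool in ("A", "B", "C")
        }
        counts = [
            len(find_global_significant(lists, ComparisonConfig(cutoff_percent=c)))
            for c in (60, 70, 80, 90, 95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_duplicate_groups_collapsed(self):
        rng = np.random.default_rng(5)
        m = make_random_motif(rng, "m", tool="A", width=8)
        twin = make_random_motif(rng, "twin", tool="B", width=8)
        twin.counts = m.counts.copy()
        # both anchors produce the identical member set -> one group kept
        groups = find_global_significant({"A": [m], "B": [twin]})
        assert len(groups) == 1
        assert groups[0].anchor.tool == "A"  # first in tool-label order


class TestFindLocalSignificant:
    def test_all_shared_means_no_locals(self):
        rng = np.random.default_rng(6)
        m = make_random_motif(rng, "m", tool="A", width=8)
        twin = make_random_motif(rng, "m", tool="B", width=8)
        twin.counts = m.counts.copy()
        lists = {"A": [m], "B": [twin]}
        groups = find_global_significant(lists)
        locals_ = find_local_significant(lists, groups)
        assert all(v == [] for v in locals_.values())

    def test_disjoint_tools_keep_everything_local(self):
        lists = {
            "A": [point_mass_motif("a", "AAAAAA", tool="A")],
            "B": [point_mass_motif("b", "CCCCCC", tool="B")],
        }
        groups = find_global_significant(lists)
        assert groups == []
        locals_ = find_local_significant(lists, groups)
        assert locals_ == {"A": lists["A"], "B": lists["B"]}

    def test_mixed_fixture_locals_are_exactly_the_uniques(self):
        lists = shared_and_unique_fixture()
        report = build_report(lists)
        assert len(report.global_groups) == 1
        locals_ = report.local_by_tool
        assert {m.id for ms in locals_.values() for m in ms} == {
            "uniq_A",
            "uniq_B",
            "uniq_C",
        }

    def test_partition_property(self):
        """Group members+anchors and locals partition each tool's list."""
        rng = np.random.default_rng(7)
        lists = {
            tool: [make_random_motif(rng, f"{tool}{i}", tool=tool) for i in range(4)]
            for tool in ("A", "B")
        }
        groups = find_global_significant(lists)
        locals_ = find_local_significant(lists, groups)
        grouped = {
            (tool, m.id) for g in groups for tool, (m, _) in g.members.items()
        }
        for tool, motifs in lists.items():
            local_ids = {(tool, m.id) for m in locals_[tool]}
            all_ids = {(tool, m.id) for m in motifs}
            assert grouped.union(local_ids) >= all_ids
            assert not (grouped & local_ids)


class TestSelectBestCommon:
    def _group(self, anchor_id, support, scores):
        rng = np.random.default_rng(hash(anchor_id) % 2**31)
        anchor = make_random_motif(rng, anchor_id, tool="t0")
        members = {"t0": (anchor, 100.0)}
        for i, s in enumerate(scores, 1):
            members[f"t{i}"] = (make_random_motif(rng, f"{anchor_id}_{i}"), s)
        assert len(members) == support
        return GlobalGroup(anchor=anchor, members=members)

    def test_majority_beats_score(self):
        weak_big = self._group("big", 4, [76.0, 76.0, 76.0])
        strong_small = self._group("small", 3, [99.0, 99.0])
        assert select_best_common([strong_small, weak_big]) is weak_big

    def test_equal_support_decided_by_mean_score(self):
        lo = self._group("lo", 3, [88.0, 88.0])
        hi = self._group("hi", 3, [92.0, 92.0])
        assert select_best_common([lo, hi]) is hi

    def test_empty_gives_none(self):
        assert select_best_common([]) is None

    def test_permutation_invariant(self):
        groups = [
            self._group("g1", 3, [80.0, 90.0]),
            self._group("g2", 4, [76.0, 77.0, 78.0]),
            self._group("g3", 3, [95.0, 96.0]),
        ]
        winners = {
            select_best_common(perm).anchor.id
            for perm in (
                groups,
                groups[::-1],
                [groups[1], groups[2], groups[0]],
            )
        }
        assert winners == {"g2"}

    def test_ordering_matches_exhaustive_sort(self):
        groups = [
            self._group(f"g{i}", s, list(sc))
            for i, (s, sc) in enumerate(
                [(3, (80, 81)), (4, (76, 75, 77)), (3, (95, 60)),
                 (4, (90, 91, 92)), (2, (100,))]
            )
        ]
        expected = sorted(
            groups,
            key=lambda g: (-g.support, -g.mean_member_score(), g.anchor.id),
        )[0]
        assert select_best_common(groups) is expected


class TestTopN:
    def test_whole_list_when_n_large(self):
        rng = np.random.default_rng(8)
        motifs = [make_random_motif(rng, f"m{i}") for i in range(3)]
        assert top_n(motifs, 10) == motifs

    def test_evalue_ranking(self):
        rng = np.random.default_rng(9)
        motifs = [
            make_random_motif(rng, mid, significance_value=v,
                              significance_kind="e_value")
            for mid, v in [("a", 0.2), ("b", 0.001), ("c", 0.04)]
        ]
        assert [m.id for m in top_n(motifs, 2)] == ["b", "c"]

    def test_unranked_motifs_keep_input_order(self):
        rng = np.random.default_rng(10)
        motifs = [make_random_motif(rng, f"m{i}") for i in range(5)]
        assert [m.id for m in top_n(motifs, 3)] == ["m0", "m1", "m2"]

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            top_n([], 0)
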