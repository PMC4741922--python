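"""Windowed matching, rescue/look-up, and similarity statistics."""

import numpy as np
import pytest

from svconcord.compare import (
    MatchWindow,
    PairComparison,
    breakpoints_match,
    classify_pair,
    combined_similarity,
    directional_similarity,
    gained_lost,
    lookup,
    match_catalogues,
    rescue,
    round_half_away,
    similarity_stats,
)
from svconcord.model import EvidenceIndex

from .conftest import make_event

W = MatchWindow(500)


class TestBreakpointsMatch:
    def test_identical_and_boundary(self):
        a = make_event("chr1", 10_000, "chr2", 20_000)
        assert breakpoints_match(a, make_event("chr1", 10_000, "chr2", 20_000), W)
        assert breakpoints_match(a, make_event("chr1", 10_500, "chr2", 19_500), W)
        assert not breakpoints_match(a, make_event("chr1", 10_000, "chr2", 20_501), W)

    def test_chromosome_pair_must_agree(self):
        a = make_event("chr1", 10_000, "chr2", 20_000)
        b = make_event("chr1", 10_000, "chr3", 20_000)
        assert not breakpoints_match(a, b, W)

    def test_sv_type_label_ignored(self):
        a = make_event("chr1", 10_000, "chr1", 60_000, "DEL")
        b = make_event("chr1", 10_000, "chr1", 60_000, "ITX")
        assert breakpoints_match(a, b, W)


class TestMatchCatalogues:
    def test_nearest_candidate_wins(self):
        a = [make_event("chr1", 10_000, "chr1", 60_000)]
        b = [
            make_event("chr1", 10_400, "chr1", 60_000),  # summed distance 400
            make_event("chr1", 10_005, "chr1", 60_005),  # summed distance 10
        ]
        assert match_catalogues(a, b, W) == [(0, 1)]

    def test_disjoint_catalogues(self):
        a = [make_event("chr1", 10_000)]
        b = [make_event("chr2", 10_000)]
        assert match_catalogues(a, b, W) == []

    def test_equal_distance_tie_prefers_lower_coordinate(self):
        a = [make_event("chr1", 10_000, "chr1", 60_000)]
        b = [
            make_event("chr1", 10_100, "chr1", 60_000),
            make_event("chr1", 9_900, "chr1", 60_000),
        ]
        assert match_catalogues(a, b, W) == [(0, 1)]  # b[1] has lower left pos

    def test_one_to_one(self):
        a = [make_event("chr1", 10_000), make_event("chr1", 10_050)]
        b = [make_event("chr1", 10_010)]
        matching = match_catalogues(a, b, W)
        assert matching == [(0, 0)]


class TestRescueLookup:
    def test_rescue_on_subthreshold_raw_call(self):
        ev = make_event("chr1", 10_000, "chr1", 60_000)
        raw = [make_event("chr1", 10_100, "chr1", 60_100, support=2)]
        rescued, remaining = rescue([ev], raw, W)
        assert [r[0] for r in rescued] == [ev] and remaining == []

    def test_rescue_respects_window(self):
        ev = make_event("chr1", 10_000, "chr1", 60_000)
        raw = [make_event("chr1", 10_600, "chr1", 60_000, support=2)]
        rescued, remaining = rescue([ev], raw, W)
        assert rescued == [] and remaining == [ev]

    def test_rescue_empty_raw_list(self):
        ev = make_event("chr1", 10_000)
        assert rescue([ev], [], W) == ([], [ev])

    def test_lookup_single_read_pair_suffices(self, genome):
        ev = make_event("chr1", 10_000, "chr2", 20_000)
        idx = EvidenceIndex(genome)
        idx.add("chr1", 10_200, "chr2", 19_900)
        found, remaining = lookup([ev], idx, W)
        assert [f[0] for f in found] == [ev] and found[0][1] == 1

    def test_lookup_needs_both_ends(self, genome):
        ev = make_event("chr1", 10_000, "chr2", 20_000)
        idx = EvidenceIndex(genome)
        idx.add("chr1", 10_200, "chr2", 30_000)  # right mate far away
        found, remaining = lookup([ev], idx, W)
        assert found == [] and remaining == [ev]

    def test_lookup_empty_evidence(self, genome):
        ev = make_event("chr1", 10_000)
        assert lookup([ev], EvidenceIndex(genome), W) == ([], [ev])


class TestClassifyPair:
    def test_identical_catalogues_all_shared(self):
        cat = [make_event("chr1", 10_000), make_event("chr2", 30_000, "chr3", 40_000)]
        pc = classify_pair(cat, list(cat), w=W)
        assert pc.n_shared == 2 and not pc.specific_a and not pc.specific_b

    def test_disjoint_catalogues_all_specific(self):
        a = [make_event("chr1", 10_000)]
        b = [make_event("chr2", 10_000)]
        pc = classify_pair(a, b, w=W)
        assert pc.n_shared == 0
        assert pc.total_a == 1 and pc.total_b == 1

    def test_lookup_only_event_shared_with_provenance(self, genome):
        a = [make_event("chr1", 10_000, "chr2", 20_000)]
        ev_b = EvidenceIndex(genome)
        ev_b.add("chr1", 10_050, "chr2", 20_050)
        pc = classify_pair(a, [], ev_b=ev_b, w=W)
        assert pc.n_shared == 1
        assert pc.shared_pairs[0].provenance == "looked_up"
        assert pc.total_a == 1 and pc.total_b == 1  # shared counts in both totals

    def test_rescue_then_lookup_order(self, genome):
        # raw match takes precedence over evidence-only match
        a = [make_event("chr1", 10_000, "chr2", 20_000)]
        raw_b = [make_event("chr1", 10_100, "chr2", 20_000, support=2)]
        ev_b = EvidenceIndex(genome)
        ev_b.add("chr1", 10_000, "chr2", 20_000)
        pc = classify_pair(a, [], raw_b=raw_b, ev_b=ev_b, w=W)
        assert pc.shared_pairs[0].provenance == "rescued"

    def test_ledger_invariant(self):
        a = [make_event("chr1", p) for p in (10_000, 200_000, 300_000)]
        b = [make_event("chr1", 10_100), make_event("chr2", 50_000)]
        pc = classify_pair(a, b, w=W)
        assert pc.total_a == pc.n_shared + len(pc.specific_a)
        assert pc.total_b == pc.n_shared + len(pc.specific_b)

    def test_shared_count_symmetric(self):
        rng = np.random.default_rng(7)
        a = [make_event("chr1", int(p)) for p in rng.integers(0, 5_000_000, 40)]
        b = [make_event("chr1", int(p) + int(j)) for p, j in
             zip(rng.integers(0, 5_000_000, 40), rng.integers(-400, 400, 40))]
        pc_ab = classify_pair(a, b, w=W)
        pc_ba = classify_pair(b, a, w=W)
        assert pc_ab.n_shared == pc_ba.n_shared

    def test_window_monotonicity(self):
        rng = np.random.default_rng(11)
        a = [make_event("chr1", int(p)) for p in rng.integers(0, 2_000_000, 30)]
        b = [make_event("chr1", int(p)) for p in rng.integers(0, 2_000_000, 30)]
        previous = 0
        for hw in (0, 100, 500, 2000):
            n = classify_pair(a, b, w=MatchWindow(hw)).n_shared
            assert n >= previous
            previous = n


class TestSimilarityStats:
    @pytest.mark.parametrize(
        "shared,total,expected", [(212, 216, 98), (99, 117, 85), (0, 10, 0), (35, 38, 92)]
    )
    def test_directional_percentages(self, shared, total, expected):
        pc = PairComparison("a", "b")
        pc.shared_pairs = [None] * shared  # only counts matter here
        pc.specific_a = [None] * (total - shared)
        pa, _ = directional_similarity(pc)
        assert round_half_away(pa) == expected

    def test_zero_total_is_flagged_not_zero(self):
        pc = PairComparison("a", "b")
        pa, pb = directional_similarity(pc)
        assert pa is None and pb is None

    def test_combined_similarity_union_formula(self):
        pc = PairComparison("a", "b")
        pc.shared_pairs = [None] * 82
        pc.specific_a = []
        pc.specific_b = [None] * 5
        # totals 82 and 87, union 87
        assert round_half_away(combined_similarity(pc)) == 94

    def test_combined_bounded_by_directional(self):
        pc = PairComparison("a", "b")
        pc.shared_pairs = [None] * 50
        pc.specific_a = [None] * 10
        pc.specific_b = [None] * 3
        stats = similarity_stats(pc)
        assert stats.pct_combined <= min(stats.pct_shared_a, stats.pct_shared_b) + 1

    def test_gained_lost_orientation(self):
        from svconcord.compare import MatchedPair

        ev = make_event("chr1", 10_000)
        pair = MatchedPair(event_a=ev, event_b=ev, support_a=5, support_b=5,
                           provenance="direct")
        pc = PairComparison("P16_P", "P16_M")
        pc.shared_pairs = [pair] * 99
        pc.specific_a = [ev] * 1
        pc.specific_b = [ev] * 18
        assert gained_lost(pc, "primary", "metastasis") == (18, 1)
        assert gained_lost(pc.swapped(), "metastasis", "primary") == (18, 1)
        with pytest.raises(ValueError):
            gained_lost(pc, "primary", "primary")

    def test_identical_catalogues_zero_gained_lost(self):
        cat = [make_event("chr1", 10_000)]
        pc = classify_pair(cat, list(cat), w=W, sample_a="p", sample_b="m")
        assert gained_lost(pc, "primary", "metastasis") == (0, 0)
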