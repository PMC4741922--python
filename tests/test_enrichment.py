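"""Enrichment nulls: genic breakpoints, cancer-gene draws, p arithmetic,
validation summary."""

import numpy as np
import pytest
from scipy import stats

from svconcord.enrichment import (
    affected_gene_table,
    cancer_gene_enrichment,
    empirical_two_sided_p,
    fold_enrichment,
    genic_breakpoints,
    simulate_genic_null_counts,
    validation_summary,
)
from svconcord.model import GeneRecord, GenomeModel

from .conftest import make_event


class TestGenicBreakpoints:
    def test_promoter_boundary_inclusive_at_2000(self):
        genes = [GeneRecord("chr1", 10_000, 20_000, "G", "+")]
        exactly = genic_breakpoints([make_event("chr1", 8_000, "chr2", 1)], genes)
        beyond = genic_breakpoints([make_event("chr1", 7_999, "chr2", 1)], genes)
        inside = genic_breakpoints([make_event("chr1", 8_001, "chr2", 1)], genes)
        assert exactly.n_genic == 1 and inside.n_genic == 1 and beyond.n_genic == 0

    def test_minus_strand_promoter_is_downstream_coordinate(self):
        genes = [GeneRecord("chr1", 10_000, 20_000, "G", "-")]
        res = genic_breakpoints([make_event("chr1", 21_999, "chr2", 1)], genes)
        assert res.n_genic == 1
        res = genic_breakpoints([make_event("chr1", 9_000, "chr2", 1)], genes)
        assert res.n_genic == 0  # upstream of a - gene is past end, not before start

    def test_counts_and_affected_set(self):
        genes = [GeneRecord("chr1", 10_000, 20_000, "A", "+"),
                 GeneRecord("chr2", 10_000, 20_000, "B", "+")]
        events = [
            make_event("chr1", 15_000, "chr2", 15_000),  # both ends genic
            make_event("chr1", 15_500, "chr1", 500_000),  # one end genic
            make_event("chr3", 100, "chr3", 90_000),  # none
        ]
        res = genic_breakpoints(events, genes)
        assert (res.n_breakpoints, res.n_genic) == (6, 3)
        assert res.n_rearr_with_genic == 2
        assert res.affected_genes == {"A", "B"}
        assert res.pct_genic == pytest.approx(50.0)

    def test_empty_gene_set(self):
        res = genic_breakpoints([make_event("chr1", 100)], [])
        assert res.pct_genic == 0.0


class TestGenicNull:
    def test_null_mean_matches_binomial(self):
        # genic fraction 0.4 of a 10 Mb genome, 1000 breakpoints, 2000 sims
        genome = GenomeModel([("chr1", 10_000_000)])
        genes = [GeneRecord("chr1", i * 1_000_000 + 2_000, i * 1_000_000 + 400_000,
                            f"g{i}", "+")
                 for i in range(10)]  # extended spans cover exactly 400 kb per Mb
        counts = simulate_genic_null_counts(1000, genome, genes, 2000, seed=5,
                                            avoid_masks=False)
        p = 0.4
        se = np.sqrt(p * (1 - p) / 1000) * 1000 / np.sqrt(2000)
        assert abs(counts.mean() - 400.0) < 3 * se

    def test_degenerate_coverage(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        everything = [GeneRecord("chr1", 0, 1_000_000, "all", "+")]
        counts = simulate_genic_null_counts(50, genome, everything, 10, seed=1,
                                            avoid_masks=False)
        assert (counts == 50).all()
        counts = simulate_genic_null_counts(50, genome, [], 10, seed=1, avoid_masks=False)
        assert (counts == 0).all()

    def test_deterministic_given_seed(self):
        genome = GenomeModel([("chr1", 1_000_000)])
        genes = [GeneRecord("chr1", 0, 300_000, "g", "+")]
        a = simulate_genic_null_counts(100, genome, genes, 50, seed=7, avoid_masks=False)
        b = simulate_genic_null_counts(100, genome, genes, 50, seed=7, avoid_masks=False)
        assert (a == b).all()


class TestPValueArithmetic:
    def test_two_tail_draws_of_ten_thousand(self):
        null = np.concatenate([np.full(9998, 26), [46, 47]])
        p, bound = empirical_two_sided_p(null, 46)
        assert p == pytest.approx(0.0004) and not bound

    def test_zero_tail_reported_as_bound(self):
        null = np.full(1000, 10)
        p, bound = empirical_two_sided_p(null, 50)
        assert p == pytest.approx(0.002) and bound

    def test_observed_at_median_gives_one(self):
        null = np.arange(100)
        p, bound = empirical_two_sided_p(null, np.median(null))
        assert p == 1.0 and not bound

    def test_fold_rounding(self):
        assert fold_enrichment(46, 26) == 1.8
        with pytest.raises(ValueError):
            fold_enrichment(1, 0)


class TestCancerGeneEnrichment:
    UNIVERSE = [f"g{i}" for i in range(500)]
    CANCER = set(UNIVERSE[:50])

    def test_null_matches_hypergeometric(self):
        # chi-square goodness of fit of the simulated null against
        # Hypergeom(N=500, K=50, n=100)
        from svconcord.enrichment import simulate_cancer_null_counts

        rv = stats.hypergeom(500, 50, 100)
        sims = simulate_cancer_null_counts(100, 500, 50, 10_000, seed=3)
        lo, hi = int(rv.ppf(0.001)), int(rv.ppf(0.999))
        observed_freq = np.array([(sims == k).sum() for k in range(lo, hi + 1)])
        expected = rv.pmf(np.arange(lo, hi + 1)) * len(sims)
        keep = expected >= 5
        chi2 = ((observed_freq[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pval = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pval > 0.01
        res = cancer_gene_enrichment(self.UNIVERSE[::5], self.UNIVERSE, self.CANCER,
                                     2_000, seed=3)
        assert abs(res.null_median - rv.median()) <= 1

    def test_whole_universe_cancer(self):
        res = cancer_gene_enrichment(self.UNIVERSE[:20], self.UNIVERSE,
                                     set(self.UNIVERSE), 100, seed=1)
        assert res.observed == 20 and res.null_median == 20 and res.fold == 1.0

    def test_affected_must_be_subset(self):
        with pytest.raises(ValueError):
            cancer_gene_enrichment(["nope"], self.UNIVERSE, self.CANCER, 10, seed=1)

    def test_true_null_p_super_uniform(self):
        # 200 replicate analyses with randomly drawn affected sets: the
        # fraction reaching p <= 0.05 stays near/below the nominal level
        rng = np.random.default_rng(12)
        universe = [f"g{i}" for i in range(400)]
        cancer = set(universe[:40])
        hits = 0
        for rep in range(200):
            affected = rng.choice(universe, size=80, replace=False)
            res = cancer_gene_enrichment(affected, universe, cancer, 400,
                                         seed=int(rng.integers(2**31)))
            if res.p_two_sided <= 0.05:
                hits += 1
        assert hits / 200 <= 0.075


class TestAffectedGeneTable:
    def test_shared_event_counts_once(self, genome):
        genes = [GeneRecord("chr1", 9_000, 60_000, "G1", "+")]
        ev = make_event("chr1", 10_000, sample_id="P1_P")
        ev2 = make_event("chr1", 10_100, sample_id="P1_M")  # same event, jittered
        table = affected_gene_table(
            {"P1_P": [ev], "P1_M": [ev2]}, {"P1_P": "P1", "P1_M": "P1"}, genes, genome
        )
        row = table.iloc[0]
        assert (row["gene"], row["n_rearrangements"], row["n_patients"]) == ("G1", 1, 1)

    def test_multiple_events_and_patients(self, genome):
        genes = [GeneRecord("chr1", 5_000, 400_000, "G1", "+")]
        cats = {
            "P1_P": [make_event("chr1", 10_000, sample_id="P1_P"),
                     make_event("chr1", 100_000, sample_id="P1_P")],
            "P2_P": [make_event("chr1", 300_000, sample_id="P2_P")],
        }
        table = affected_gene_table(cats, {"P1_P": "P1", "P2_P": "P2"}, genes, genome)
        row = table.iloc[0]
        assert (row["n_rearrangements"], row["n_patients"]) == (3, 2)

    def test_empty_catalogues(self, genome):
        table = affected_gene_table({}, {}, [], genome)
        assert len(table) == 0


class TestValidationSummary:
    def test_reference_counts(self):
        out = validation_summary(62, 62, 8, 51, 41)
        assert out["shared_pct"] == 100
        assert out["specific_pct"] == 80
        assert out["overall_pct_all_informative"] == 91  # 103/113
        assert out["overall_pct_excl_germline"] == 90  # (62-8+41)/(113-8) = 90.48

    def test_zero_tested_category_omitted(self):
        out = validation_summary(0, 0, 0, 10, 8)
        assert "shared_pct" not in out and out["specific_pct"] == 80
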