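"""Synthetic cohort generator: determinism, sharing structure, support
model and annotation geometry."""

import dataclasses

import numpy as np
import pytest

from svconcord.cnv import compare_profiles
from svconcord.filtering import filter_catalogue, support_threshold
from svconcord.model import SampleMeta
from svconcord.simulate import (
    SimConfig,
    build_genome,
    render_observed,
    simulate_annotation,
    simulate_cn_profiles,
    simulate_cohort,
    simulate_patient,
)

SMALL = SimConfig(
    seed=42,
    chrom_lengths=(20_000_000,) * 3,
    n_primary_events=30,
    n_met_private=5,
    n_germline=3,
    genic_fraction_target=0.3,
    n_cancer_genes=10,
)


def meta(which, config):
    role = "primary" if which == "primary" else "metastasis"
    cov = config.coverage_primary if which == "primary" else config.coverage_met
    seq = config.seq_coverage_primary if which == "primary" else config.seq_coverage_met
    return SampleMeta(f"P1_{'P' if which == 'primary' else 'M'}", "P1", role, cov, seq)


class TestSimulatePatient:
    def test_deterministic_given_seed(self):
        t1 = simulate_patient(SMALL)
        t2 = simulate_patient(SMALL)
        assert [e.primary for e in t1.events] == [e.primary for e in t2.events]
        assert [e.met for e in t1.events] == [e.met for e in t2.events]

    def test_full_sharing_no_jitter_gives_identical_catalogues(self):
        cfg = dataclasses.replace(
            SMALL, shared_fraction=1.0, n_met_private=0, jitter_sd=0.0,
            subclonal_fraction=0.0, lookup_only_fraction=0.0,
        )
        truth = simulate_patient(cfg)
        prim = {e.primary.key() for e in truth.events}
        met = {e.met.key() for e in truth.events}
        assert prim == met

    def test_zero_sharing_means_no_shared_somatic(self):
        cfg = dataclasses.replace(SMALL, shared_fraction=0.0)
        truth = simulate_patient(cfg)
        shared_somatic = [e for e in truth.events if e.shared and not e.germline]
        assert shared_somatic == []

    def test_shared_count_is_rounded_fraction(self):
        truth = simulate_patient(SMALL)
        shared_somatic = [e for e in truth.events if e.shared and not e.germline]
        assert len(shared_somatic) == round(SMALL.shared_fraction * SMALL.n_primary_events)

    def test_shared_coordinates_differ_by_jitter_only(self):
        truth = simulate_patient(SMALL)
        for e in truth.events:
            if e.shared and e.primary and e.met:
                assert abs(e.primary.left.pos - e.met.left.pos) < 10 * SMALL.jitter_sd
                assert e.primary.left.chrom == e.met.left.chrom

    def test_capacity_error(self):
        cfg = dataclasses.replace(
            SMALL, chrom_lengths=(2_000,), centromere_half_width=0,
            n_primary_events=5_000, genic_fraction_target=0.0, min_intra_span=100,
            max_intra_span=500,
        )
        with pytest.raises(RuntimeError, match="capacity|place"):
            simulate_patient(cfg)


class TestRenderObserved:
    def test_poisson_support_mean(self):
        # 1000 events at clonal fraction 0.5 and coverage 20: mean
        # observed support within 3 s.e. of 10
        cfg = dataclasses.replace(
            SMALL, chrom_lengths=(200_000_000,) * 3, n_primary_events=1000,
            shared_fraction=0.0, n_met_private=0, n_germline=0,
            coverage_primary=20.0, subclonal_fraction=0.0, genic_fraction_target=0.0,
        )
        truth = simulate_patient(cfg)
        for e in truth.events:
            e.cf_primary = 0.5
        obs = render_observed(truth, meta("primary", cfg), cfg, "primary")
        supports = [r.support for r in obs.raw_calls]
        # zero-support events are unobservable; at mean 10 they are ~5e-5
        se = np.sqrt(10.0 / 1000)
        assert abs(np.mean(supports) - 10.0) < 3 * se + 0.01

    def test_full_clonal_event_reaches_catalogue(self):
        cfg = dataclasses.replace(
            SMALL, n_primary_events=50, shared_fraction=1.0, subclonal_fraction=0.0,
            lookup_only_fraction=0.0, clonal_beta=(1e6, 1e-6),  # cf ~ 1
        )
        truth = simulate_patient(cfg)
        obs = render_observed(truth, meta("primary", cfg), cfg, "primary")
        # Poisson(22.3) below threshold 4 is vanishingly rare
        assert len(obs.catalogue) >= 49

    def test_absent_event_nowhere(self):
        cfg = dataclasses.replace(SMALL, shared_fraction=0.0, n_germline=0)
        truth = simulate_patient(cfg)
        obs_met = render_observed(truth, meta("met", cfg), cfg, "met")
        prim_keys = {e.primary.key() for e in truth.events if e.primary}
        met_keys = {r.key() for r in obs_met.raw_calls}
        # primary-specific events (cf_met = 0) never appear in the metastasis
        assert not (prim_keys & met_keys)

    def test_lookup_only_events_withheld_from_calls(self):
        cfg = dataclasses.replace(
            SMALL, n_primary_events=40, shared_fraction=1.0,
            subclonal_fraction=0.5, lookup_only_fraction=0.5,
        )
        truth = simulate_patient(cfg)
        lookup_primary = [
            e for e in truth.events if e.lookup_only_in == "primary" and e.primary
        ]
        assert lookup_primary, "fixture should produce look-up-only events"
        obs = render_observed(truth, meta("primary", cfg), cfg, "primary")
        raw_keys = {r.key() for r in obs.raw_calls}
        for e in lookup_primary:
            assert e.primary.key() not in raw_keys

    def test_sub_threshold_events_only_in_raw(self):
        cfg = dataclasses.replace(SMALL, subclonal_fraction=0.4, lookup_only_fraction=0.0)
        truth = simulate_patient(cfg)
        obs = render_observed(truth, meta("primary", cfg), cfg, "primary")
        thr = support_threshold(cfg.seq_coverage_primary)
        cat_keys = {r.key() for r in obs.catalogue}
        for r in obs.raw_calls:
            if r.support < thr:
                assert r.key() not in cat_keys
            else:
                assert r.key() in cat_keys


class TestCnProfiles:
    def test_full_sharing_identical(self):
        cfg = dataclasses.replace(SMALL, shared_cn_fraction=1.0)
        prim, met = simulate_cn_profiles(simulate_patient(cfg), cfg)
        assert prim.segments == met.segments

    def test_all_normal_config(self):
        cfg = dataclasses.replace(SMALL, cn_n_segments=0)
        prim, met = simulate_cn_profiles(simulate_patient(cfg), cfg)
        assert prim.segments == {} and met.segments == {}

    def test_event_similarity_recovers_sharing(self):
        cfg = dataclasses.replace(
            SMALL, chrom_lengths=(100_000_000,) * 5, cn_n_segments=200,
            shared_cn_fraction=0.4,
        )
        truth = simulate_patient(cfg)
        genome = truth.genome
        sims = []
        for seed in range(5):
            c = dataclasses.replace(cfg, seed=seed)
            prim, met = simulate_cn_profiles(truth, c)
            event, _ = compare_profiles(prim, met, genome)
            sims.append(event)
        # binomial s.e. at n=200, p=0.4 is ~3.5 points per replicate
        assert abs(np.mean(sims) - 40.0) < 6.0


class TestAnnotation:
    def test_footprint_matches_target(self):
        cfg = dataclasses.replace(SMALL, chrom_lengths=(50_000_000,) * 5,
                                  genic_fraction_target=0.433)
        genome = build_genome(cfg, with_annotation=False)
        genes, cancer = simulate_annotation(cfg, genome)
        footprint = sum(len(g.extended_span()) for g in genes)
        target = 0.433 * 250_000_000
        assert abs(footprint - target) / target < 0.01
        assert len(cancer) == cfg.n_cancer_genes

    def test_genes_non_overlapping_when_extended(self):
        genome = build_genome(SMALL, with_annotation=False)
        genes, _ = simulate_annotation(SMALL, genome)
        spans = sorted(
            (g.chrom, g.extended_span().start, g.extended_span().end) for g in genes
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 <= s2

    def test_zero_genes(self):
        cfg = dataclasses.replace(SMALL, genic_fraction_target=0.0, n_cancer_genes=0)
        genome = build_genome(cfg, with_annotation=False)
        genes, cancer = simulate_annotation(cfg, genome)
        assert genes == [] and cancer == set()


class TestCohort:
    def test_germline_never_survives_pool_filtering(self):
        cohort = simulate_cohort(SMALL, n_patients=3)
        germline_keys = set()
        for pat in cohort.patients:
            for e in pat.truth.germline_events:
                for r in (e.primary, e.met):
                    if r is not None:
                        germline_keys.add(r.key())
        assert germline_keys
        for pat in cohort.patients:
            for obs in (pat.primary, pat.met):
                filtered, _ = filter_catalogue(
                    obs.raw_calls, obs.meta, cohort.pool_catalogue, cohort.genome
                )
                for r in filtered:
                    assert r.key() not in germline_keys

    def test_cohort_deterministic(self):
        c1 = simulate_cohort(SMALL, n_patients=2)
        c2 = simulate_cohort(SMALL, n_patients=2)
        for p1, p2 in zip(c1.patients, c2.patients):
            assert p1.primary.catalogue == p2.primary.catalogue
            assert sorted(p1.met.evidence.records()) == sorted(p2.met.evidence.records())
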