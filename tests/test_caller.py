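"""Statistical step, quality filters, end-to-end calling, LOD and query modes."""

from __future__ import annotations

import numpy as np
import pytest

import taucall as tc
from taucall.caller import (
    FILTER_HIGH_QUAL_SD,
    FILTER_LOW_MEAN_QUAL,
    FILTER_LOW_RATIO,
    FILTER_STRAND_IMBALANCE,
)
from taucall.pileup_io import GenomicRegion, RegionProfile

from .conftest import make_column


def noise_est(count=0, rate=0.0):
    return tc.NoiseEstimate(
        noise_count=count,
        noise_rate=rate,
        kept=[count] if count else [],
        removed=[],
        window_start=1,
        window_end=200,
        mean_depth=1000.0,
        alpha=0.001,
    )


def observation(fwd=25, rev=25, qual=35, allele="T", quals=None):
    if quals is not None:
        half = len(quals) // 2
        return tc.AlleleObservation(allele, quals[:half], quals[half:])
    return tc.AlleleObservation(allele, [qual] * fwd, [qual] * rev)


class TestStatisticalStep:
    @pytest.mark.parametrize(
        "count,noise_count,expected",
        [(50, 2, True), (2, 2, False), (1, 0, True), (3, 2, True)],
    )
    def test_strict_inequality_against_noise_count(
        self, count, noise_count, expected
    ):
        assert tc.statistical_step(count, noise_est(noise_count)) is expected


class TestApplyFilters:
    def test_comfortable_candidate_passes_all_filters(self):
        obs = observation(fwd=25, rev=25, qual=35)
        fails = tc.apply_filters(obs, 1000, noise_est(1, 0.001), tc.FilterConfig())
        assert fails == []

    def test_mean_quality_exactly_at_floor_fails(self):
        obs = observation(fwd=25, rev=25, qual=20)
        fails = tc.apply_filters(obs, 1000, noise_est(1, 0.001), tc.FilterConfig())
        assert fails == [FILTER_LOW_MEAN_QUAL]

    def test_quality_sd_at_ceiling_fails(self):
        # alternating 28/42 -> mean 35, population SD exactly 7
        obs = observation(quals=[28, 42] * 25)
        fails = tc.apply_filters(obs, 1000, noise_est(1, 0.001), tc.FilterConfig())
        assert fails == [FILTER_HIGH_QUAL_SD]

    def test_strand_imbalance_only(self):
        obs = observation(fwd=10, rev=30, qual=35)  # forward fraction 0.25
        fails = tc.apply_filters(obs, 1000, noise_est(1, 0.001), tc.FilterConfig())
        assert fails == [FILTER_STRAND_IMBALANCE]

    def test_inclusive_strand_bounds(self):
        obs = observation(fwd=30, rev=70, qual=35)  # exactly 0.30
        fails = tc.apply_filters(obs, 1000, noise_est(1, 0.0005), tc.FilterConfig())
        assert FILTER_STRAND_IMBALANCE not in fails

    def test_rate_filter_is_strict(self):
        # vaf 0.004 vs 2 x 0.002: equality fails
        obs = observation(fwd=2, rev=2, qual=35)
        fails = tc.apply_filters(obs, 1000, noise_est(2, 0.002), tc.FilterConfig())
        assert fails == [FILTER_LOW_RATIO]

    def test_single_read_has_sd_zero_but_extreme_strand(self):
        obs = observation(fwd=1, rev=0, qual=35)
        fails = tc.apply_filters(obs, 1000, noise_est(0, 0.0), tc.FilterConfig())
        assert FILTER_HIGH_QUAL_SD not in fails
        assert FILTER_STRAND_IMBALANCE in fails

    def test_reporting_cutoff_tags_low_vaf(self):
        obs = observation(fwd=3, rev=3, qual=35)
        cfg = tc.FilterConfig(vaf_min_snv=0.01)
        fails = tc.apply_filters(obs, 1000, noise_est(0, 0.0), cfg)
        assert "below_reporting_cutoff" in fails

    def test_every_failure_is_recorded(self):
        # mean 20, SD 10, forward fraction 1.0, vaf 0.004 vs noise floor 0.02
        obs = tc.AlleleObservation("T", [10, 30, 10, 30], [])
        fails = tc.apply_filters(obs, 1000, noise_est(5, 0.01), tc.FilterConfig())
        assert set(fails) == {
            FILTER_LOW_RATIO,
            FILTER_LOW_MEAN_QUAL,
            FILTER_HIGH_QUAL_SD,
            FILTER_STRAND_IMBALANCE,
        }


class TestCollectCandidates:
    def test_all_reference_profile_is_empty(self):
        cols = [make_column("chr1", i + 1, depth=100) for i in range(5)]
        profile = RegionProfile(GenomicRegion("chr1", 1, 5), cols)
        assert tc.collect_candidates(profile) == []

    def test_multiallelic_position_yields_independent_candidates(self):
        col = make_column("chr1", 1, depth=100, alt="T", alt_fwd=15, alt_rev=15)
        col.alts["G"] = tc.AlleleObservation("G", [30], [30])
        col.alts["+AG"] = tc.AlleleObservation("+AG", [33, 33], [33])
        profile = RegionProfile(GenomicRegion("chr1", 1, 1), [col])
        candidates = tc.collect_candidates(profile)
        assert [(pos, obs.allele) for pos, obs in candidates] == [
            (1, "+AG"),
            (1, "G"),
            (1, "T"),
        ]


class TestCallVariants:
    def test_injected_variant_is_the_only_pass_call(self, clean_variant_sim):
        _, profiles, truth = clean_variant_sim
        calls = tc.call_variants(profiles)
        passing = [c for c in calls if c.is_pass]
        assert len(passing) == 1
        call = passing[0]
        assert (call.chrom, call.pos, call.alt) == ("chr1", 101, "T")
        assert call.alt_count == int(truth.iloc[0]["alt_count"])
        assert call.alt_count > call.noise.noise_count

    def test_every_pass_call_rechecked_from_raw_column_data(
        self, clean_variant_sim
    ):
        _, profiles, _ = clean_variant_sim
        cfg = tc.FilterConfig()
        calls = tc.call_variants(profiles, cfg)
        by_pos = {p.pos: p for p in profiles[0].columns}
        for call in calls:
            col = by_pos[call.pos]
            obs = col.alts[call.alt]
            quals = np.array(obs.qualities, float)
            assert call.alt_count == obs.count
            assert call.depth == col.depth
            if call.is_pass:
                assert obs.count > call.noise.noise_count
                assert obs.count / col.depth > cfg.noise_multiplier * call.noise.noise_rate
                assert quals.mean() > cfg.min_mean_phred
                assert quals.std(ddof=0) < cfg.max_phred_sd
                frac = obs.fwd_count / obs.count
                assert cfg.strand_balance_low <= frac <= cfg.strand_balance_high

    def test_calls_are_deterministic_and_sorted(self, clean_variant_sim):
        _, profiles, _ = clean_variant_sim
        calls_a = tc.call_variants(profiles)
        calls_b = tc.call_variants(profiles)
        keys = [(c.chrom, c.pos, c.alt) for c in calls_a]
        assert keys == sorted(keys)
        assert keys == [(c.chrom, c.pos, c.alt) for c in calls_b]
        assert [c.filter_status for c in calls_a] == [
            c.filter_status for c in calls_b
        ]

    def test_higher_alpha_trims_at_least_as_aggressively(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            sample = rng.poisson(1.5, size=80)
            sample = sample[sample > 0].tolist()
            if len(sample) < 3:
                continue
            _, removed_strict = tc.detect_outliers(sample, 0.001)
            _, removed_loose = tc.detect_outliers(sample, 0.1)
            assert len(removed_loose) >= len(removed_strict)

    def test_empty_profile_list_gives_no_calls(self):
        assert tc.call_variants([]) == []


class TestLodReport:
    def test_zero_noise_lod_is_one_over_depth(self):
        cfg = tc.SimulationConfig(
            regions=[tc.GenomicRegion("chr1", 1, 101)],
            depth=1000,
            error_rate=0.0,
            seed=1,
        )
        profiles, _ = tc.simulate_profiles(cfg)
        (report,) = tc.lod_report(profiles)
        assert report.lod_mean == pytest.approx(1 / 1000)
        assert report.lod_max == pytest.approx(1 / 1000)
        assert report.min_detectable_ratio == report.lod_max

    def test_lod_formula_direct_evaluation(self):
        # noise_count 2 at mean depth 1000 -> max(2*0.002, 3/1000) = 0.004
        from taucall.caller import _position_lod
        from .test_noise import profile_from_alt_counts

        counts = [0] * 101
        for i in (10, 30, 70, 90):
            counts[i] = 2
        profile = profile_from_alt_counts(counts, depth=1000)
        lod, noise = _position_lod(profile, 51, tc.FilterConfig())
        assert noise.noise_count == 2
        assert lod == pytest.approx(0.004)

    def test_lod_scales_inversely_with_depth(self):
        lods = {}
        for depth in (150, 1500):
            cfg = tc.SimulationConfig(
                regions=[tc.GenomicRegion("chr1", 1, 101)],
                depth=depth,
                error_rate=0.0,
                seed=2,
            )
            profiles, _ = tc.simulate_profiles(cfg)
            lods[depth] = tc.lod_report(profiles)[0].lod_mean
        assert lods[150] == pytest.approx(10 * lods[1500], rel=1e-6)

    def test_position_target_and_uncovered_target_error(self, clean_variant_sim):
        _, profiles, _ = clean_variant_sim
        (report,) = tc.lod_report(profiles, targets=[("chr1", 150)])
        assert report.start == report.end == 150
        assert 0 <= report.min_detectable_ratio <= 1
        with pytest.raises(ValueError, match="not covered"):
            tc.lod_report(profiles, targets=[("chr9", 5)])


class TestPositionReport:
    def test_all_reference_position_has_no_alt(self, clean_variant_sim):
        _, profiles, _ = clean_variant_sim
        col = next(c for c in profiles[0].columns if not c.alts)
        rep = tc.position_report(profiles, "chr1", col.pos)
        assert rep.alt_allele is None and rep.alt_count == 0
        assert rep.depth == col.depth
        assert rep.mean_qual > 0

    def test_variant_position_echoes_counts(self, clean_variant_sim):
        _, profiles, truth = clean_variant_sim
        rep = tc.position_report(profiles, "chr1", 101)
        assert rep.alt_allele == "T"
        assert rep.alt_count == int(truth.iloc[0]["alt_count"])
        assert rep.alt_fwd + rep.alt_rev == rep.alt_count
        assert rep.vaf == pytest.approx(rep.alt_count / rep.depth)

    def test_region_edge_report_still_produced(self, clean_variant_sim):
        _, profiles, _ = clean_variant_sim
        rep = tc.position_report(profiles, "chr1", 1)
        assert rep.noise.window_start == 1

    def test_uncovered_position_is_an_error(self, clean_variant_sim):
        _, profiles, _ = clean_variant_sim
        with pytest.raises(ValueError, match="not covered"):
            tc.position_report(profiles, "chr1", 5000)
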