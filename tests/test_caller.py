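"""Binomial error-model caller: thresholds, power, site and sample calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncopanel import (
    CallerConfig, ErrorModel, PileupSite, call_sample, call_site,
    detection_power, min_supporting_reads,
)
from oncopanel.caller import strand_bias_pvalue
from oncopanel.simulate import SimulationSpec, SiteTruth, simulate_pileups


def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """Independent brute-force P(X >= k | Binomial(n, p)) by pmf summation."""
    return sum(
        math.comb(n, i) * p**i * (1.0 - p) ** (n - i) for i in range(k, n + 1)
    )


class TestMinSupportingReads:
    def test_any_read_significant_when_errors_negligible(self):
        assert min_supporting_reads(10, 1e-12, 0.05) == 1

    @pytest.mark.parametrize("depth,e,alpha,expected", [
        (450, 1e-3, 1e-5, 6),
        (750, 1e-4, 1e-5, 4),
    ])
    def test_against_binomial_tail_oracle(self, depth, e, alpha, expected):
        k = min_supporting_reads(depth, e, alpha)
        assert k == expected
        assert binom_tail_oracle(k, depth, e) <= alpha
        assert binom_tail_oracle(k - 1, depth, e) > alpha

    def test_unattainable_returns_depth_plus_one(self):
        assert min_supporting_reads(3, 0.49, 1e-12) == 4

    @pytest.mark.parametrize("kwargs", [
        dict(depth=0, error_rate=0.001, alpha=0.05),
        dict(depth=10, error_rate=0.0, alpha=0.05),
        dict(depth=10, error_rate=0.001, alpha=1.5),
    ])
    def test_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            min_supporting_reads(**kwargs)


class TestDetectionPower:
    def test_certain_at_full_allele_fraction(self):
        assert detection_power(450, 1.0, 1e-3, 1e-5) == pytest.approx(1.0)

    def test_contract_at_three_percent(self):
        power = detection_power(450, 0.03, 1e-3, 1e-5)
        assert power == pytest.approx(binom_tail_oracle(6, 450, 0.03), abs=1e-12)
        assert power > 0.99

    def test_partial_at_one_percent(self):
        power = detection_power(450, 0.01, 1e-3, 1e-5)
        assert 0.2 < power < 0.8
        assert power < detection_power(450, 0.03, 1e-3, 1e-5)

    def test_monotone_in_vaf(self):
        grid = [0.005, 0.01, 0.02, 0.03, 0.05, 0.08, 0.1, 0.2, 0.5]
        powers = [detection_power(450, v, 1e-3, 1e-5) for v in grid]
        assert powers == sorted(powers)

    def test_monotone_in_depth_at_constant_threshold(self):
        # the discrete test's power saw-tooths where k* increments; between
        # increments it must grow with depth, and k* itself never decreases
        prev_k, prev_power = 0, -1.0
        for depth in range(100, 1001, 25):
            k = min_supporting_reads(depth, 1e-3, 1e-5)
            power = detection_power(depth, 0.03, 1e-3, 1e-5)
            assert k >= prev_k
            if k == prev_k:
                assert power >= prev_power - 1e-12
            prev_k, prev_power = k, power


class TestCallSite:
    def test_zero_alt_reads_no_call(self):
        site = PileupSite("chr7", 55249070, "C", 500, {"T": 0})
        assert call_site(site) == []

    def test_vaf_arithmetic_and_pass(self):
        site = PileupSite("chr7", 55242463, "A", 456, {"del15": 80})
        (call,) = call_site(site)
        assert call.filter == "PASS"
        assert call.vaf == pytest.approx(0.1754)
        assert call.vtype == "InDel"

    def test_weak_support_filtered_with_oracle_pvalue(self):
        site = PileupSite("chr1", 10, "A", 450, {"T": 3})
        (call,) = call_site(site)
        assert call.p_value == pytest.approx(
            binom_tail_oracle(3, 450, 1e-3), rel=1e-9)
        assert call.p_value > 1e-5
        assert "sig" in call.filter and "min_alt_reads" in call.filter

    def test_shallow_site_skipped_not_raised(self):
        site = PileupSite("chr1", 10, "A", 20, {"T": 10})
        assert call_site(site, config=CallerConfig(min_depth=50)) == []

    def test_oracle_equivalence_exhaustive_small_depths(self):
        model = ErrorModel(e_sub=0.02, e_indel=0.01)
        config = CallerConfig(alpha=0.05, min_alt_reads=1, min_vaf=0.0, min_depth=1)
        for depth in range(1, 31):
            for count in range(1, depth + 1):
                site = PileupSite("chr1", 0, "A", depth, {"C": count})
                (call,) = call_site(site, model, config)
                assert call.p_value == pytest.approx(
                    binom_tail_oracle(count, depth, 0.02), abs=1e-12)


class TestCallSample:
    HOTSPOTS = [("chr7", 55249070), ("chr7", 55259514)]

    def test_empty_input(self):
        assert call_sample([], hotspots=self.HOTSPOTS) == []

    def test_single_mutant_hotspot_detected(self):
        mutant = PileupSite("chr7", 55249070, "C", 450, {"T": 36})  # 8% T790M
        wild = PileupSite("chr7", 55259514, "T", 450, {"G": 1})
        calls = call_sample([mutant, wild], hotspots=self.HOTSPOTS)
        assert len([c for c in calls if c.is_pass]) == 1
        assert calls[0].pos == 55249070

    def test_co_occurring_variants_both_pass(self):
        ex19 = PileupSite("chr7", 55242463, "A", 456, {"del15": 80})   # 17.54%
        pik = PileupSite("chr3", 178952084, "A", 451, {"T": 40})       # 8.87%
        calls = call_sample(
            [ex19, pik], hotspots=[("chr7", 55242463), ("chr3", 178952084)])
        assert [c.is_pass for c in calls] == [True, True]
        assert calls[0].chrom == "chr3"  # sorted by coordinate
        assert calls[1].vaf == pytest.approx(0.1754)
        assert calls[0].vaf == pytest.approx(0.0887)

    def test_hotspot_mode_requires_hotspots(self):
        with pytest.raises(ValueError, match="hotspot"):
            call_sample([PileupSite("chr1", 0, "A", 100, {})], hotspots=None)

    def test_only_hotspot_positions_tested(self):
        off_target = PileupSite("chr9", 1000, "A", 450, {"T": 200})
        calls = call_sample([off_target], hotspots=self.HOTSPOTS)
        assert calls == []

    def test_panel_wide_bonferroni_is_stricter(self):
        # 40 sites tested => alpha/120; pick support whose p-value sits between
        sites = [PileupSite("chr1", i, "A", 450, {}) for i in range(39)]
        margin = PileupSite("chr1", 100, "A", 450, {"T": 6})  # p ~ 7.6e-6
        config = CallerConfig(mode="panel-wide")
        calls = call_sample(sites + [margin], config=config)
        flagged = [c for c in calls if c.alt == "T"]
        assert len(flagged) == 1 and not flagged[0].is_pass
        hotspot_calls = call_sample([margin], hotspots=[("chr1", 100)])
        assert hotspot_calls[0].is_pass


class TestSimulationContract:
    def test_vaf_recovery_unbiased(self):
        truth_vaf, depth, n = 0.2, 450, 1000
        spec = SimulationSpec(
            seed=11, sites=tuple(
                SiteTruth("chr7", 55249070, "C", "T", truth_vaf) for _ in range(n)),
        )
        calls = [c for s in simulate_pileups(spec) for c in call_site(s)]
        assert len(calls) == n
        p_eff = truth_vaf + 1e-3 * (1 - truth_vaf)
        se = math.sqrt(p_eff * (1 - p_eff) / depth / n)
        assert abs(np.mean([c.vaf for c in calls]) - p_eff) < 3 * se


@given(
    depth=st.integers(min_value=50, max_value=2000),
    count_frac=st.floats(min_value=0.0, max_value=1.0),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_call_invariants_hold_for_arbitrary_sites(depth, count_frac):
    """PASS always implies the significance and floor thresholds."""
    count = int(round(count_frac * depth))
    site = PileupSite("chr1", 0, "A", depth, {"T": count})
    config = CallerConfig()
    for call in call_site(site, config=config):
        assert 0.0 <= call.p_value <= 1.0
        assert 0.0 <= call.vaf <= 1.0
        if call.is_pass:
            assert call.p_value <= config.alpha
            assert call.alt_count >= config.min_alt_reads
            assert call.vaf >= config.min_vaf


def test_strand_bias_pvalue_sanity():
    assert strand_bias_pvalue(20, 20) == pytest.approx(1.0)
    assert strand_bias_pvalue(40, 0) < 1e-9
    with pytest.raises(ValueError):
        strand_bias_pvalue(0, 0)
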