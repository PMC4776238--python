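"""Copy-number ratios/calls and split-read fusion clustering."""

import numpy as np
import pytest

from oncopanel import (
    DepthProfile, Panel, SplitReadEvidence, TargetRegion,
    call_cnv, call_fusion, cluster_split_reads, normalize_and_ratio,
    read_depth_profile, read_split_reads, write_depth_profile, write_split_reads,
)
from oncopanel.simulate import (
    simulate_depth_profile, simulate_split_reads, synthetic_panel,
)


def _profile(depths, genes=None):
    genes = genes or [f"G{i}" for i in range(len(depths))]
    regions = tuple(
        TargetRegion("chr1", 1000 * i, 1000 * i + 500, g)
        for i, g in enumerate(genes)
    )
    return DepthProfile(regions, tuple(float(d) for d in depths))


class TestNormalizeAndRatio:
    def test_identical_profiles_ratio_zero(self):
        p = _profile([400, 450, 500])
        for rr in normalize_and_ratio(p, p):
            assert rr.log2_ratio == pytest.approx(0.0)

    def test_single_gain_closed_form(self):
        base = _profile([450] * 5)
        sample = _profile([450, 450, 675, 450, 450])
        ratios = normalize_and_ratio(sample, base)
        assert ratios[2].log2_ratio == pytest.approx(np.log2(1.5), abs=1e-12)
        assert all(r.log2_ratio == pytest.approx(0.0) for i, r in enumerate(ratios) if i != 2)

    def test_library_size_removed_by_median_scaling(self):
        base = _profile([450] * 5)
        sample = _profile([900, 900, 1350, 900, 900])  # 2x library, one 1.5x gain
        ratios = normalize_and_ratio(sample, base)
        assert ratios[2].log2_ratio == pytest.approx(np.log2(1.5), abs=1e-12)

    def test_shallow_baseline_excluded(self):
        base = _profile([450, 10, 450])
        sample = _profile([450, 400, 450])
        ratios = normalize_and_ratio(sample, base, min_baseline_depth=50)
        assert ratios[1].excluded

    def test_zero_median_profile_raises(self):
        with pytest.raises(ValueError, match="median"):
            normalize_and_ratio(_profile([0, 0, 0]), _profile([450] * 3))

    def test_mismatched_regions_raise(self):
        with pytest.raises(ValueError, match="region set"):
            normalize_and_ratio(_profile([1, 2]), _profile([1, 2, 3]))


class TestCallCnv:
    def test_all_diploid_no_calls(self):
        p = _profile([450] * 6)
        assert call_cnv(normalize_and_ratio(p, p)) == []

    def test_single_region_met_gain_copy_number_three(self):
        base = _profile([450] * 5, genes=["A", "B", "MET", "C", "D"])
        sample = _profile([450, 450, 675, 450, 450], genes=["A", "B", "MET", "C", "D"])
        (call,) = call_cnv(normalize_and_ratio(sample, base))
        assert call.direction == "gain"
        assert call.copy_number == 3
        assert call.genes == ("MET",)

    def test_adjacent_loss_regions_merged(self):
        genes = ["A", "B", "X", "X", "C", "D"]
        base = _profile([450] * 6, genes=genes)
        sample = _profile([450, 450, 225, 225, 450, 450], genes=genes)
        (call,) = call_cnv(normalize_and_ratio(sample, base))
        assert call.direction == "loss"
        assert call.copy_number == 1
        assert call.n_regions == 2

    def test_short_run_in_multi_region_gene_suppressed(self):
        genes = ["X", "X", "X", "X"]
        base = _profile([450] * 4, genes=genes)
        sample = _profile([450, 675, 450, 450], genes=genes)
        assert call_cnv(normalize_and_ratio(sample, base), min_regions=2) == []

    @pytest.mark.parametrize("cn", [1, 2, 3, 4, 6])
    def test_noise_free_integer_copy_number_recovery(self, cn):
        genes = ["A", "B", "MET", "C", "D"]
        base = _profile([450] * 5, genes=genes)
        sample = _profile(
            [450, 450, 450 * cn / 2.0, 450, 450], genes=genes)
        calls = call_cnv(normalize_and_ratio(sample, base))
        if cn == 2:
            assert calls == []
        else:
            assert calls[0].copy_number == cn

    def test_invalid_thresholds(self):
        p = _profile([450] * 3)
        with pytest.raises(ValueError, match="thresholds"):
            call_cnv(normalize_and_ratio(p, p), gain_threshold=-0.1)

    def test_noisy_single_gene_gain_recovery_rate(self):
        # per-base lognormal noise at sigma=0.1 averages out over a target,
        # so a CN=3 single-exon gain is recovered nearly always
        regions = tuple(
            TargetRegion("chr7", 116435940 + 5000 * i, 116435940 + 5000 * i + 600,
                         g, "exon1")
            for i, g in enumerate(["MET", "A", "B", "C", "D", "E", "F", "G"])
        )
        small_panel = Panel(regions)
        hits = 0
        n_sim = 500
        for seed in range(n_sim):
            sample, base = simulate_depth_profile(
                small_panel, {"MET": 3}, noise_sigma=0.1, seed=seed)
            calls = call_cnv(normalize_and_ratio(sample, base))
            if any(c.copy_number == 3 and "MET" in c.genes and
                   c.direction == "gain" for c in calls):
                hits += 1
        assert hits / n_sim >= 0.95


def brute_force_clusters(records, window):
    """Independent oracle: transitive closure of pairwise consistency."""
    def consistent(a, b):
        return (a.chrom_a == b.chrom_a and a.chrom_b == b.chrom_b
                and a.strand_a == b.strand_a and a.strand_b == b.strand_b
                and abs(a.pos_a - b.pos_a) <= window
                and abs(a.pos_b - b.pos_b) <= window)

    unassigned = list(range(len(records)))
    groups = []
    while unassigned:
        frontier = [unassigned.pop(0)]
        group = set(frontier)
        while frontier:
            i = frontier.pop()
            for j in list(unassigned):
                if consistent(records[i], records[j]):
                    unassigned.remove(j)
                    group.add(j)
                    frontier.append(j)
        groups.append(frozenset(group))
    return set(groups)


class TestClusterSplitReads:
    def test_empty(self):
        assert cluster_split_reads([]) == []

    def test_identical_records_single_cluster(self):
        recs = [
            SplitReadEvidence(f"r{i}", "chr2", 29446561, "+", "chr2", 42523152, "-")
            for i in range(10)
        ]
        (cluster,) = cluster_split_reads(recs)
        assert cluster.support == 10
        assert (cluster.breakpoint_a, cluster.breakpoint_b) == (29446561, 42523152)

    def test_modal_breakpoint_tie_goes_to_smallest(self):
        recs = [
            SplitReadEvidence("r1", "chr2", 100, "+", "chr2", 200, "-"),
            SplitReadEvidence("r2", "chr2", 102, "+", "chr2", 200, "-"),
        ]
        (cluster,) = cluster_split_reads(recs, window=5)
        assert cluster.breakpoint_a == 100

    def test_strand_pattern_separates_clusters(self):
        recs = [
            SplitReadEvidence("r1", "chr2", 100, "+", "chr2", 200, "-"),
            SplitReadEvidence("r2", "chr2", 100, "+", "chr2", 200, "+"),
        ]
        assert len(cluster_split_reads(recs, window=5)) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_transitive_grouping(self, seed):
        rng = np.random.default_rng(seed)
        recs = [
            SplitReadEvidence(
                f"r{i}",
                "chr2", int(rng.integers(0, 60)), "+" if rng.random() < 0.8 else "-",
                "chr5", int(rng.integers(0, 60)), "+",
            )
            for i in range(80)
        ]
        expected = brute_force_clusters(recs, window=5)
        got = {
            frozenset(recs.index(r) for r in c.records)
            for c in cluster_split_reads(recs, window=5)
        }
        assert got == expected

    def test_jittered_fixture_recovers_modal_breakpoints(self, panel):
        recs = simulate_split_reads(
            support=50, jitter_bp=2, noise_records=5, panel=panel, seed=3)
        clusters = cluster_split_reads(recs, window=5)
        top = clusters[0]
        assert top.support == 50
        assert (top.breakpoint_a, top.breakpoint_b) == (29446561, 42523152)


class TestCallFusion:
    def _cluster(self, **kw):
        recs = simulate_split_reads(support=kw.pop("support", 10), jitter_bp=0, seed=0)
        return cluster_split_reads(recs)[0]

    def test_low_support_not_called(self, panel):
        clusters = cluster_split_reads(
            simulate_split_reads(support=2, jitter_bp=0, seed=0))
        assert call_fusion(clusters, panel, min_support=3) == []

    def test_worked_example_alk_eml4(self, panel):
        recs = simulate_split_reads(
            support=50, jitter_bp=2, noise_records=5, panel=panel, seed=3)
        calls = call_fusion(cluster_split_reads(recs, 5), panel, 3)
        top = calls[0]
        assert (top.gene_a, top.breakpoint_a) == ("ALK", 29446561)
        assert (top.gene_b, top.breakpoint_b) == ("EML4", 42523152)
        assert top.orientation == "+/-"  # EML4 minus strand reverse-joined

    def test_non_fusion_target_side_dropped(self, panel):
        # breakpoint in an EGFR exon: EGFR has no intron-level capture
        recs = [
            SplitReadEvidence(f"r{i}", "chr2", 29446561, "+", "chr7", 55242450, "+")
            for i in range(10)
        ]
        assert call_fusion(cluster_split_reads(recs), panel, 3) == []

    def test_breakpoint_outside_panel_dropped(self, panel):
        recs = [
            SplitReadEvidence(f"r{i}", "chr2", 29446561, "+", "chr2", 5, "+")
            for i in range(10)
        ]
        assert call_fusion(cluster_split_reads(recs), panel, 3) == []

    def test_panel_without_introns_raises(self):
        bare = Panel((TargetRegion("chr1", 0, 100, "G", "exon1"),))
        with pytest.raises(ValueError, match="fusion-target"):
            call_fusion([], bare)


class TestRoundTrips:
    def test_depth_profile_tsv(self, tmp_path):
        profile = _profile([450.0, 675.25, 10.5])
        path = tmp_path / "depth.tsv"
        write_depth_profile(profile, path)
        back = read_depth_profile(path)
        assert back.regions == profile.regions
        assert back.depths == pytest.approx(profile.depths)

    def test_split_reads_tsv(self, tmp_path):
        recs = simulate_split_reads(support=5, jitter_bp=2, seed=1)
        path = tmp_path / "sr.tsv"
        write_split_reads(recs, path)
        assert read_split_reads(path) == recs
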