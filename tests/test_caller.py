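"""Normalization, segmentation (vs exhaustive oracle), calling and labeling."""

import math
import statistics

import numpy as np
import pytest
from scipy import stats as sps

from liquidcnv import (
    CallerConfig,
    SimEvent,
    SimSample,
    call_sample,
    call_segment,
    expected_log2,
    normalize_bins,
    segment_arm,
    simulate_sample,
)
from liquidcnv.caller import Segment, detect_gene_amplification, label_positions
from liquidcnv.simulate import DepthProfile, ReferenceProfile


def oracle_segments(x, min_bins, alpha):
    """Exhaustive-search segmentation oracle, written independently of the
    production path: plain-python loops over every candidate breakpoint with
    the same acceptance statistic (pooled t, Bonferroni over candidates)."""
    x = list(map(float, x))

    def rec(lo, hi, out):
        n = hi - lo
        if n < 2 * min_bins:
            out.append((lo, hi))
            return
        best_t, best_b = -1.0, None
        candidates = list(range(lo + min_bins, hi - min_bins + 1))
        for b in candidates:
            left, right = x[lo:b], x[b:hi]
            m1, m2 = statistics.fmean(left), statistics.fmean(right)
            rss = sum((v - m1) ** 2 for v in left) + sum((v - m2) ** 2 for v in right)
            sp2 = rss / (n - 2)
            diff = abs(m1 - m2)
            if sp2 <= 1e-300:
                t = math.inf if diff > 1e-12 else 0.0
            else:
                t = diff / math.sqrt(sp2 * (1 / len(left) + 1 / len(right)))
            if t > best_t:
                best_t, best_b = t, b
        p = 0.0 if math.isinf(best_t) else 2 * sps.t.sf(best_t, n - 2)
        if min(p * len(candidates), 1.0) <= alpha:
            rec(lo, best_b, out)
            rec(best_b, hi, out)
        else:
            out.append((lo, hi))

    out = []
    rec(0, len(x), out)
    return out


def _seg(mean, n=50, z=10.0):
    return Segment("5q", 0, n, mean, n, z)


class TestNormalize:
    def test_identical_sample_gives_zeros(self):
        ref = ReferenceProfile(np.full(100, 500.0), np.zeros(100), 5)
        prof = normalize_bins(DepthProfile("s", np.full(100, 500.0)), ref)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_doubled_bin_reads_plus_one(self):
        depths = np.full(400, 500.0)
        depths[7] = 1000.0
        ref = ReferenceProfile(np.full(400, 500.0), np.zeros(400), 5)
        prof = normalize_bins(DepthProfile("s", depths), ref)
        assert prof.values[7] == pytest.approx(1.0, abs=0.01)

    def test_median_centering_invariant(self):
        rng = np.random.default_rng(0)
        depths = 500 * 2 ** rng.normal(0, 0.2, 501)
        ref = ReferenceProfile(np.full(501, 500.0), np.full(501, 0.2), 5)
        prof = normalize_bins(DepthProfile("s", depths), ref)
        assert abs(np.median(prof.values)) < 1e-9
        assert np.all(np.isfinite(prof.values))

    def test_noiseless_full_clonal_loss_is_minus_one(self, bins40, genome, reference40):
        sim = SimSample(
            "s", [SimEvent(chrom="5", arm="q", tumor_copies=1)],
            tumor_fraction=1.0, noise_sigma=0.0, seed=1,
        )
        depths = simulate_sample(bins40, sim, reference40, genome)
        prof = normalize_bins(depths, reference40, pseudo=0.0)
        cen = genome.arm("5q").start
        mask = np.array([b.chrom == "5" and b.start >= cen for b in bins40])
        np.testing.assert_allclose(prof.values[mask], -1.0, atol=1e-6)

    def test_length_mismatch_rejected(self):
        ref = ReferenceProfile(np.full(10, 500.0), np.zeros(10), 5)
        with pytest.raises(ValueError, match="bins"):
            normalize_bins(DepthProfile("s", np.full(9, 500.0)), ref)


class TestSegmentation:
    def test_constant_input_single_segment(self):
        cfg = CallerConfig()
        segs = segment_arm(np.zeros(100), np.full(100, 0.1), cfg, arm_name="1p")
        assert len(segs) == 1 and segs[0].mean_log2 == 0.0

    def test_noiseless_step_splits_at_breakpoint(self):
        cfg = CallerConfig()
        x = np.concatenate([np.zeros(50), np.full(50, -1.0)])
        segs = segment_arm(x, np.full(100, 0.1), cfg)
        assert [(s.start, s.end) for s in segs] == [(0, 50), (50, 100)]
        assert segs[1].mean_log2 == pytest.approx(-1.0)

    def test_short_arm_is_single_low_resolution_segment(self):
        cfg = CallerConfig(min_seg_bins=5)
        segs = segment_arm(np.array([0.1, 0.2, 0.3]), np.full(3, 0.1), cfg)
        assert len(segs) == 1 and segs[0].low_resolution

    def test_segments_partition_the_arm(self):
        cfg = CallerConfig(min_seg_bins=3, split_alpha=0.05)
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.2, 80)
        x[30:] -= 1.0
        segs = segment_arm(x, np.full(80, 0.2), cfg)
        bounds = [(s.start, s.end) for s in segs]
        assert bounds[0][0] == 0 and bounds[-1][1] == 80
        for (a, b), (c, d) in zip(bounds, bounds[1:]):
            assert b == c
        assert all(s.n_bins >= 3 for s in segs)

    def test_matches_exhaustive_oracle_on_small_instances(self):
        cfg = CallerConfig(min_seg_bins=2, split_alpha=0.05)
        rng = np.random.default_rng(123)
        for i in range(250):
            n = int(rng.integers(8, 13))
            x = rng.normal(0, 0.3, n)
            if rng.random() < 0.6:
                b = int(rng.integers(2, n - 1))
                x[b:] += rng.choice([-1, 1]) * rng.uniform(0.5, 2.0)
            mine = [(s.start, s.end) for s in segment_arm(x, np.full(n, 0.3), cfg)]
            assert mine == oracle_segments(x, 2, 0.05), f"instance {i}"


class TestCallSegment:
    @pytest.mark.parametrize(
        "mean, z, expected",
        [
            (0.40, 10, "gain"),          # boundary inclusive
            (0.41, 10, "gain"),
            (-1.50, 10, "homozygous-loss"),
            (-1.49, 10, "loss"),
            (-0.40, 10, "loss"),
            (-0.39, 1.0, "neutral"),
            (-0.39, 8.0, "faint-loss"),
            (0.18, 8.0, "faint-gain"),
            (0.0, 0.0, "neutral"),
        ],
    )
    def test_threshold_states(self, mean, z, expected):
        assert call_segment(_seg(mean, z=z), CallerConfig()) == expected

    def test_config_validates_threshold_ordering(self):
        with pytest.raises(ValueError):
            CallerConfig(call_threshold=2.0, hom_loss_threshold=-1.5)


class TestLabelPositions:
    def test_loss_and_gain_on_q_arm_proximal_distal(self):
        segs = [Segment("17q", 0, 40, -0.6, 40, -9), Segment("17q", 40, 80, 0.6, 40, 9)]
        labeled = label_positions("17q", segs, ["loss", "gain"], CallerConfig())
        assert [(st, lb) for _, st, lb in labeled] == [
            ("loss", "proximal"), ("gain", "distal")
        ]

    def test_p_arm_orientation_reversed(self):
        # on a p arm the centromere is at the high-coordinate end
        segs = [Segment("17p", 0, 40, -0.6, 40, -9), Segment("17p", 40, 80, 0.6, 40, 9)]
        labeled = label_positions("17p", segs, ["loss", "gain"], CallerConfig())
        assert [(st, lb) for _, st, lb in labeled] == [
            ("loss", "distal"), ("gain", "proximal")
        ]

    def test_two_same_sign_segments_still_labeled(self):
        segs = [Segment("3q", 0, 40, 0.5, 40, 9), Segment("3q", 40, 80, 0.9, 40, 9)]
        labeled = label_positions("3q", segs, ["gain", "gain"], CallerConfig())
        assert [lb for _, _, lb in labeled] == ["proximal", "distal"]

    def test_single_full_arm_call_is_whole(self):
        segs = [Segment("5q", 0, 100, -0.8, 100, -9)]
        labeled = label_positions("5q", segs, ["loss"], CallerConfig())
        assert labeled[0][2] == "whole"

    def test_partial_arm_call_is_unlabeled(self):
        segs = [Segment("5q", 0, 30, -0.8, 30, -9), Segment("5q", 30, 100, 0.0, 70, 0)]
        labeled = label_positions("5q", segs, ["loss", "neutral"], CallerConfig())
        assert labeled[0][2] == ""


class TestEndToEnd:
    def test_isolated_5q_deletion_yields_single_whole_arm_loss(
        self, bins200, genome, reference200
    ):
        sim = SimSample(
            "del5q", [SimEvent(chrom="5", arm="q", tumor_copies=1)],
            tumor_fraction=0.97, noise_sigma=0.1, seed=3,
        )
        depths = simulate_sample(bins200, sim, reference200, genome)
        result = call_sample(bins200, genome, depths, reference200, vaf=0.485)
        called = result.called()
        assert len(called) == 1
        e = called[0]
        assert (e.scope, e.location, e.direction, e.position_label) == (
            "arm", "5q", "loss", "whole",
        )
        assert result.detectability == "clear"

    def test_normal_sample_calls_nothing(self, bins200, genome, reference200):
        sim = SimSample("nrm", [], noise_sigma=0.15, seed=5)
        depths = simulate_sample(bins200, sim, reference200, genome)
        result = call_sample(bins200, genome, depths, reference200)
        assert result.called() == []

    def test_whole_chromosome_promotion_to_monosomy(
        self, bins200, genome, reference200
    ):
        sim = SimSample(
            "mono7", [SimEvent(chrom="7", tumor_copies=1)],
            tumor_fraction=0.9, noise_sigma=0.1, seed=11,
        )
        depths = simulate_sample(bins200, sim, reference200, genome)
        result = call_sample(bins200, genome, depths, reference200)
        promoted = [e for e in result.called() if e.scope == "whole-chromosome"]
        assert len(promoted) == 1 and promoted[0].klass == "monosomy"
        assert not any(e.location in ("7p", "7q") for e in result.events)

    def test_acrocentric_q_gain_promotes_to_trisomy(
        self, bins200, genome, reference200
    ):
        sim = SimSample(
            "tri13", [SimEvent(chrom="13", arm="q", tumor_copies=3)],
            tumor_fraction=1.0, noise_sigma=0.1, seed=13,
        )
        depths = simulate_sample(bins200, sim, reference200, genome)
        result = call_sample(bins200, genome, depths, reference200)
        promoted = [e for e in result.called() if e.scope == "whole-chromosome"]
        assert len(promoted) == 1 and promoted[0].klass == "trisomy"

    def test_dilute_trisomy_is_faint_not_called(self, bins200, genome, reference200):
        # expected log2 of a trisomy at f=0.26 is 0.176, under the 0.4 cut
        sim = SimSample(
            "tri8", [SimEvent(chrom="8", tumor_copies=3)],
            tumor_fraction=0.26, noise_sigma=0.15, seed=17,
        )
        depths = simulate_sample(bins200, sim, reference200, genome)
        result = call_sample(bins200, genome, depths, reference200, vaf=0.13)
        assert result.called() == []
        faint = [e for e in result.events if e.tier == "faint"]
        assert any(e.chrom == "8" and e.direction == "gain" for e in faint)
        assert result.detectability == "clear"

    def test_tier_never_demotes_as_fraction_rises(self, bins40, genome, reference40):
        rank = {"absent": 0, "faint": 1, "called": 2}
        best = 0
        for f in (0.2, 0.4, 0.6, 0.8, 1.0):
            sim = SimSample(
                f"f{f}", [SimEvent(chrom="5", arm="q", tumor_copies=1)],
                tumor_fraction=f, noise_sigma=0.1, seed=23,
            )
            depths = simulate_sample(bins40, sim, reference40, genome)
            result = call_sample(bins40, genome, depths, reference40)
            tier = "absent"
            for e in result.events:
                if e.chrom == "5" and e.direction == "loss":
                    tier = max(tier, e.tier, key=lambda t: rank[t])
            assert rank[tier] >= best
            best = rank[tier]

    def test_determinism(self, bins40, genome, reference40):
        sim = SimSample(
            "det", [SimEvent(chrom="7", tumor_copies=1)],
            tumor_fraction=0.9, noise_sigma=0.15, seed=29,
        )
        depths = simulate_sample(bins40, sim, reference40, genome)
        a = call_sample(bins40, genome, depths, reference40)
        b = call_sample(bins40, genome, depths, reference40)
        assert a.events == b.events and a.segments == b.segments


class TestGeneAmplification:
    def _profile(self, genome, focal_log2, arm_log2):
        from liquidcnv import make_panel
        from liquidcnv.caller import Log2Profile

        genes, bins = make_panel(60, genome, seed=41)
        target = next(g for g in genes if g.arm.name == "11q")
        values = np.zeros(len(bins))
        for i, b in enumerate(bins):
            if b.chrom == "11" and b.start >= target.arm.start:
                values[i] = arm_log2
            if b.gene == target.symbol:
                values[i] = focal_log2
        prof = Log2Profile("s", values, np.full(len(bins), 0.1))
        return prof, bins, target

    def test_focal_high_copy_gene_detected(self, genome):
        prof, bins, target = self._profile(genome, focal_log2=2.0, arm_log2=0.1)
        events = detect_gene_amplification(prof, bins, genome, CallerConfig())
        assert [e.location for e in events] == [target.symbol]
        assert events[0].klass == "amplification"

    def test_gene_riding_an_arm_gain_is_not_amplification(self, genome):
        prof, bins, _ = self._profile(genome, focal_log2=0.5, arm_log2=0.45)
        assert detect_gene_amplification(prof, bins, genome, CallerConfig()) == []

    def test_simulated_eight_copy_focal_event_recovered(self, genome):
        # expected_log2(8, 0.8) = log2(3.4) = 1.77, over the 1.0 threshold
        from liquidcnv import make_panel, simulate_reference_pool

        genes, bins = make_panel(60, genome, seed=41)
        target = next(g for g in genes if g.arm.name == "11q")
        ref = simulate_reference_pool(bins, 20, 500, 0.1, seed=43)
        sim = SimSample(
            "amp", [SimEvent(chrom="11", gene=target.symbol, tumor_copies=8)],
            tumor_fraction=0.8, noise_sigma=0.1, seed=47,
        )
        depths = simulate_sample(bins, sim, ref, genome)
        result = call_sample(bins, genome, depths, ref)
        amps = [e for e in result.events if e.klass == "amplification"]
        assert [e.location for e in amps] == [target.symbol]
        assert amps[0].mean_log2 == pytest.approx(math.log2(3.4), abs=0.15)
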