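from __future__ import annotations

import numpy as np
import pytest

from broadcna import calling, synthcohort
from broadcna.calling import (
    AlterationCall,
    BaselineEstimate,
    SampleThresholds,
    ThresholdOffsets,
    approximate_baseline,
    arm_binary_events,
    call_alterations,
    call_broad_cnas,
    call_cohort,
    derive_global_offsets,
    sample_thresholds,
)
from broadcna.segio import Segment, SegmentedProfile, ValidationError

from conftest import single_chrom_profile
from oracles import baseline_by_enumeration


class TestApproximateBaseline:
    def test_constant_profile(self):
        profile = single_chrom_profile([(40, 0.2), (30, 0.2), (30, 0.2)])
        est = approximate_baseline(profile)
        assert est.baseline == pytest.approx(0.2)
        assert est.baseline_sd == 0.0

    def test_single_segment(self):
        profile = single_chrom_profile([(100, 0.37)])
        est = approximate_baseline(profile)
        assert est.baseline == pytest.approx(0.37)
        assert est.baseline_sd == 0.0
        assert est.covered_fraction == 1.0

    def test_worked_example(self):
        # (40 Mb, 0.01), (30 Mb, 0.00), (20 Mb, 0.52), (10 Mb, -0.45):
        # the 70 Mb near-zero pair is the minimum-SD majority group
        profile = single_chrom_profile(
            [(40, 0.01), (30, 0.00), (20, 0.52), (10, -0.45)]
        )
        est = approximate_baseline(profile)
        assert est.baseline == pytest.approx((40 * 0.01 + 30 * 0.0) / 70)
        assert set(est.member_segments) == {0, 1}

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_enumeration_oracle_small_profiles(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 13))
        lengths_mb = rng.uniform(1, 60, n)
        heights = np.round(rng.normal(0, 0.3, n), 4)
        profile = single_chrom_profile(list(zip(lengths_mb, heights)))
        est = approximate_baseline(profile)
        lengths = [s.length_bp for s in profile.segments]
        mean, sd, _ = baseline_by_enumeration(lengths, heights)
        assert est.baseline_sd == pytest.approx(sd, abs=1e-9)
        assert est.baseline == pytest.approx(mean, abs=1e-9)

    def test_heuristic_path_near_optimal_on_clustered_profiles(self):
        # above the exact-enumeration cutoff the contiguous-run search must
        # still land on the baseline cluster
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_base, n_alt = 14, 6
            base = [(float(rng.uniform(20, 60)), float(rng.normal(0, 0.03)))
                    for _ in range(n_base)]
            alt = [(float(rng.uniform(1, 15)),
                    float(rng.choice([-1, 1]) * rng.uniform(0.3, 1.0)))
                   for _ in range(n_alt)]
            profile = single_chrom_profile(base + alt)
            est = approximate_baseline(profile)  # n=20 -> run search
            true_mean = np.average([h for _, h in base],
                                   weights=[l for l, _ in base])
            assert abs(est.baseline - true_mean) < 0.03
            assert est.covered_fraction >= 0.51

    def test_covered_fraction_respects_majority(self):
        profile = single_chrom_profile([(30, 0.0), (30, 0.01), (40, 0.5)])
        est = approximate_baseline(profile, majority_fraction=0.51)
        assert est.covered_fraction >= 0.51


class TestGlobalOffsets:
    @staticmethod
    def panel(heights, length_mb=10):
        return [
            single_chrom_profile([(length_mb, h)], sample_id=f"N{i}")
            for i, h in enumerate(heights)
        ]

    def test_offsets_by_direct_arithmetic(self):
        heights = [-0.08, -0.02, 0.0, 0.02, 0.08]
        offsets = derive_global_offsets(self.panel(heights))
        # independent arithmetic: collection baseline is the central tight
        # trio's weighted mean (0.0); SD over all five retained heights
        sd = float(np.std(heights))
        assert offsets.collection_baseline == pytest.approx(0.0)
        assert offsets.gain_offset == pytest.approx(0.08 + sd)
        assert offsets.loss_offset == pytest.approx(0.08 + sd)
        assert offsets.n_segments_used == 5

    def test_extreme_outlier_does_not_change_offsets(self):
        heights = [-0.08, -0.02, 0.0, 0.02, 0.08]
        base = derive_global_offsets(self.panel(heights))
        spiked = derive_global_offsets(self.panel(heights + [5.0]))
        assert spiked.gain_offset == pytest.approx(base.gain_offset)
        assert spiked.loss_offset == pytest.approx(base.loss_offset)

    def test_degenerate_panel_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            derive_global_offsets(self.panel([0.1] * 6))

    def test_short_segments_ignored(self):
        # sub-broad segments must not enter the pool
        profiles = self.panel([-0.05, 0.0, 0.05])
        profiles.append(single_chrom_profile([(2, 9.9)], sample_id="N9"))
        offsets = derive_global_offsets(profiles)
        assert offsets.n_segments_used == 3

    def test_empty_pool_rejected(self):
        with pytest.raises(ValidationError, match="normal panel"):
            derive_global_offsets(self.panel([0.0], length_mb=1))


class TestSampleThresholds:
    def test_stated_arithmetic(self):
        est = BaselineEstimate("S1", baseline=0.02, baseline_sd=0.01,
                               member_segments=(0,), covered_fraction=1.0)
        offsets = ThresholdOffsets(0.11, 0.11, 0.0, 0.03, 5)
        thr = sample_thresholds(est, offsets)
        assert thr.gain_threshold == pytest.approx(0.14)
        assert thr.loss_threshold == pytest.approx(-0.10)

    def test_zero_sd_gives_baseline_plus_offsets(self):
        est = BaselineEstimate("S1", 0.05, 0.0, (0,), 1.0)
        offsets = ThresholdOffsets(0.2, 0.1, 0.0, 0.0, 3)
        thr = sample_thresholds(est, offsets)
        assert thr.gain_threshold == pytest.approx(0.25)
        assert thr.loss_threshold == pytest.approx(-0.05)

    def test_symmetric_offsets_symmetric_thresholds(self):
        est = BaselineEstimate("S1", 0.0, 0.02, (0,), 1.0)
        offsets = ThresholdOffsets(0.15, 0.15, 0.0, 0.0, 3)
        thr = sample_thresholds(est, offsets)
        assert thr.gain_threshold == pytest.approx(-thr.loss_threshold)


class TestCallAlterations:
    def test_all_within_thresholds_gives_no_calls(self, flat_arm_map):
        profile = single_chrom_profile([(40, 0.1), (60, -0.1)])
        thr = SampleThresholds(0.3, -0.3, 0.0)
        assert call_alterations(profile, thr, flat_arm_map) == []

    def test_split_and_merge_worked_example(self, flat_arm_map):
        # heights [0, 0.5, 0.35, -0.4, 0] on one arm; thresholds +-0.3:
        # extreme 0.5, adjacent gains differ by 0.15 >= 0.125 -> split
        profile = single_chrom_profile(
            [(20, 0.0), (10, 0.5), (10, 0.35), (10, -0.4), (20, 0.0)]
        )
        thr = SampleThresholds(0.3, -0.3, 0.0)
        calls = call_alterations(profile, thr, flat_arm_map)
        assert len(calls) == 3
        assert [c.direction for c in calls] == ["gain", "gain", "loss"]
        assert calls[0].mean_height == pytest.approx(0.5)
        assert calls[1].mean_height == pytest.approx(0.35)

    def test_adjacent_similar_gains_merge(self, flat_arm_map):
        profile = single_chrom_profile([(20, 0.0), (10, 0.50), (10, 0.45)])
        thr = SampleThresholds(0.3, -0.3, 0.0)
        calls = call_alterations(profile, thr, flat_arm_map)
        assert len(calls) == 1
        assert calls[0].mean_height == pytest.approx(0.475)
        assert calls[0].length_bp == 20_000_000

    def test_clonality_filter_drops_weak_call(self, flat_arm_map):
        profile = single_chrom_profile([(30, 0.8), (10, 0.0), (30, 0.09)])
        thr = SampleThresholds(0.05, -0.05, 0.0)
        calls = call_alterations(profile, thr, flat_arm_map)
        assert len(calls) == 1
        assert calls[0].mean_height == pytest.approx(0.8)

    def test_runs_do_not_merge_across_arms(self, flat_arm_map):
        profile = single_chrom_profile(
            [(100, 0.5), (100, 0.5)], start=1  # 1..100Mb (p), 100..200Mb (q)
        )
        thr = SampleThresholds(0.3, -0.3, 0.0)
        calls = call_alterations(profile, thr, flat_arm_map)
        assert len(calls) == 2
        assert {c.arm for c in calls} == {"p", "q"}

    def test_intervening_baseline_segment_breaks_run(self, flat_arm_map):
        profile = single_chrom_profile([(30, 0.5), (10, 0.0), (30, 0.5)])
        thr = SampleThresholds(0.3, -0.3, 0.0)
        assert len(call_alterations(profile, thr, flat_arm_map)) == 2

    def test_deviation_measured_from_baseline(self, flat_arm_map):
        profile = single_chrom_profile([(40, 0.6), (60, 0.1)])
        thr = SampleThresholds(0.4, -0.2, 0.1)
        (call,) = call_alterations(profile, thr, flat_arm_map)
        assert call.deviation == pytest.approx(0.5)


class TestBroadCalls:
    @staticmethod
    def alteration(start, end, direction="gain"):
        return AlterationCall("S1", "1", "q", start, end, direction,
                              0.5 if direction == "gain" else -0.5,
                              0.5 if direction == "gain" else -0.5)

    def test_exactly_three_mb_is_not_broad(self):
        calls, count = call_broad_cnas([self.alteration(1, 3_000_000)])
        assert calls == [] and count == 0

    def test_three_mb_plus_one_is_broad(self):
        calls, count = call_broad_cnas([self.alteration(1, 3_000_001)])
        assert count == 1
        assert calls[0].length_bp == 3_000_001

    def test_same_arm_double_event_counts_twice_binarizes_once(self):
        alts = [
            self.alteration(1, 10_000_000),
            self.alteration(20_000_000, 40_000_000),
        ]
        calls, count = call_broad_cnas(alts)
        assert count == 2
        assert len(arm_binary_events(calls)) == 1


class TestCohortRecovery:
    def test_recovery_on_staged_cohort(self, staged_cohort_small):
        cfg, tumors, normals, _, truth, _ = staged_cohort_small
        results = call_cohort(tumors, normals, cfg.arm_map)
        tp = fp = fn = 0
        for pid, tr in truth.patients.items():
            called = results[f"{pid}-T"].events
            true = frozenset(tr.events)
            tp += len(called & true)
            fp += len(called - true)
            fn += len(true - called)
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.95

    def test_baseline_recovery_on_staged_cohort(self, staged_cohort_small):
        cfg, tumors, normals, _, truth, _ = staged_cohort_small
        results = call_cohort(tumors, normals, cfg.arm_map)
        errors = [
            abs(results[f"{pid}-T"].baseline.baseline - tr.baseline)
            for pid, tr in truth.patients.items()
        ]
        assert float(np.mean(errors)) <= 0.02

    def test_recall_monotone_in_purity(self):
        recalls = []
        for purity in (0.2, 0.35, 0.5, 0.65, 0.8):
            cfg = synthcohort.GeneratorConfig(
                n_patients=40, seed=77, n_normals=15,
                purity_range=(purity, purity),
            )
            tumors, normals, _, truth = synthcohort.generate_cohort(cfg)
            results = call_cohort(tumors, normals, cfg.arm_map)
            tp = fn = 0
            for pid, tr in truth.patients.items():
                called = results[f"{pid}-T"].events
                true = frozenset(tr.events)
                tp += len(called & true)
                fn += len(true - called)
            recalls.append(tp / max(tp + fn, 1))
        assert all(b >= a - 1e-12 for a, b in zip(recalls, recalls[1:]))
        assert recalls[-1] > recalls[0]

    def test_calls_invariant_to_global_height_shift(self):
        cfg = synthcohort.GeneratorConfig(n_patients=10, seed=3, n_normals=10)
        tumors, normals, _, _ = synthcohort.generate_cohort(cfg)

        def shift(profiles, c):
            return [
                SegmentedProfile(
                    p.sample_id,
                    [Segment(s.chromosome, s.start_bp, s.end_bp, s.height + c,
                             s.num_probes) for s in p.segments],
                    sample_type=p.sample_type,
                )
                for p in profiles
            ]

        base = call_cohort(tumors, normals, cfg.arm_map)
        shifted = call_cohort(shift(tumors, 0.37), shift(normals, 0.37), cfg.arm_map)
        for sid in base:
            assert base[sid].events == shifted[sid].events
            assert base[sid].broad_count == shifted[sid].broad_count
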