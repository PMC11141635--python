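import numpy as np
import pandas as pd
import pytest

from complexdep import (
    curate_peaks,
    differential_regions,
    generate_region_fixture,
    merge_condition_peaks,
    spikein_scale_factors,
)


class TestSpikeinScaleFactors:
    def test_printed_formula_forced_values(self):
        f = spikein_scale_factors(pd.Series([100.0, 300.0], index=["a", "b"]))
        assert f["a"] == pytest.approx(2.0)
        assert f["b"] == pytest.approx(2.0 / 3.0)

    def test_equal_counts_give_unit_factors(self):
        f = spikein_scale_factors(pd.Series([500.0] * 4, index=list("abcd")))
        np.testing.assert_allclose(f, 1.0)

    def test_single_sample_factor_is_one(self):
        assert spikein_scale_factors(pd.Series([123.0], index=["a"]))["a"] == 1.0

    def test_scaling_equalizes_totals_to_pre_scaling_mean(self):
        counts = pd.Series([120.0, 80.0, 200.0, 55.0], index=list("abcd"))
        f = spikein_scale_factors(counts)
        np.testing.assert_allclose(counts * f, counts.mean())

    def test_zero_count_names_the_sample(self):
        with pytest.raises(ValueError, match="b"):
            spikein_scale_factors(pd.Series([10.0, 0.0], index=["a", "b"]))


def _regions(aucs, starts=None):
    n = len(aucs)
    starts = starts if starts is not None else np.arange(n) * 1000
    return pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 500,
         "name": [f"r{i}" for i in range(n)], "auc": aucs}
    )


class TestCuratePeaks:
    def test_auc_boundary_log2_rule(self):
        # log2(8191 + 1) == 13 exactly -> retained; 8190 falls below
        t = _regions([8191.0, 8190.0])
        out, counts = curate_peaks(t)
        assert list(out["name"]) == ["r0"]
        assert counts == {"low_auc": 1, "blacklist": 0, "retained": 1}

    def test_single_bp_blacklist_overlap_removes(self):
        t = _regions([10**6, 10**6], starts=np.array([0, 1000]))
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [499], "end": [500]})
        out, counts = curate_peaks(t, blacklist=bl)
        assert list(out["name"]) == ["r1"]
        assert counts["blacklist"] == 1

    def test_adjacent_blacklist_interval_does_not_remove(self):
        # half-open: blacklist [500, 600) touches region [0, 500) at no base
        t = _regions([10**6])
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600]})
        out, _ = curate_peaks(t, blacklist=bl)
        assert len(out) == 1

    def test_idempotent_and_bookkeeping_sums(self):
        rng = np.random.default_rng(0)
        t = _regions(rng.uniform(0, 2**14, size=20))
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [2500], "end": [3600]})
        out, counts = curate_peaks(t, blacklist=bl)
        assert counts["low_auc"] + counts["blacklist"] + counts["retained"] == len(t)
        again, counts2 = curate_peaks(out, blacklist=bl)
        pd.testing.assert_frame_equal(again, out)
        assert counts2["low_auc"] == 0 and counts2["blacklist"] == 0


class TestMergeConditionPeaks:
    def test_overlapping_intervals_merge(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [150]})
        m = merge_condition_peaks(a, b)
        assert list(m[["start", "end"]].iloc[0]) == [0, 150]

    def test_touching_intervals_merge_disjoint_stay(self):
        a = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 20], "end": [10, 30]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [15]})
        m = merge_condition_peaks(a, b)
        assert m[["start", "end"]].to_numpy().tolist() == [[0, 15], [20, 30]]

    def test_idempotence(self):
        a = pd.DataFrame({"chrom": ["chr2", "chr1"], "start": [5, 0], "end": [9, 7]})
        once = merge_condition_peaks(a, a)
        twice = merge_condition_peaks(once)
        pd.testing.assert_frame_equal(once, twice)


class TestDifferentialRegions:
    def test_identical_conditions_not_significant(self):
        fx = generate_region_fixture(5, 3, 3, noise=False, seed=0)
        calls = differential_regions(fx.counts, fx.groups, fx.aucs)
        assert all(c.call == "not_significant" and c.delta == 0 for c in calls)

    def test_fold_change_four_classified_increase(self):
        fx = generate_region_fixture(8, 3, 3, effect_regions={2: 4.0},
                                     baseline_mean=1000, noise=False, seed=1)
        calls = {c.region: c for c in differential_regions(fx.counts, fx.groups, fx.aucs)}
        assert calls["region_0002"].call == "increase"
        assert calls["region_0002"].delta == pytest.approx(2.0, abs=0.01)
        assert all(c.call == "not_significant"
                   for r, c in calls.items() if r != "region_0002")

    def test_decrease_called_symmetrically(self):
        fx = generate_region_fixture(6, 3, 3, effect_regions={0: 0.25},
                                     baseline_mean=2000, noise=False, seed=2)
        calls = {c.region: c for c in differential_regions(fx.counts, fx.groups, fx.aucs)}
        assert calls["region_0000"].call == "decrease"

    def test_delta_gate_binds_even_at_tiny_p(self):
        # strong count evidence but |delta| < 1.5 must stay not_significant
        fx = generate_region_fixture(4, 3, 3, effect_regions={1: 2.0},
                                     baseline_mean=5000, noise=False, seed=3)
        calls = {c.region: c for c in differential_regions(fx.counts, fx.groups, fx.aucs)}
        c = calls["region_0001"]
        assert abs(c.delta) == pytest.approx(1.0, abs=0.01)
        assert c.p < 0.01
        assert c.call == "not_significant"

    def test_nb_lrt_p_against_exact_permutation_oracle(self):
        """On a noisy 3v3 design the LRT p for a real effect should land in
        the same decision band as the exact 20-relabeling permutation p."""
        fx = generate_region_fixture(30, 3, 3, effect_regions={0: 4.0},
                                     baseline_mean=1000, dispersion=0.05, seed=7)
        lrt = {c.region: c for c in differential_regions(fx.counts, fx.groups, fx.aucs)}
        perm = {c.region: c for c in differential_regions(
            fx.counts, fx.groups, fx.aucs, method="permutation")}
        # effect region: both routes call it significant at the 0.10 gate
        assert lrt["region_0000"].p <= 0.10
        assert perm["region_0000"].p <= 0.10  # 1/20 = 0.05 at best
        assert lrt["region_0000"].call == perm["region_0000"].call == "increase"

    def test_null_fixture_false_call_rate_bounded(self):
        fx = generate_region_fixture(300, 3, 3, dispersion=0.05, seed=11)
        calls = differential_regions(fx.counts, fx.groups, fx.aucs)
        frac = np.mean([c.call != "not_significant" for c in calls])
        assert frac <= 0.10 + 0.05  # p gate + Monte-Carlo slack; delta gate binds harder

    def test_all_zero_region_returns_p_one(self):
        fx = generate_region_fixture(3, 2, 2, noise=False, seed=0)
        counts = fx.counts.copy()
        counts.iloc[0] = 0.0
        aucs = fx.aucs.copy()
        aucs.iloc[0] = 0.0
        calls = differential_regions(counts, fx.groups, aucs)
        assert calls[0].p == 1.0 and calls[0].call == "not_significant"

    def test_scale_factors_absorb_depth_differences(self):
        fx = generate_region_fixture(10, 2, 2, baseline_mean=1000, noise=False, seed=4)
        counts = fx.counts.copy()
        # double one treated sample's depth; matching spike-in factor 0.5
        counts["treated_0"] *= 2.0
        factors = pd.Series(1.0, index=counts.columns)
        factors["treated_0"] = 0.5
        calls = differential_regions(counts, fx.groups, fx.aucs, scale_factors=factors)
        assert all(c.call == "not_significant" for c in calls)

    def test_requires_exactly_two_conditions_with_replicates(self):
        fx = generate_region_fixture(3, 2, 2, seed=0)
        with pytest.raises(ValueError):
            differential_regions(fx.counts, {"only": fx.groups["treated"]}, fx.aucs)
        with pytest.raises(ValueError, match="zero replicates"):
            differential_regions(fx.counts, {"a": fx.groups["treated"], "b": []}, fx.aucs)
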