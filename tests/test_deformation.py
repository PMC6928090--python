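"""Top/bottom deformation, hill/valley categories and their oracles."""

import numpy as np
import pytest
from scipy import stats

import memdeform as md
from memdeform.deformation import (
    CATEGORIES,
    classify_cells,
    cumulative_category_distribution,
    deformation_time_series,
    skewness_trend,
    top_bottom_deformation,
)
from memdeform.heightmap import height_maps_series

from conftest import make_map


def brute_force_top_bottom(values, k):
    ordered = sorted(values)
    return sum(ordered[-k:]) / k, sum(ordered[:k]) / k


def brute_force_classify(values, t1=4.0, t2=8.0):
    hbar = sum(values) / len(values)
    hills = {c: 0 for c in CATEGORIES}
    valleys = {c: 0 for c in CATEGORIES}
    zero = 0
    for h in values:
        dev = h - hbar
        if dev == 0:
            zero += 1
            continue
        cat = "I" if abs(dev) >= t2 else ("II" if abs(dev) >= t1 else "III")
        (hills if dev > 0 else valleys)[cat] += 1
    return hills, valleys, zero


class TestTopBottom:
    def test_uniform_map_zero_deformation(self):
        rec = top_bottom_deformation(make_map([5.0] * 12), k=5)
        assert rec.deformation == 0.0

    def test_enumeration_1_to_20(self):
        rec = top_bottom_deformation(make_map(np.arange(1.0, 21.0)), k=5)
        assert rec.top == 18.0
        assert rec.bottom == 3.0
        assert rec.deformation == 15.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_oracle(self, seed, random_map):
        hm = random_map(np.random.default_rng(seed))
        rec = top_bottom_deformation(hm, k=5)
        top, bottom = brute_force_top_bottom(list(hm.valid_heights()), 5)
        assert rec.top == pytest.approx(top, rel=1e-12)
        assert rec.bottom == pytest.approx(bottom, rel=1e-12)

    def test_too_few_valid_cells_raises(self):
        with pytest.raises(ValueError, match="3 valid cells but k=5"):
            top_bottom_deformation(make_map([1.0, 2.0, 3.0]), k=5)

    def test_deformation_non_increasing_in_k(self, random_map):
        hm = random_map(np.random.default_rng(8))
        defs = [top_bottom_deformation(hm, k=k).deformation for k in (1, 3, 5, 10, 20)]
        assert all(a >= b for a, b in zip(defs, defs[1:]))

    def test_invariant_to_constant_shift(self, random_map):
        hm = random_map(np.random.default_rng(4))
        shifted = make_map(hm.valid_heights() + 123.4, nx=hm.grid.nx, ny=hm.grid.ny)
        a = top_bottom_deformation(hm, k=5).deformation
        b = top_bottom_deformation(shifted, k=5).deformation
        assert a == pytest.approx(b, abs=1e-9)

    def test_skewness_is_adjusted_fisher_pearson(self, random_map):
        hm = random_map(np.random.default_rng(6))
        rec = top_bottom_deformation(hm, k=5)
        assert rec.skewness == pytest.approx(stats.skew(hm.valid_heights(), bias=False))


class TestClassification:
    def test_hill_category_I(self):
        # one cell 9 Å above the rest's mean pulls itself into Category I
        hm = make_map([0.0] * 30 + [9.3 * 31 / 30], nx=8, ny=4)
        tally = classify_cells(hm)
        assert tally.hills["I"] == 1

    def test_threshold_boundaries(self):
        # deviations engineered around a zero-mean set
        vals = [9.0, -5.0, 2.0, -6.0]  # mean 0 → devs are the values
        tally = classify_cells(make_map(vals))
        assert tally.hills == {"I": 1, "II": 0, "III": 1}
        assert tally.valleys == {"I": 0, "II": 2, "III": 0}

    def test_exact_mean_counts_separately_as_valley_label(self):
        vals = [2.0, 2.0, 2.0]
        tally = classify_cells(make_map(vals))
        assert tally.zero_deviation == 3
        assert tally.n_hills == 0 and tally.n_valleys == 0
        assert all("valley" in s for s in tally.labels.ravel() if s)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed, random_map):
        hm = random_map(np.random.default_rng(100 + seed), sigma=6.0)
        tally = classify_cells(hm)
        hills, valleys, zero = brute_force_classify(list(hm.valid_heights()))
        assert tally.hills == hills
        assert tally.valleys == valleys
        assert tally.zero_deviation == zero
        assert tally.n_hills + tally.n_valleys + tally.zero_deviation == tally.n_valid

    def test_normal_heights_category_I_fraction(self):
        # closed-form check of the threshold wiring: P(|dev| >= 8) = 2Φ(−8/σ)
        rng = np.random.default_rng(12)
        sigma, n, frames = 6.0, 4500, 25
        count_I = total = 0
        for _ in range(frames):
            hm = make_map(rng.normal(0.0, sigma, n), nx=50, ny=90)
            t = classify_cells(hm)
            count_I += t.hills["I"] + t.valleys["I"]
            total += t.n_valid
        expected = 2 * stats.norm.cdf(-8.0 / sigma)
        mc_err = 4 * np.sqrt(expected * (1 - expected) / total)
        assert abs(count_I / total - expected) < mc_err


class TestCumulativeDistribution:
    def test_single_frame_all_cat_III_valleys(self):
        tally = classify_cells(make_map([-1.0, -2.0, -3.0, 6.0]))
        dist = cumulative_category_distribution([tally])
        assert np.allclose(dist["valleys"], (0.0, 0.0, 1.0))

    def test_two_frame_hand_count(self):
        # hills (1, 1, 2) then (0, 0, 4): pooled hill dist = (1/8, 1/8, 6/8)
        from memdeform.deformation import CategoryTally
        a = CategoryTally(hills={"I": 1, "II": 1, "III": 2},
                          valleys={"I": 0, "II": 0, "III": 0},
                          zero_deviation=0, thresholds=(4, 8), n_valid=4)
        b = CategoryTally(hills={"I": 0, "II": 0, "III": 4},
                          valleys={"I": 0, "II": 0, "III": 0},
                          zero_deviation=0, thresholds=(4, 8), n_valid=4)
        dist = cumulative_category_distribution([a, b])
        assert np.allclose(dist["hills"], (0.125, 0.125, 0.75))

    def test_pooled_equals_frame_mean_at_constant_counts(self, random_map):
        rng = np.random.default_rng(17)
        tallies = [classify_cells(random_map(rng)) for _ in range(6)]
        # constant n_valid and (here) equal per-frame side totals not guaranteed,
        # so check the algebraic identity on frames with equal hill counts
        pooled = cumulative_category_distribution(tallies, mode="pooled")
        per_frame = cumulative_category_distribution(tallies, mode="per_frame")
        weights = np.array([t.n_hills for t in tallies], dtype=float)
        mats = np.array([[t.hills[c] / t.n_hills for c in CATEGORIES] for t in tallies])
        assert np.allclose(pooled["hills"], (weights[:, None] * mats).sum(0) / weights.sum())
        assert np.allclose(per_frame["hills"], mats.mean(axis=0))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no tallies"):
            cumulative_category_distribution([])


class TestTimeSeries:
    def test_constant_deformation_zero_se(self):
        maps = [make_map(np.arange(1.0, 21.0), time=0.1 * i) for i in range(4)]
        _, summary = deformation_time_series(maps, k=5)
        assert summary["mean"] == 15.0
        assert summary["se"] == 0.0

    def test_single_mode_recovers_2A(self):
        params = md.SyntheticParams(
            n_frames=15, seed=0, noise_sigma=0.0, head_density=0.3,
            modes=(md.Mode.from_wavelength(5.0, 80.0, angular_speed=2.0),),
            include_protein=False, bump_amplitude=0.0, with_forces=False)
        traj, _, _ = md.generate(params)
        maps = height_maps_series(traj, "upper")
        _, summary = deformation_time_series(maps, k=5)
        assert abs(summary["mean"] - 10.0) / 10.0 < 0.05

    def test_k_insensitivity_on_noisy_surface(self):
        params = md.SyntheticParams(n_frames=15, seed=3, include_protein=False,
                                    bump_amplitude=0.0, with_forces=False)
        traj, _, _ = md.generate(params)
        maps = height_maps_series(traj, "upper")
        means = [deformation_time_series(maps, k=k)[1]["mean"] for k in (3, 5, 10)]
        assert max(means) / min(means) - 1 < 0.10

    def test_fewer_than_two_frames_raises(self):
        with pytest.raises(ValueError, match="2 frames"):
            deformation_time_series([make_map(np.arange(20.0))])


class TestSkewnessTrend:
    def test_constant_skewness_zero_slope(self):
        recs = [md.DeformationRecord(time=t, top=1, bottom=0, deformation=1,
                                     skewness=0.3, k=5) for t in (0.0, 0.1, 0.2, 0.3)]
        assert skewness_trend(recs)["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_skewness(self):
        recs = [md.DeformationRecord(time=t, top=1, bottom=0, deformation=1,
                                     skewness=0.1 * t, k=5)
                for t in np.arange(0.0, 1.0, 0.1)]
        fit = skewness_trend(recs)
        assert fit["slope"] == pytest.approx(0.1)

    def test_stationary_synthetic_slope_within_2se(self):
        params = md.SyntheticParams(n_frames=60, seed=0, include_protein=False,
                                    bump_amplitude=0.0, with_forces=False)
        traj, _, _ = md.generate(params)
        maps = height_maps_series(traj, "upper")
        recs, _ = deformation_time_series(maps)
        fit = skewness_trend(recs)
        assert abs(fit["slope"]) < 2 * fit["stderr"]

    def test_too_few_records_raises(self):
        with pytest.raises(ValueError, match=">= 3"):
            skewness_trend([md.DeformationRecord(0, 1, 0, 1, 0.0, 5)] * 2)
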