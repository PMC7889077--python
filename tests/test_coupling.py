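import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stgcoupling as sc
from stgcoupling.coupling import (PeriodPair, bonferroni_threshold,
                                  coupling_area, ks_integer_coupling,
                                  pair_periods, ratio_vs_temperature,
                                  shuffle_null, significand_cdf)
from conftest import make_burst_seq


def pairs_from(slow_periods, fast_means, temps=None):
    temps = temps if temps is not None else [11.0] * len(slow_periods)
    return [PeriodPair(s, f, T, "p0")
            for s, f, T in zip(slow_periods, fast_means, temps)]


# ---------------------------------------------------------------- pairing

def test_pairing_integer_ratio_construction():
    fast = make_burst_seq(np.arange(0.0, 25.0, 1.0), period=1.0)
    slow = make_burst_seq([0.2, 10.2, 20.2], period=10.0, neuron="LG")
    pairs = pair_periods(slow, fast)
    assert len(pairs) == 2
    for p in pairs:
        assert p.ratio == pytest.approx(10.0)
        assert p.significand == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("slow_period, expected", [(10.1, 0.1), (9.9, 0.9)])
def test_significand_fractional_part_convention(slow_period, expected):
    """Slow period 10.1 s over fast mean 1 s -> 0.1; 9.9 s -> 0.9."""
    p = PeriodPair(slow_period, 1.0, 11.0, "p0")
    assert p.significand == pytest.approx(expected)


def test_slow_bursts_without_fast_bursts_dropped():
    fast = make_burst_seq([0.0, 1.0, 2.0], period=1.0)   # ends early
    slow = make_burst_seq([0.5, 10.5, 20.5, 30.5], period=10.0, neuron="LG")
    pairs = pair_periods(slow, fast)
    assert len(pairs) == 1  # only the first slow window contains fast starts


def test_disjoint_recordings_give_empty_result(caplog):
    fast = make_burst_seq([100.0, 101.0, 102.0], period=1.0)
    slow = make_burst_seq([0.0, 10.0], period=10.0, neuron="LG")
    with caplog.at_level("WARNING"):
        assert pair_periods(slow, fast) == []


# ---------------------------------------------------------------- c.d.f.

def test_point_mass_cdf_is_step_function():
    cdf = significand_cdf(np.full(20, 0.5), n_boot=10, seed=0)
    assert cdf(0.49) == 0.0 and cdf(0.5) == 1.0


def test_uniform_grid_cdf_tracks_diagonal():
    n = 100
    x = np.arange(1, n + 1) / n
    cdf = significand_cdf(x, n_boot=10, seed=0)
    assert np.max(np.abs(cdf(cdf.grid) - cdf.grid)) <= 1.0 / n + 1e-12


def test_band_contains_point_estimate_and_is_seed_deterministic():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 1, 80)
    a = significand_cdf(x, n_boot=200, seed=9)
    b = significand_cdf(x, n_boot=200, seed=9)
    point = a(a.grid)
    assert np.all(a.band_lower <= point + 1e-12)
    assert np.all(a.band_upper >= point - 1e-12)
    np.testing.assert_array_equal(a.band_lower, b.band_lower)
    np.testing.assert_array_equal(a.band_upper, b.band_upper)


def test_bootstrap_band_covers_uniform_truth():
    """95% pointwise band over a uniform sample covers the diagonal at most
    grid points (Monte-Carlo coverage over seeds)."""
    cover = []
    for seed in range(20):
        x = np.random.default_rng(seed).uniform(0, 1, 100)
        cdf = significand_cdf(x, n_boot=300, level=0.95, seed=seed)
        inner = (cdf.grid >= 0.05) & (cdf.grid <= 0.95)
        ok = (cdf.band_lower[inner] <= cdf.grid[inner]) & \
             (cdf.grid[inner] <= cdf.band_upper[inner])
        cover.append(ok.mean())
    assert np.mean(cover) >= 0.9


def test_cdf_rejects_bad_config():
    with pytest.raises(ValueError):
        significand_cdf(np.array([0.1, 0.2]), n_boot=0)


# ---------------------------------------------------------------- area

def area_oracle(sample, m=2_000_001):
    """Independent check: dense-grid Riemann sum of |F(x) - x|."""
    s = np.sort(sample)
    x = np.linspace(0, 1, m)
    F = np.searchsorted(s, x, side="right") / s.size
    return np.trapezoid(np.abs(F - x), x)


def test_perfect_coupling_area_is_one_quarter():
    eps = 1e-9
    sample = np.concatenate([np.zeros(500), np.full(500, 1 - eps)])
    assert coupling_area(sample) == pytest.approx(0.25, abs=1e-6)


def test_uniform_sample_area_vanishes():
    for n in (10, 1000):
        x = np.arange(1, n + 1) / n
        assert coupling_area(x) == pytest.approx(1 / (2 * n), abs=1e-12)


def test_one_sided_clustering_exceeds_quarter():
    # all significands at 0: integral of (1 - x) = 0.5
    assert coupling_area(np.zeros(100)) == pytest.approx(0.5)
    # clustering at 0.5 also scores 0.25: documented metric limitation
    assert coupling_area(np.full(100, 0.5)) == pytest.approx(0.25)


@given(st.lists(st.floats(0, 1, exclude_max=True), min_size=1, max_size=60))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_area_closed_form_matches_grid_oracle(xs):
    sample = np.asarray(xs)
    assert coupling_area(sample) == pytest.approx(area_oracle(sample), abs=2e-5)
    assert 0.0 <= coupling_area(sample) <= 0.5


# ---------------------------------------------------------------- shuffle null

def test_shuffle_rejects_zero_shuffles():
    with pytest.raises(ValueError):
        shuffle_null(pairs_from([10.1, 9.9], [1.0, 1.0]), n_shuffle=0)


def test_coupled_pairs_exceed_all_null_areas():
    rng = np.random.default_rng(0)
    fast = rng.uniform(0.9, 1.1, 300)
    slow = 10.0 * fast            # exact 10:1 coupling
    areas, null_sample = shuffle_null(pairs_from(slow, fast), n_shuffle=500,
                                      seed=1)
    obs = coupling_area(np.mod(slow / fast, 1.0))
    assert obs > areas.max()
    assert null_sample.size == slow.size


def test_independent_pairs_land_inside_null_band():
    rng = np.random.default_rng(3)
    fast = rng.uniform(0.9, 1.1, 300)
    slow = rng.uniform(8.0, 25.0, 300)
    pairs = pairs_from(slow, fast)
    areas, _ = shuffle_null(pairs, n_shuffle=500, seed=2)
    obs = coupling_area(np.array([p.significand for p in pairs]))
    lo, hi = np.quantile(areas, [0.025, 0.975])
    assert lo <= obs <= hi
    # shuffling preserves the expected area for already-independent pairs
    assert abs(areas.mean() - obs) < 5 * areas.std(ddof=1)


# ---------------------------------------------------------------- KS

def ks_oracle(a, b):
    """Brute-force sup of |F_a - F_b| over all merged sample points."""
    pts = np.concatenate([a, b])
    return max(abs(np.mean(a <= t) - np.mean(b <= t)) for t in pts)


def test_ks_identical_and_disjoint_samples():
    x = np.array([0.1, 0.2, 0.3])
    D, p = ks_integer_coupling(x, x)
    assert D == 0.0 and p == pytest.approx(1.0)
    lo = np.arange(0.01, 0.06, 0.01)
    hi = np.arange(0.51, 0.56, 0.01)
    D, p = ks_integer_coupling(lo, hi)
    assert D == 1.0


@given(st.lists(st.floats(0, 1), min_size=2, max_size=20),
       st.lists(st.floats(0, 1), min_size=2, max_size=20))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_ks_statistic_matches_brute_force(a, b):
    a, b = np.asarray(a), np.asarray(b)
    D, _ = ks_integer_coupling(a, b)
    assert D == pytest.approx(ks_oracle(a, b), abs=1e-12)


def test_ks_rejects_empty_sample():
    with pytest.raises(ValueError):
        ks_integer_coupling(np.array([]), np.array([0.5]))


# ---------------------------------------------------------------- misc stats

def test_bonferroni_thresholds():
    assert bonferroni_threshold(0.05, 9) == pytest.approx(0.05 / 9)
    assert round(bonferroni_threshold(0.05, 9), 4) == 0.0056
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.01, 4) == 0.0025
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
    with pytest.raises(ValueError):
        bonferroni_threshold(1.5, 9)


def test_spearman_monotone_ratios():
    temps = [7, 9, 11, 13, 15, 17]
    slow = [10.0, 10.1, 10.2, 10.3, 10.4, 10.5]
    rho, _ = ratio_vs_temperature(pairs_from(slow, [1.0] * 6, temps))
    assert rho == pytest.approx(1.0)


def test_spearman_midranks_match_hand_ranked_example():
    """Ties on temperature use midranks: checked against an explicit
    rank-then-Pearson computation on a 6-point example."""
    temps = np.array([7.0, 7.0, 11.0, 11.0, 15.0, 15.0])
    ratios = np.array([10.3, 10.1, 10.2, 10.6, 10.4, 10.5])
    rho, _ = ratio_vs_temperature(pairs_from(ratios, np.ones(6), temps))
    rank_T = np.array([1.5, 1.5, 3.5, 3.5, 5.5, 5.5])
    rank_r = np.array([3, 1, 2, 6, 4, 5], dtype=float)
    hand = np.corrcoef(rank_T, rank_r)[0, 1]
    assert rho == pytest.approx(hand, abs=1e-12)


def test_constant_ratios_flagged():
    rho, p = ratio_vs_temperature(pairs_from([10.0] * 4, [1.0] * 4,
                                             [7, 7, 11, 11]))
    assert np.isnan(rho) and np.isnan(p)
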