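import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stgcoupling as sc
from stgcoupling.phase import (PhaseSample, aligned_raster, burst_start_phases,
                               circular_stats, phase_at, rayleigh_test,
                               spike_phase_probability)
from conftest import make_burst_seq, make_train


# ---------------------------------------------------------------- phase_at

def test_phase_linear_within_cycle():
    fast = make_burst_seq([0.0, 1.2, 2.4], period=1.2)
    assert phase_at(0.0, fast)[0] == 0.0
    assert phase_at(0.6, fast)[0] == pytest.approx(0.5)
    assert phase_at(0.3, fast)[0] == pytest.approx(0.25)


def test_phase_undefined_outside_cycles():
    fast = make_burst_seq([1.0, 2.0, 3.0], period=1.0)
    ph = phase_at([0.5, 3.5], fast)
    assert np.isnan(ph).all()


def test_phase_zero_at_every_fast_burst_start():
    starts = np.cumsum(np.random.default_rng(0).uniform(0.8, 1.2, 20))
    fast = make_burst_seq(starts, period=1.0)
    ph = phase_at(starts[:-1], fast)
    np.testing.assert_allclose(ph, 0.0, atol=1e-12)


# ---------------------------------------------------- first-40 truncation

def _locked_pair(n_slow, lock=0.5, slow_every=10):
    n_fast = n_slow * slow_every + 2
    fast = make_burst_seq(np.arange(n_fast, dtype=float), period=1.0)
    slow_starts = np.arange(n_slow) * slow_every + lock
    slow = make_burst_seq(slow_starts, period=float(slow_every), neuron="LG")
    return slow, fast


def test_first_forty_of_fifty_burst_starts():
    slow, fast = _locked_pair(50)
    sample = burst_start_phases(slow, fast, first_n=40)
    assert sample.n == 40
    np.testing.assert_allclose(sample.angles, 0.5, atol=1e-12)


def test_unit_with_thirty_nine_starts_excluded(caplog):
    slow, fast = _locked_pair(39)
    with caplog.at_level("INFO"):
        assert burst_start_phases(slow, fast, first_n=40) is None
    assert any("excluding" in r.message for r in caplog.records)


def test_zero_jitter_coupled_unit_locks_at_half(noiseless_cfg):
    proto = sc.TemperatureProtocol(((11.0, 600.0),))
    pd_tr, pd_truth = sc.generate_pacemaker(noiseless_cfg, proto)
    lg_tr, _ = sc.generate_coupled_slow(noiseless_cfg, pd_truth, protocol=proto)
    sample = burst_start_phases(sc.detect_bursts(lg_tr[0]),
                                sc.detect_bursts(pd_tr[0]), first_n=40)
    stats = circular_stats(sample)
    assert stats.mean_phase == pytest.approx(0.5, abs=1e-9)
    assert stats.R == pytest.approx(1.0)


# ---------------------------------------------------------- circular stats

def test_concentrated_sample():
    s = circular_stats(PhaseSample(np.full(30, 0.3)))
    assert s.mean_phase == pytest.approx(0.3)
    assert s.R == pytest.approx(1.0) and s.circ_std == pytest.approx(0.0)


def test_antipodal_cancellation():
    # opposite phases cancel: resultant length vanishes (to rounding),
    # leaving the mean direction meaningless
    s = circular_stats(PhaseSample(np.array([0.0, 0.5])))
    assert s.R == pytest.approx(0.0, abs=1e-12)
    assert s.circ_std > 1.0  # sqrt(-2 ln R) blows up as R -> 0


def test_mean_by_symmetry_and_hand_vector_sum():
    angles = np.array([0.1, 0.2, 0.3])
    s = circular_stats(PhaseSample(angles))
    assert s.mean_phase == pytest.approx(0.2)
    R_hand = np.abs(np.exp(2j * np.pi * angles).sum()) / 3
    assert s.R == pytest.approx(R_hand, abs=1e-12)


def test_circular_stats_match_reference_toolbox():
    """Cross-check against pingouin (port of the CircStat toolbox)."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    for n in (5, 8, 30):
        a = rng.uniform(0, 1, n)
        s = circular_stats(PhaseSample(a))
        z_ref, p_ref = pg.circ_rayleigh(a * 2 * np.pi)
        assert s.rayleigh_z == pytest.approx(z_ref, abs=1e-6)
        assert s.rayleigh_p == pytest.approx(p_ref, abs=1e-6)
        assert s.mean_phase == pytest.approx(
            (pg.circ_mean(a * 2 * np.pi) % (2 * np.pi)) / (2 * np.pi), abs=1e-9)
        assert s.R == pytest.approx(pg.circ_r(a * 2 * np.pi), abs=1e-9)


# ---------------------------------------------------------- Rayleigh test

def test_rayleigh_maximal_concentration():
    z, p = rayleigh_test(PhaseSample(np.full(30, 0.7)))
    assert z == pytest.approx(30.0)
    assert p < 1e-3


def test_rayleigh_uniform_grid():
    z, p = rayleigh_test(PhaseSample(np.arange(24) / 24))
    assert z == pytest.approx(0.0, abs=1e-12)
    assert p > 0.9


def test_rayleigh_needs_two_angles():
    with pytest.raises(ValueError):
        rayleigh_test(PhaseSample(np.array([0.2])))


@given(st.lists(st.floats(0, 1, exclude_max=True), min_size=2, max_size=50))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_z_equals_n_R_squared(angles):
    sample = PhaseSample(np.asarray(angles))
    stats = circular_stats(sample)
    assert stats.rayleigh_z == pytest.approx(stats.n * stats.R ** 2, abs=1e-9)


# ---------------------------------------------------------------- rasters

def test_raster_rows_align_for_locked_units():
    slow, fast = _locked_pair(20)
    fast_train = make_train(np.array([b.start for b in fast.bursts]), neuron="PD")
    raster = aligned_raster(slow, fast_train, fast, window=3.0)
    assert len(raster.rows) == 20
    np.testing.assert_allclose(raster.row_norms, 1.0)
    # perfectly periodic fast unit: interior rows show identical patterns
    # (the first row is clipped by the recording edge)
    for row in raster.rows[2:]:
        np.testing.assert_allclose(row, raster.rows[1], atol=1e-9)
    # window 3 s over period 1 s spans ~6 normalized periods
    assert raster.rows[1].size in (6, 7)


def test_raster_requires_positive_window():
    slow, fast = _locked_pair(5)
    fast_train = make_train(np.array([b.start for b in fast.bursts]))
    with pytest.raises(ValueError):
        aligned_raster(slow, fast_train, fast, window=0.0)


# ------------------------------------------------------ spike phase hists

def test_spike_probability_concentrates_at_midpoint():
    fast = make_burst_seq(np.arange(0.0, 30.0), period=1.0)
    spikes = np.arange(0.0, 28.0) + 0.5
    hist = spike_phase_probability(make_train(spikes, neuron="LG"), fast,
                                   n_bins=20)
    assert hist.probability.sum() == pytest.approx(1.0)
    assert hist.probability[10] == pytest.approx(1.0)
    assert hist.fast_onset_phase == 0.0
    assert hist.fast_offset_phase == pytest.approx(0.3)  # duty of the fixture


def test_uniform_spikes_bounded_bin_mass():
    fast = make_burst_seq(np.arange(0.0, 400.0), period=1.0)
    rng = np.random.default_rng(2)
    spikes = np.sort(rng.uniform(0, 399, 4000))
    hist = spike_phase_probability(make_train(spikes, neuron="LG"), fast,
                                   n_bins=20)
    assert hist.probability.max() <= 2.0 / 20
    assert hist.probability.sum() == pytest.approx(1.0)


def test_empty_overlap_flagged():
    fast = make_burst_seq([100.0, 101.0, 102.0], period=1.0)
    hist = spike_phase_probability(make_train([0.1, 0.2], neuron="LG"), fast, 10)
    assert hist.empty
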