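"""Phase locking of slow-unit bursts and spikes to the fast pacemaker cycle.

Phases are cycle fractions in [0, 1) at every interface (matching how this
field plots pacemaker phase) and are converted to radians only inside the
circular math. Phase within a cycle is linear in time: an event at time t in
the pacemaker cycle [start_k, start_{k+1}) has phase
(t − start_k) / period_k.

Non-uniformity of burst-start phases is tested with the Rayleigh test
(z = n·R² with R the mean resultant length) using the standard small-sample
corrected p approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import BurstSequence, SpikeTrain

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhaseSample:
    """Angles in cycle units [0, 1) with their provenance."""

    angles: np.ndarray
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", a)
        if a.size and (a.min() < 0 or a.max() >= 1):
            raise ValueError("phases must lie in [0, 1) cycles")

    @property
    def n(self) -> int:
        return int(self.angles.size)


@dataclass(frozen=True)
class PhaseStats:
    mean_phase: float      # cycles; NaN when R == 0
    R: float               # mean resultant length in [0, 1]
    circ_std: float        # cycles; sqrt(-2 ln R) / 2π
    rayleigh_z: float
    rayleigh_p: float
    n: int


def phase_at(t: float | np.ndarray, fast: BurstSequence) -> np.ndarray:
    """Pacemaker phase of time(s) t, NaN outside the defined cycles.

    A time is within a defined cycle if it falls in [start_k, start_{k+1})
    for consecutive fast burst starts; phase increases linearly over the
    cycle and is exactly 0 at a fast burst start.
    """
    starts = np.array([b.start for b in fast.bursts])
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.full(t.shape, np.nan)
    if starts.size < 2:
        return out
    idx = np.searchsorted(starts, t, side="right") - 1
    ok = (idx >= 0) & (idx < starts.size - 1)
    i = idx[ok]
    out[ok] = (t[ok] - starts[i]) / (starts[i + 1] - starts[i])
    n_out = int((~ok).sum())
    if n_out:
        log.debug("phase_at: %d times outside defined fast cycles", n_out)
    return out


def burst_start_phases(slow: BurstSequence, fast: BurstSequence,
                       first_n: int = 40) -> PhaseSample | None:
    """Pacemaker phases of the first ``first_n`` slow burst starts.

    Only burst starts with a defined phase qualify. If fewer than ``first_n``
    qualifying starts exist, the whole (preparation, temperature) unit is
    excluded (returns None, logged) — truncating every unit to the same count
    avoids time-dependent confounds and weights units equally.
    """
    phases = phase_at(slow.starts, fast)
    phases = phases[np.isfinite(phases)]
    ctx = dict(preparation_id=slow.train.preparation_id, slow=slow.neuron,
               fast=fast.neuron, temperature=slow.temperature)
    if phases.size < first_n:
        log.info("excluding %s: only %d of the required %d burst starts",
                 ctx, phases.size, first_n)
        return None
    return PhaseSample(np.mod(phases[:first_n], 1.0), ctx)


def circular_stats(sample: PhaseSample) -> PhaseStats:
    """Circular mean, resultant length, circular SD, and Rayleigh test."""
    a = sample.angles * 2 * np.pi
    n = a.size
    if n < 1:
        raise ValueError("empty phase sample")
    C, S = np.cos(a).sum(), np.sin(a).sum()
    Rn = np.hypot(C, S)
    R = min(Rn / n, 1.0)  # guard the 1 + ulp rounding case
    if R == 0:
        mean = float("nan")
        log.warning("circular mean undefined (R = 0)")
    else:
        mean = (np.arctan2(S, C) / (2 * np.pi)) % 1.0
    std = np.sqrt(-2 * np.log(R)) / (2 * np.pi) if R > 0 else float("inf")
    z, p = (rayleigh_test(sample) if n >= 2 else (float("nan"), float("nan")))
    return PhaseStats(mean_phase=float(mean), R=float(R), circ_std=float(std),
                      rayleigh_z=z, rayleigh_p=p, n=int(n))


def rayleigh_test(sample: PhaseSample) -> tuple[float, float]:
    """Rayleigh test for non-uniformity of circular data.

    z = n·R²; p uses the standard small-sample corrected approximation
    p = exp(sqrt(1 + 4n + 4(n² − Rn²)) − (1 + 2n)) with Rn = n·R.
    """
    a = sample.angles * 2 * np.pi
    n = a.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least two angles")
    Rn = np.hypot(np.cos(a).sum(), np.sin(a).sum())
    z = Rn * Rn / n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n * n - Rn * Rn)) - (1 + 2 * n))
    return float(z), float(min(p, 1.0))


@dataclass
class AlignedRaster:
    """Fast-unit spikes re-plotted around each slow burst start.

    Each row holds fast spike times relative to one slow burst start,
    normalized by the mean fast burst period computed from fast bursts whose
    starts fall inside that row's ±window; rows with no in-window fast burst
    are dropped (count kept).
    """

    rows: list[np.ndarray]
    row_norms: np.ndarray
    window: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    n_dropped_rows: int = 0


def aligned_raster(slow: BurstSequence, fast_train: SpikeTrain,
                   fast: BurstSequence, window: float = 3.0,
                   n_bins: int = 120) -> AlignedRaster:
    """Burst-aligned raster of the fast unit around slow burst starts."""
    if window <= 0:
        raise ValueError("window must be positive")
    fast_starts = np.array([b.start for b in fast.bursts])
    fast_periods = np.array([b.period for b in fast.bursts])
    rows, norms = [], []
    dropped = 0
    for t0 in slow.starts:
        in_win = (fast_starts >= t0 - window) & (fast_starts <= t0 + window)
        in_win &= np.isfinite(fast_periods)
        if not in_win.any():
            dropped += 1
            continue
        norm = float(fast_periods[in_win].mean())
        sp = fast_train.spike_times
        sp = sp[(sp >= t0 - window) & (sp <= t0 + window)]
        rows.append((sp - t0) / norm)
        norms.append(norm)
    if dropped:
        log.info("aligned_raster: dropped %d rows with no in-window fast burst",
                 dropped)
    if rows:
        span = max(np.abs(np.concatenate(rows)).max(), 1e-9)
        edges = np.linspace(-span, span, n_bins + 1)
        counts = np.histogram(np.concatenate(rows), bins=edges)[0]
    else:
        edges, counts = np.linspace(-1, 1, n_bins + 1), np.zeros(n_bins, int)
    return AlignedRaster(rows=rows, row_norms=np.array(norms), window=window,
                         hist_edges=edges, hist_counts=counts,
                         n_dropped_rows=dropped)


@dataclass
class SpikePhaseHistogram:
    """Probability of slow-unit spiking per fast-cycle phase bin."""

    bin_edges: np.ndarray
    probability: np.ndarray      # sums to 1 (or empty flag)
    fast_onset_phase: float      # 0 by construction
    fast_offset_phase: float     # mean fast duty cycle
    n_spikes: int

    @property
    def empty(self) -> bool:
        return self.n_spikes == 0


def spike_phase_probability(slow_train: SpikeTrain, fast: BurstSequence,
                            n_bins: int = 25) -> SpikePhaseHistogram:
    """Histogram over [0, 1) of fast-cycle phases of all slow-unit spikes,
    normalized to sum to 1, annotated with the mean fast burst extent."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    phases = phase_at(slow_train.spike_times, fast)
    phases = np.mod(phases[np.isfinite(phases)], 1.0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.histogram(phases, bins=edges)[0]
    n = int(phases.size)
    prob = counts / n if n else counts.astype(float)
    if n == 0:
        log.warning("spike_phase_probability: no qualifying spikes")
    duty = np.array([b.duty_cycle for b in fast.bursts])
    duty = duty[np.isfinite(duty)]
    offset = float(duty.mean()) if duty.size else float("nan")
    return SpikePhaseHistogram(bin_edges=edges, probability=prob,
                               fast_onset_phase=0.0, fast_offset_phase=offset,
                               n_spikes=n)
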