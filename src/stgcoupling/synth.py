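"""Synthetic spike trains with the statistical structure the analysis assumes.

Three units are generated per preparation:

* a fast pacemaker ("PD"-like): a renewal burster whose mean burst period
  follows the thermal scaling law ``P(T) = P_ref * q10**(-(T - T_ref)/10)``,
* a coupled slow unit ("LG"-like): each burst starts at a fixed phase of a
  pacemaker cycle chosen an integer number k of cycles after the previous
  burst's anchor cycle, so slow periods are built from pacemaker cycles and
  integer coupling holds by construction,
* an uncoupled slow unit ("DG"-like): a renewal burster on the same timescale
  whose onsets are independent of the pacemaker.

Every generator is deterministic under a fixed seed; ground truth (k
sequence, anchor cycles, true phases) is returned for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .types import (COUPLED_SLOW, PACEMAKER, UNCOUPLED_SLOW, SpikeTrain,
                    TemperatureProtocol)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic preparation.

    Defaults emulate the biological study conditions: a ~1 s pacemaker period
    at the 11 °C reference, period halving per 10 °C (Q10 = 2), a roughly
    constant pacemaker duty cycle, slow bursts spanning 5–25 pacemaker cycles
    with onsets locked near phase 0.5 of the pacemaker cycle.
    """

    reference_temperature: float = 11.0
    pacemaker_period_ref: float = 1.0
    pacemaker_q10: float = 2.0
    pacemaker_duty_cycle: float = 0.3
    pacemaker_spikes_per_burst: int = 8
    period_jitter_cv: float = 0.02
    cycles_per_slow_burst: tuple[int, int] = (5, 25)  # inclusive range for k
    lock_phase: float = 0.5
    lock_jitter_sd: float = 0.02           # cycles
    slow_burst_duration_frac: float = 0.5  # of the k-cycle slow period
    slow_intraburst_rate: float = 10.0     # Hz
    uncoupled_period_cv: float = 0.15
    slowdown_rate: float = 0.0             # fractional period growth per slow cycle
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cycles_per_slow_burst, int):
            k = self.cycles_per_slow_burst
            object.__setattr__(self, "cycles_per_slow_burst", (k, k))
        else:
            object.__setattr__(self, "cycles_per_slow_burst",
                               tuple(int(k) for k in self.cycles_per_slow_burst))
        if self.pacemaker_q10 <= 0:
            raise ValueError("pacemaker_q10 must be positive")
        if not 0 < self.pacemaker_duty_cycle < 1:
            raise ValueError("pacemaker_duty_cycle must be in (0, 1)")
        if not 0 <= self.lock_phase < 1:
            raise ValueError("lock_phase must be in [0, 1)")
        k_min, k_max = self.cycles_per_slow_burst
        if k_min < 1 or k_max < k_min:
            raise ValueError("cycles_per_slow_burst must satisfy 1 <= k_min <= k_max")
        if self.pacemaker_spikes_per_burst < 2:
            raise ValueError("pacemaker_spikes_per_burst must be >= 2")
        for name in ("pacemaker_period_ref", "slow_intraburst_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("period_jitter_cv", "lock_jitter_sd", "uncoupled_period_cv",
                     "slowdown_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.slow_burst_duration_frac < 1:
            raise ValueError("slow_burst_duration_frac must be in (0, 1)")

    def mean_period(self, temperature: float) -> float:
        """Thermal scaling law P(T) = P_ref * q10**(-(T - T_ref)/10)."""
        return self.pacemaker_period_ref * self.pacemaker_q10 ** (
            -(temperature - self.reference_temperature) / 10.0)

    @property
    def mean_k(self) -> float:
        k_min, k_max = self.cycles_per_slow_burst
        return 0.5 * (k_min + k_max)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child stream of the config seed (fixed offsets)."""
        return np.random.default_rng(np.random.SeedSequence(
            entropy=int(self.seed), spawn_key=(int(stream),)))


@dataclass
class PacemakerTruth:
    """Per-epoch ground truth of the pacemaker generator."""

    onsets: dict[str, np.ndarray] = field(default_factory=dict)
    periods: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class CoupledTruth:
    """Ground truth of the coupled slow generator, keyed by epoch."""

    k: dict[str, np.ndarray] = field(default_factory=dict)
    anchor_cycles: dict[str, np.ndarray] = field(default_factory=dict)
    phases: dict[str, np.ndarray] = field(default_factory=dict)
    burst_starts: dict[str, np.ndarray] = field(default_factory=dict)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative log-normal jitter with unit mean and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def _epoch_id(i: int) -> str:
    return f"step{i}"


def generate_pacemaker(cfg: GeneratorConfig, protocol: TemperatureProtocol,
                       preparation_id: str = "synth0",
                       ) -> tuple[list[SpikeTrain], PacemakerTruth]:
    """Generate the fast pacemaker, one SpikeTrain per protocol step.

    Burst onsets form a renewal process with mean period ``cfg.mean_period(T)``
    and multiplicative log-normal jitter of the configured CV; each burst has
    ``pacemaker_spikes_per_burst`` spikes spread uniformly over
    ``duty_cycle * period``. Times are relative to each epoch's start.
    """
    rng = cfg.rng(0)
    trains: list[SpikeTrain] = []
    truth = PacemakerTruth()
    for i, (T, dur) in enumerate(protocol.steps):
        mean_p = cfg.mean_period(T)
        if dur < mean_p:
            log.warning("protocol step %d (%g s) shorter than one period (%g s); "
                        "may emit zero bursts", i, dur, mean_p)
        n_max = int(np.ceil(dur / mean_p * 1.5)) + 20
        periods = mean_p * _lognormal_factors(rng, cfg.period_jitter_cv, n_max)
        onsets = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
        keep = onsets < dur
        onsets, periods = onsets[keep], periods[keep]
        spikes = []
        for o, p in zip(onsets, periods):
            burst = np.linspace(o, o + cfg.pacemaker_duty_cycle * p,
                                cfg.pacemaker_spikes_per_burst)
            spikes.append(burst[burst < dur])
        times = np.concatenate(spikes) if spikes else np.empty(0)
        eid = _epoch_id(i)
        trains.append(SpikeTrain(preparation_id, PACEMAKER, T, times, eid))
        truth.onsets[eid] = onsets
        truth.periods[eid] = periods
    return trains, truth


def generate_coupled_slow(cfg: GeneratorConfig, pacemaker: PacemakerTruth,
                          preparation_id: str = "synth0",
                          temperatures: Sequence[float] | None = None,
                          protocol: TemperatureProtocol | None = None,
                          ) -> tuple[list[SpikeTrain], CoupledTruth]:
    """Generate the integer-coupled slow unit from pacemaker ground truth.

    Each slow burst starts at phase ``lock_phase`` (plus wrapped Gaussian
    jitter of SD ``lock_jitter_sd`` cycles) of the pacemaker cycle located k
    cycles after the previous burst's anchor cycle, with k drawn uniformly
    from ``cycles_per_slow_burst`` per burst. Burst duration is
    ``slow_burst_duration_frac * k * (local pacemaker period)`` and spikes are
    regular at ``slow_intraburst_rate``.

    Raises
    ------
    ValueError
        If phase jitter wraps so far that burst starts stop being monotonic.
    """
    if protocol is not None:
        temperatures = protocol.temperatures
    rng = cfg.rng(1)
    trains: list[SpikeTrain] = []
    truth = CoupledTruth()
    k_min, k_max = cfg.cycles_per_slow_burst
    for i, eid in enumerate(sorted(pacemaker.onsets, key=lambda e: int(e[4:]))):
        onsets = pacemaker.onsets[eid]
        periods = pacemaker.periods[eid]
        T = temperatures[i] if temperatures is not None else float("nan")
        ks, anchors, phases, starts, stops, spikes = [], [], [], [], [], []
        c = 0
        while c < len(onsets):
            k = int(rng.integers(k_min, k_max + 1))
            phase = cfg.lock_phase
            if cfg.lock_jitter_sd > 0:
                phase = (phase + rng.normal(0.0, cfg.lock_jitter_sd)) % 1.0
            start = onsets[c] + phase * periods[c]
            dur = cfg.slow_burst_duration_frac * k * periods[c]
            n_sp = max(2, int(round(cfg.slow_intraburst_rate * dur)))
            spikes.append(np.linspace(start, start + dur, n_sp))
            ks.append(k)
            anchors.append(c)
            phases.append(phase)
            starts.append(start)
            stops.append(start + dur)
            c += k
        starts_a = np.array(starts)
        if starts_a.size > 1 and (np.any(np.diff(starts_a) <= 0)
                                  or np.any(starts_a[1:] <= np.array(stops)[:-1])):
            raise ValueError("lock_jitter_sd too large: wrapped phases break "
                             "monotonic, non-overlapping burst starts")
        times = np.concatenate(spikes) if spikes else np.empty(0)
        times = np.unique(times)
        trains.append(SpikeTrain(preparation_id, COUPLED_SLOW, T, times, eid))
        truth.k[eid] = np.array(ks, dtype=int)
        truth.anchor_cycles[eid] = np.array(anchors, dtype=int)
        truth.phases[eid] = np.array(phases)
        truth.burst_starts[eid] = starts_a
    return trains, truth


def generate_uncoupled_slow(cfg: GeneratorConfig, protocol: TemperatureProtocol,
                            preparation_id: str = "synth0") -> list[SpikeTrain]:
    """Generate the uncoupled slow unit: a renewal burster independent of the
    pacemaker with mean period ``mean(k) * P(T)`` and CV ``uncoupled_period_cv``.

    A positive ``slowdown_rate`` grows the period multiplicatively per cycle,
    emulating the slow drift of evoked gastric rhythms.
    """
    rng = cfg.rng(2)
    trains: list[SpikeTrain] = []
    for i, (T, dur) in enumerate(protocol.steps):
        mean_p = cfg.mean_k * cfg.mean_period(T)
        n_max = int(np.ceil(dur / mean_p * 2)) + 20
        periods = mean_p * _lognormal_factors(rng, cfg.uncoupled_period_cv, n_max)
        if cfg.slowdown_rate > 0:
            periods = periods * (1.0 + cfg.slowdown_rate) ** np.arange(n_max)
        first = rng.uniform(0, mean_p)
        onsets = first + np.concatenate([[0.0], np.cumsum(periods)[:-1]])
        keep = onsets < dur
        onsets, periods = onsets[keep], periods[keep]
        spikes = []
        for o, p in zip(onsets, periods):
            d = cfg.slow_burst_duration_frac * p
            n_sp = max(2, int(round(cfg.slow_intraburst_rate * d)))
            spikes.append(np.linspace(o, o + d, n_sp))
        times = np.concatenate(spikes) if spikes else np.empty(0)
        trains.append(SpikeTrain(preparation_id, UNCOUPLED_SLOW, T,
                                 np.unique(times), _epoch_id(i)))
    return trains


def generate_preparation(cfg: GeneratorConfig, protocol: TemperatureProtocol,
                         preparation_id: str = "synth0"):
    """Generate all three units for one preparation.

    Returns
    -------
    trains : list of SpikeTrain
        Pacemaker, coupled slow and uncoupled slow trains for every step.
    truth : dict
        ``{"pacemaker": PacemakerTruth, "coupled": CoupledTruth}``.
    """
    pd_trains, pd_truth = generate_pacemaker(cfg, protocol, preparation_id)
    lg_trains, lg_truth = generate_coupled_slow(
        cfg, pd_truth, preparation_id, temperatures=protocol.temperatures)
    dg_trains = generate_uncoupled_slow(cfg, protocol, preparation_id)
    return (pd_trains + lg_trains + dg_trains,
            {"pacemaker": pd_truth, "coupled": lg_truth})
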