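"""Shared data model: spike trains, temperature protocols, bursts.

All times are seconds (decimal floats, full precision) relative to the start
of an epoch; temperatures are degrees Celsius; phases at module interfaces
are cycle fractions in [0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Conventional neuron labels. PD indexes the fast (pyloric) pacemaker,
#: LG the slow gastric-mill unit coupled to it, DG a slow unit that is not.
PACEMAKER = "PD"
COUPLED_SLOW = "LG"
UNCOUPLED_SLOW = "DG"


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one neuron in one preparation epoch.

    Parameters
    ----------
    preparation_id : str
        Identifier of the animal / preparation.
    neuron : str
        Neuron label ("PD", "LG", "DG" or arbitrary).
    temperature : float
        Bath temperature in degrees Celsius during the epoch.
    spike_times : ndarray
        Strictly increasing, finite, non-negative times in seconds.
    epoch_id : str
        Distinguishes repeated holds at the same temperature.
    """

    preparation_id: str
    neuron: str
    temperature: float
    spike_times: np.ndarray
    epoch_id: str = "e0"

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", t)
        if t.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError("spike_times must be finite")
        if t.size and t[0] < 0:
            raise ValueError("spike_times must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike_times must be strictly increasing")
        if not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def key(self) -> tuple[str, str, float, str]:
        return (self.preparation_id, self.neuron, self.temperature, self.epoch_id)


@dataclass(frozen=True)
class TemperatureProtocol:
    """Ordered sequence of (temperature °C, hold duration s) steps."""

    steps: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        steps = tuple((float(T), float(d)) for T, d in self.steps)
        object.__setattr__(self, "steps", steps)
        if not steps:
            raise ValueError("protocol needs at least one step")
        if any(d <= 0 for _, d in steps):
            raise ValueError("hold durations must be positive")

    @classmethod
    def uniform(cls, temperatures: Sequence[float], hold: float) -> "TemperatureProtocol":
        return cls(tuple((T, hold) for T in temperatures))

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(T for T, _ in self.steps)


@dataclass(frozen=True)
class Burst:
    """One detected burst.

    ``period`` is start-to-start to the following retained burst and is NaN
    for the last burst of an epoch; ``duty_cycle`` = duration / period.
    """

    start: float
    stop: float
    n_spikes: int
    period: float = float("nan")

    @property
    def duration(self) -> float:
        return self.stop - self.start

    @property
    def duty_cycle(self) -> float:
        return self.duration / self.period  # NaN propagates for last burst


@dataclass
class BurstSequence:
    """Ordered bursts detected in one spike train."""

    bursts: list[Burst]
    train: SpikeTrain
    n_discarded_spikes: int = 0

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)

    @property
    def starts(self) -> np.ndarray:
        return np.array([b.start for b in self.bursts])

    @property
    def periods(self) -> np.ndarray:
        """Defined start-to-start periods (excludes the last burst)."""
        p = np.array([b.period for b in self.bursts])
        return p[np.isfinite(p)]

    @property
    def neuron(self) -> str:
        return self.train.neuron

    @property
    def temperature(self) -> float:
        return self.train.temperature


@dataclass
class ResultTable:
    """Tidy (preparation, neuron, temperature, metric) -> value records."""

    records: list[dict] = field(default_factory=list)

    def add(self, preparation_id: str, neuron: str, temperature: float,
            metric: str, value: float) -> None:
        key = (preparation_id, neuron, temperature, metric)
        if any((r["preparation_id"], r["neuron"], r["temperature"], r["metric"]) == key
               for r in self.records):
            raise ValueError(f"duplicate result key {key}")
        self.records.append(dict(preparation_id=preparation_id, neuron=neuron,
                                 temperature=temperature, metric=metric, value=value))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records,
                            columns=["preparation_id", "neuron", "temperature",
                                     "metric", "value"])
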