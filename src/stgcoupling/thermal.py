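"""Q10 temperature scaling of burst frequency.

Q10 is the factor by which a rate changes per 10 °C:

    Q10 = (f_T / f_ref) ** (10 / (T - T_ref))

computed at every non-reference temperature and summarised per preparation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bursts import BurstSequence, pooled_frequency


def q10(f_T: float, f_ref: float, T: float, T_ref: float) -> float:
    """Temperature coefficient of a rate between T_ref and T.

    Scale-invariant in (f_T, f_ref) and undefined at T == T_ref.
    """
    if T == T_ref:
        raise ValueError("Q10 is undefined at the reference temperature "
                         "(exponent 10/(T - T_ref) diverges)")
    if not (f_T > 0 and f_ref > 0):
        raise ValueError("frequencies must be positive")
    return float((f_T / f_ref) ** (10.0 / (T - T_ref)))


@dataclass
class ThermalScalingResult:
    """Per-preparation, per-neuron Q10 of burst frequency."""

    preparation_id: str
    neuron: str
    reference_temperature: float
    per_temperature: dict[float, float] = field(default_factory=dict)

    @property
    def summary(self) -> float:
        """Arithmetic mean of per-temperature Q10s."""
        if not self.per_temperature:
            return float("nan")
        return float(np.mean(list(self.per_temperature.values())))

    @property
    def summary_logfit(self) -> float:
        """Alternative joint estimate: regression of log f on temperature.

        slope of ln f vs T gives Q10 = exp(10 * slope); uses the reference
        point as well. Equivalent to the mean for two temperatures.
        """
        pts = [(self.reference_temperature, 0.0)] + [
            (T, np.log(v) * (T - self.reference_temperature) / 10.0)
            for T, v in self.per_temperature.items()]
        T_arr = np.array([p[0] for p in pts])
        logf = np.array([p[1] for p in pts])
        slope = np.polyfit(T_arr, logf, 1)[0]
        return float(np.exp(10.0 * slope))


def preparation_q10(seqs: list[BurstSequence], reference_temperature: float = 11.0,
                    reciprocal_of_mean: bool = False) -> ThermalScalingResult:
    """Q10 at every non-reference temperature with a defined frequency.

    ``seqs`` are burst sequences of one neuron in one preparation across
    temperatures; epochs at the same temperature are pooled. Raises if the
    reference temperature has no defined frequency.
    """
    if not seqs:
        raise ValueError("no burst sequences given")
    prep = seqs[0].train.preparation_id
    neuron = seqs[0].neuron
    by_T: dict[float, list[BurstSequence]] = {}
    for s in seqs:
        by_T.setdefault(s.temperature, []).append(s)
    freqs = {T: pooled_frequency(g, reciprocal_of_mean) for T, g in by_T.items()}

    if reference_temperature not in freqs or not freqs[reference_temperature].defined:
        raise ValueError(
            f"preparation {prep}/{neuron}: no defined burst frequency at the "
            f"reference temperature {reference_temperature} °C")
    f_ref = freqs[reference_temperature].mean_frequency

    result = ThermalScalingResult(prep, neuron, reference_temperature)
    for T, summ in sorted(freqs.items()):
        if T == reference_temperature or not summ.defined:
            continue
        result.per_temperature[T] = q10(summ.mean_frequency, f_ref,
                                        T, reference_temperature)
    return result


@dataclass(frozen=True)
class Q10Comparison:
    t: float
    p: float
    n: int
    df: int
    degenerate: bool = False


def compare_q10(group_a: list[float], group_b: list[float],
                paired: bool = True) -> Q10Comparison:
    """Compare per-preparation Q10s of two rhythms (paired t-test by default).

    With paired samples the entries must be matched by preparation. A paired
    sample whose differences have zero variance but nonzero mean yields an
    infinite t and is flagged degenerate.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal-length groups")
    if min(a.size, b.size) < 2:
        raise ValueError("need at least two preparations per group")
    if paired:
        d = a - b
        if np.allclose(d.std(ddof=1), 0):
            if np.allclose(d.mean(), 0):
                return Q10Comparison(0.0, 1.0, a.size, a.size - 1)
            return Q10Comparison(float(np.inf) * np.sign(d.mean()), 0.0,
                                 a.size, a.size - 1, degenerate=True)
        t, p = stats.ttest_rel(a, b)
        return Q10Comparison(float(t), float(p), int(a.size), int(a.size - 1))
    t, p = stats.ttest_ind(a, b)
    return Q10Comparison(float(t), float(p), int(a.size + b.size),
                         int(a.size + b.size - 2))
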