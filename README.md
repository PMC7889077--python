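# stgcoupling

Analysis of temperature-dependent coupling between a fast and a slow
neuronal oscillator from spike times.

In the crustacean stomatogastric nervous system, the fast pyloric rhythm
(~1 s burst period, indexed by PD neuron bursts) and the slow gastric mill
rhythm (~6–25 s, indexed by LG bursts) run concurrently, and the slow
rhythm's period tends to be an *integer multiple* of the fast one's. This
package asks, from spike-time tables alone: how do both rhythms scale with
temperature, and is their integer coupling and phase relationship preserved
as the bath warms?

It provides:

* **ISI burst detection** — bursts are maximal spike runs whose inter-spike
  intervals stay within a gap threshold (1 s and ≥5 spikes for slow units,
  0.2 s and ≥2 spikes for the fast pacemaker), yielding burst starts, stops,
  start-to-start periods and duty cycles.
* **Q10 thermal scaling** — the temperature coefficient of burst frequency,
  `Q10 = (f_T / f_ref)^(10 / (T − T_ref))` with an 11 °C reference, per
  preparation and per neuron, plus a paired t-test between rhythms.
* **Integer coupling** — for every slow burst period, the ratio to the mean
  fast period within it; the fractional part ("significand") of that ratio
  clusters near 0/1 under integer coupling. Coupling strength is the exact
  area `∫|F(x) − x| dx` between the significand empirical c.d.f. and the
  diagonal (0 = uniform, 0.25 = perfect coupling), with 1000-fold bootstrap
  bands, a shuffled-period null, two-sample Kolmogorov–Smirnov tests per
  temperature, and Bonferroni correction across temperature steps.
* **Phase locking** — burst-start phases of the slow unit in the fast cycle
  (first 40 per preparation and temperature), circular means, the Rayleigh
  test (`z = n·R²`), burst-aligned rasters and spike-phase histograms.
* **A synthetic generator** — temperature-scaled pacemaker, a slow unit
  built to burst an integer number of pacemaker cycles apart at a locked
  phase, and an uncoupled control unit, all with ground truth for recovery
  tests.

## Worked example

```sh
python analysis/01_simulate.py       # 10 synthetic preparations, 7–21 °C
python analysis/02_burst_metrics.py
python analysis/03_thermal_scaling.py
python analysis/04_integer_coupling.py
python analysis/05_phase_locking.py
```

The thermal-scaling step prints, for the simulated dataset:

```
PD: Q10 = 2.000 ± 0.001 (n = 10 preparations)
LG: Q10 = 2.059 ± 0.103 (n = 10 preparations)
DG: Q10 = 2.001 ± 0.031 (n = 10 preparations)
paired t-test PD vs LG: t = -1.73, p = 0.119, N = 10
```

i.e. both the fast and the slow rhythm roughly halve their period per 10 °C
and are statistically indistinguishable in their scaling. The coupling step
prints, per temperature:

```
LG @  7.0 °C: area 0.225 (null 0.157), D 0.254, p 3.2e-26 -> COUPLED
...
DG @  7.0 °C: area 0.010 (null 0.014), D 0.024, p 0.95 -> not significant
```

The LG-like unit's significand distribution sits far outside its
shuffled-period null at every temperature (the area stays near the 0.25
ceiling and the KS p is far below the corrected threshold 0.05/5), while the
uncoupled DG-like unit is indistinguishable from its null. Note the null
area itself is well above zero: with a low-jitter pacemaker, even shuffled
period ratios keep near-integer structure — which is why significance is
judged by the two-sample KS test against the shuffle null rather than
against uniformity. The phase step shows the coupled unit starting its
bursts at pacemaker phase ~0.5 with Rayleigh z ≈ 39 everywhere, and the
uncoupled unit close to uniform.

The same stages are scriptable via the CLI
(`stgcoupling simulate | bursts | q10 | coupling | phase | run-all`); the
library functions underneath (`detect_bursts`, `preparation_q10`,
`pair_periods`, `coupling_area`, `shuffle_null`, `circular_stats`, …) are
the intended programmatic interface. Real recordings are read from a plain
delimited spike table with columns
`preparation_id, neuron, temperature_C, spike_time_s[, epoch_id]`.

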