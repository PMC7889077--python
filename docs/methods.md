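# Methods

## The system and the questions

Two rhythmic motor circuits share one preparation: a fast pacemaker-driven
oscillator (PD bursts, ~1 s period at 11 °C) and a slow oscillator an order
of magnitude slower (LG bursts, 6–25 s), whose burst onsets are timed by the
pacemaker's cycle through periodic disinhibition — so the slow period is
built from an integer number of fast cycles. A third unit (DG) bursts on the
slow timescale without direct pacemaker coupling and serves as the control.
The analyses quantify, across a 7–21 °C range: (1) how each rhythm's burst
frequency scales with temperature, (2) whether the slow/fast period ratio
stays integer-locked, and (3) whether the slow unit's burst-start phase in
the fast cycle is preserved.

## Burst detection

Bursts are maximal runs of spikes whose internal inter-spike intervals are
all ≤ a gap threshold; a run with fewer than a minimum number of spikes is
discarded entirely (its spikes belong to no burst). The boundary case of an
ISI exactly equal to the threshold is within-burst, consistent with gaps
*longer than* the threshold separating bursts. Defaults: gap 1 s with ≥5
spikes for the slow units; for the fast pacemaker the convention fixes only
the minimum of 2 spikes, and the gap default of 0.2 s is this package's
choice — the fast unit's whole cycle is ~1 s at 11 °C, so a 1 s gap would
merge its bursts. Review this parameter for other circuits.

Burst period is start-to-start to the next retained burst (this makes the
duty cycle, duration/period, < 1 by construction); the last burst of an
epoch has undefined period and is excluded from frequency summaries. Bursts
are never merged across temperature-step boundaries.

Mean burst frequency at a temperature is the mean over bursts of 1/period
(the reciprocal-of-mean-period alternative is available behind a flag);
fewer than two retained bursts yields a flagged missing value that
downstream stages skip.

## Thermal scaling (Q10)

`Q10 = (f_T / f_ref)^(10 / (T − T_ref))`, reference 11 °C, computed at each
non-reference temperature with a defined frequency. The per-preparation
summary is the arithmetic mean of per-temperature Q10s; a joint fit of
log-frequency against temperature is also provided (`summary_logfit`) and is
less noisy when per-step data are sparse, but the per-step mean is the
default reduction. Rhythms are compared by a paired t-test on
per-preparation summary Q10s, each preparation contributing once.

## Integer coupling

For every slow burst with a defined period, the fast bursts whose starts
fall in the half-open window [slow start, next slow start) and have defined
periods contribute their mean period; the pair's ratio is slow period /
mean fast period and the significand is its fractional part (10.1/1.0 →
0.1; 9.9/1.0 → 0.9). Slow bursts containing no qualifying fast burst are
dropped with a logged count.

Coupling strength is the unsigned area between the significand empirical
c.d.f. and the unit diagonal, `∫₀¹ |F(x) − x| dx`, integrated exactly on
the staircase (each constant segment contributes a closed-form term, split
at the crossing when the segment straddles the diagonal; no grid
approximation). Uniform significands give 0; mass split between 0 and just
below 1 — perfect integer coupling — gives the maximal 0.25. The unsigned
integrand is required so that symmetric clustering at both ends scores 0.25
rather than canceling; its documented limitation is that a cluster at 0.5
(half-integer locking) also scores 0.25, and one-sided clustering at 0 alone
scores up to 0.5.

Uncertainty on the c.d.f. is a pointwise percentile band over 1000
bootstrap resamples, evaluated on a 1001-point grid (band level 0.95 by
default; the level is configurable since the convention does not fix it).

Significance is assessed against a shuffle null: each of 1000 shuffles
permutes the slow-period list against the fast-period-mean list — breaking
the pairing while preserving both marginals — and recomputes significands
and area. Because period ranges alone can make even independent ratios'
significands non-uniform (with a low-jitter fast period, a shuffled ratio
k·P_i/P_j is still near-integer), the test is a *two-sample*
Kolmogorov–Smirnov test of observed significands against a designated null
sample (the first shuffle, sized like the observed sample, keeping the
test's power comparable to a matched design; the remaining shuffles feed
the area null band only). Tests are run per temperature, pooling
preparations, with the significance threshold Bonferroni-divided by the
number of temperature steps (0.05/9 = 0.0056 for a nine-step protocol).
Asymptotic two-sample p-values are used. The ratio's trend with temperature
is a Spearman rank correlation (midranks on ties), pooled across
preparations.

## Phase locking

Phase is linear within a fast cycle: an event at time t in
[start_k, start_{k+1}) has phase (t − start_k)/period_k, in cycle units
[0, 1); times outside defined cycles are excluded with a log entry. To
weight preparations equally and avoid time-dependent confounds (evoked slow
rhythms drift), only the first 40 slow burst starts per (preparation,
temperature) are analyzed; units with fewer than 40 qualifying starts are
excluded entirely.

Circular statistics: mean direction from the resultant vector, R = resultant
length / n, circular SD = sqrt(−2 ln R) (reported in cycles). The Rayleigh
non-uniformity statistic is z = n·R² with the standard small-sample
corrected p-value `exp(sqrt(1 + 4n + 4(n² − Rn²)) − (1 + 2n))`, Rn = n·R;
the implementation agrees with the pingouin port of the CircStat toolbox to
1e-6, which the tests verify as an independent cross-check. R = 0 leaves
the mean direction undefined (flagged).

Burst-aligned rasters re-plot fast spikes in a ±3 s window around each slow
burst start, normalizing each row by the mean period of fast bursts whose
starts fall inside that row's window (rows without an in-window fast burst
are dropped with a count); a column histogram of the pooled normalized spike
times summarizes alignment. Spike-phase histograms use 25 bins over [0, 1)
by default (the convention does not fix a bin count) and are annotated with
the mean fast-unit duty cycle as the burst-extent marker.

## Synthetic data

The generator emulates the study conditions, not the biophysics: no
membrane potentials, just point-process structure.

* **Pacemaker**: renewal burster with mean period
  `P(T) = P_ref · Q10^(−(T − T_ref)/10)` (defaults P_ref = 1 s, Q10 = 2,
  T_ref = 11 °C), multiplicative log-normal period jitter (CV 0.02 —
  log-normal keeps periods positive), a constant duty cycle of 0.3 and 8
  evenly spaced spikes per burst. Temperature changes take effect instantly
  at step boundaries; the experimental minutes-long transitions are not
  modeled because analyses only use data within holds.
* **Coupled slow unit**: each burst starts at phase 0.5 (± Gaussian jitter
  of SD 0.02 cycles, wrapped) of the pacemaker cycle k cycles after the
  previous burst's anchor cycle, k drawn uniformly from 5–25 per burst.
  Building the slow period from pacemaker cycles (rather than drawing a
  period and snapping it) mirrors the biological mechanism of
  pacemaker-timed disinhibition and guarantees integer structure. Burst
  duration is half the k-cycle span; spikes are regular at 10 Hz (ample for
  the ≥5-spike detection minimum). Ground truth (k sequence, anchor cycles,
  true phases) is returned for recovery tests. Excessive phase jitter that
  would make bursts collide raises an error rather than emitting a
  non-physical train.
* **Uncoupled slow unit**: renewal burster with mean period mean(k)·P(T)
  and period CV 0.15, onsets independent of the pacemaker; an optional
  multiplicative per-cycle slowdown emulates the drift of evoked slow
  rhythms (default off; it applies to this unit only — the coupled unit's
  drift is expressible through its k range).

Defaults the convention does not fix (lock jitter 0.02 cycles, uncoupled
CV 0.15, duration fraction 0.5, intraburst rate 10 Hz, 8 spikes per fast
burst) were chosen once as realistic for these rhythms and are not fitted
to any figure. The default protocol holds each of 7, 11, 15, 19, 21 °C for
1800 s: evoked slow rhythms run for tens of minutes per step, and holds of
this length give every unit ≥40 slow bursts per temperature — enough for
the first-40 phase rule and for stable mean frequencies given the wide k
range (with much shorter holds, the k-sampling noise, amplified by the
10/ΔT exponent over 4 °C steps, dominates the slow unit's Q10).

What passing tests on this generator do **not** show about real data: the
generator has no measurement noise, no spike-sorting errors, no missing
bursts, no within-step drift by default, and its jitters are stationary and
log-normal/Gaussian; real preparations violate all of these to some degree.

## Reproducibility and numerics

Every stochastic routine takes a seed or Generator; the pipeline derives
per-stage seeds from one top-level seed by fixed offsets (and per-preparation
seeds by a fixed stride), so stages are independently rerunnable and a full
run is byte-reproducible (the manifest records SHA-256 hashes of all
artifacts). Degenerate inputs are flagged rather than silently propagated:
single-burst epochs give missing frequencies, zero-variance paired
differences give a flagged infinite t, constant ratios give an undefined
Spearman rho, R = 0 gives an undefined circular mean. Duplicate spike
timestamps in input tables collapse to one spike with a warning. The exact
staircase area and the brute-force checks in the test suite (partition
oracle for burst detection, sup-scan for KS D, dense-grid integration for
the area) are deliberately independent of the implementation paths they
verify.

## Known limitations

* The area metric cannot distinguish integer locking from half-integer
  locking (both can reach 0.25); the KS test against the shuffle null is
  the inferential instrument.
* The fast unit's gap threshold is a package convention (see above).
* With sparse per-step data the per-step-mean Q10 summary is noisy and
  upward-biased (the exponent is convex); prefer longer holds or the
  log-fit summary.
* Reading the original deposit's native file layout is out of scope; real
  data must be converted to the plain spike-table schema first.
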