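# Methods

## Pulse model

A stimulus is a charge-balanced biphasic pulse: two consecutive phases of
equal charge and opposite sign. Three families parameterise how the phase is
shaped as the charge level Q (the stimulus intensity) is swept:

| family | free parameter | solved per level | closed form |
|---|---|---|---|
| rectangular | phase duration t (default 21 µs) | amplitude A | A = Q/(2t) |
| fixed slope | slope angle (85°, 80°) | A and t together | t = √(Q/s), A = s·t, s = tan(angle) µA/µs |
| fixed amplitude | peak A (750, 500 µA) | duration t | t = Q/A |

Units are fixed at µA, µs, nC (1 µA·µs = 1 pC).

**Charge convention.** Q is the *total biphasic* charge magnitude: a
triangular phase of peak A and duration t carries A·t/2, so Q = A·t over both
phases. This is the only reading that reproduces all four printed
(A, t) pairs — 750 µA spanning 4–42 µs and 500 µA spanning 6–63 µs against a
3–31.5 nC schedule — simultaneously. A per-phase convention is available via
`charge_convention="per_phase"` for protocols that state charge per phase.

**Slope angles.** The 85°/80° slope angles are schematic; their physical
meaning depends on the units of the current and time axes. We declare the
convention s = tan(angle) in µA/µs (85° → ≈11.43 µA/µs, 80° → ≈5.67 µA/µs).
No (A, t) pair is printed for the fixed-slope families, so the scale cannot
be pinned further; everything downstream (charge accounting, monotonicity,
quantisation) is independent of this choice.

**Rectangular parameterisation.** The reference protocol never states the
rectangular phase duration. We hold it fixed (default 21 µs, configurable)
and solve the amplitude from Q, so that — as in the ramp families — charge is
the only quantity varying across the schedule.

**Sampling.** Waveforms are sampled at interval midpoints with the effective
period t/n (n = round(t/Δt)); midpoint sampling integrates both the rectangle
and the triangle exactly, so the continuous waveform's rectangular-rule
integral equals Q to rounding error. Each phase of a ramp family
independently rises 0 → peak; a time-mirrored (ramp-down) second phase is
available behind `mirrored_second_phase` but is untested against any
reference data. A phase shorter than one sample period raises a
degenerate-waveform error.

**Device quantisation.** The hardware realises ramps as staircases with a
25 µA current step. Sample magnitudes are rounded up to the next step
multiple (⌈A/step⌉ distinct levels, e.g. 30 for a 750 µA peak), then the
sample period — equivalently every step dwell — is rescaled uniformly so the
staircase integrates exactly to Q. Dwell rescaling was chosen over peak
adjustment to preserve the printed peak amplitudes. If the staircase would
need dwells shorter than `min_dwell_us` (default one sample period; set
3.5 µs to enforce the stimulator's stated 3–4 µs timing resolution on
dwells), the step count is capped at a coarser effective step and a
`constraint_violation` flag is set rather than erroring — this bites at the
shortest phases (4 µs at 750 µA), where 30 steps cannot fit. Whether the
device resolution constrains dwell times or only phase timing is not
documented; the flag records the ambiguity instead of hiding it.

## Synthetic recordings

The generator emulates the protocol's structure: per recording × shape,
20 charge levels × 32 repetitions at 4 Hz (250 ms inter-pulse window),
presented as ascending level blocks (rasters of the in-vivo protocol show
block structure; randomised ordering is available and only permutes table
rows, since spike times are pulse-relative).

Per trial at charge Q:

- spontaneous spikes — homogeneous Poisson at `spont_rate_Hz` over the full
  250 ms window;
- evoked spikes — Poisson count with mean `rate(Q) × 36 ms`, where
  `rate(Q) = gain·Rmax / (1 + exp(−(Q − (Q50 − shift))/k))`, each spike at a
  latency drawn from Normal(`latency_mean`, `latency_sd`) truncated to
  [9, 45) ms.

The logistic growth function matches the monotone saturating growth seen in
cortical recordings; the truncation keeps every simulated evoked spike inside
the analysis window, because sub-9 ms activity would only exercise the
discard rule, which has its own fixtures. Refractoriness is not modelled:
multi-unit clusters aggregate 2–6 neurons, so Poisson superposition is a
reasonable approximation at these rates.

**Cohort priors** (uniform, per recording): spontaneous 5–15 Hz, Rmax
30–90 Hz, Q50 10–20 nC, k 1–3 nC. These place cohort means of spontaneous
rate, MaxFR and threshold near the scale of the reported cathodic-first
cohorts — a calibration choice, not a measured fact. Latency mean 12–18 ms
with 2 ms SD is a realistic onset-latency range for electrically evoked
guinea-pig A1 responses. **Shape effects** default to the reported
cathodic-first contrasts (threshold shift = rectangular − ramped mean
threshold; gain = ramped/rectangular mean MaxFR): FS85 2.1 nC/×1.14,
FS80 2.3 nC/×1.22, FA750 2.1 nC/×1.36, FA500 3.5 nC/×1.29.

What passing tests on these simulations do **not** show: the generator has
no electrode artefact, no electrophonic contamination, no rate adaptation
across the 32 repetitions, no correlated noise across simultaneously
recorded channels, and its growth functions are exactly logistic. Recovery
results therefore demonstrate correctness of the analysis chain under its
own assumptions, not robustness to real-data pathologies.

## Quantification

- Evoked window [9, 45) ms (36 ms → rates = counts/0.036 s); spontaneous
  window [150, 250) ms (rates = counts/0.1 s). The "latency < 9 ms
  discarded" rule is implemented per spike (window start at 9 ms); the
  alternative per-recording reading — dropping recordings whose onset
  latency is below 9 ms — is available as
  `filter_early_onset_recordings`.
- Significance criterion: mean raw evoked rate > spontaneous mean +
  3·SD, with the spontaneous SD taken across all 640 trials of the
  recording × shape (the pooling unit is not stated in the source protocol;
  pooling maximises the stability of the baseline estimate). The multiplier
  is configurable (`sd_multiplier`, default 3).
- Threshold: lowest significant level whose next two levels are also
  significant; no multiple-testing correction across levels — the
  two-successor confirmation rule is the guard. A significant pair at the
  top two levels has no second successor and therefore never counts.
- MaxFR ties break toward the lowest charge, the conservative choice for
  the dynamic range. With noisy data the detected threshold can in
  principle exceed the MaxFR charge (negative dynamic range); values are
  reported as computed rather than clipped.
- `quantify_events` is a vectorised (bincount-based) implementation of the
  count → average → extract chain; its agreement with the per-recording
  object path is asserted in the test suite.

## Statistics

Wilcoxon signed-rank, two-tailed, zeros dropped before ranking, average
ranks on ties. For n ≤ 25 informative pairs the null distribution of W⁺ is
computed exactly by convolving the generating function Π(1 + x^{2rᵢ})/2 (the
doubling keeps half-integral average ranks on an integer lattice); beyond
that, the normal approximation with tie-corrected variance
n(n+1)(2n+1)/24 − Σ(t³−t)/48 and no continuity correction. The switch point
trades exactly reproducible fixture-scale p-values against the standard
large-sample form at cohort scale. Summaries skip the test (flagged, not
erroring) below 5 informative pairs. DynRange80 comparisons are computed and
flagged as absent from the printed reference tables.

Paired cohorts include only recordings significant under **both** shapes,
matching how the reference cohort sizes are counted. Under a null effect
this filter is symmetric between shapes, so it does not bias the paired
test; the test suite verifies a type-I error near 0.05 over 100 simulated
null cohorts (n = 106 each) for all four parameters.

## Recovery criteria used in the tests

Thresholds: the estimate is compared with the infinite-trial expectation —
the first schedule level where the true evoked rate exceeds three true
spontaneous-rate SDs (for a 100 ms Poisson baseline window,
SD = √(rate/0.1 s)) — and the median absolute error over 5 × 100 simulated
recordings must be within one schedule step (1.5 nC). MaxFR: the
max-over-levels estimator carries an upward selection bias of a few Hz at 32
repetitions (the maximum of ~20 noisy level means), which is an inherent
property of the published estimator, not an implementation artefact; the
median absolute error against the injected `Rmax·gain` is therefore required
to stay within twice the pooled per-level standard error of the rate
estimate — the precision the 32-repetition protocol affords.

## Problem sizes

Cohort-scale checks use 100–106 recordings per cohort, 100 cohorts per
calibration arm, and 5 seeds × 100 recordings for recovery — sizes chosen so
the full suite completes in about a minute on one core while keeping
Monte-Carlo error on a 0.05 rejection rate near ±0.02.

## Known limitations

- The fixed-slope µA/µs convention is declared, not derived (see above).
- The generator's effects act only on Q50 and Rmax; latency and spontaneous
  rate are shape-independent, so latency-based contrasts cannot be studied.
- `read_spike_events` validates format and range but not protocol
  completeness; quantification raises on an incomplete grid.
- The signed-rank normal approximation omits the continuity correction;
  at n > 25 the difference is far below the Monte-Carlo noise of any
  calibration performed here.
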