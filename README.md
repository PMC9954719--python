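# rampulse

Cochlear implants excite the auditory nerve with charge-balanced biphasic
current pulses. Replacing the conventional rectangular phase with a **ramped**
phase — current rising linearly from 0 to a peak — changes how spiral ganglion
neurons are recruited: in guinea-pig primary auditory cortex, ramped pulses
evoke higher maximal firing rates at lower charge thresholds than rectangular
pulses of the same charge. `rampulse` implements the computational chain of
such a pulse-shape experiment for stimulation engineers and auditory
neuroscientists:

1. **Pulse synthesis** (`rampulse.pulses`) — the five stimulus families
   (rectangular `Rec`; fixed-slope ramps `FS85`, `FS80`; fixed-amplitude ramps
   `FA750`, `FA500`; cathodic- or anodic-first) solved and sampled across a
   20-level charge schedule (3–31.5 nC), including the 25 µA device
   current-step quantisation.
2. **Synthetic recordings** (`rampulse.simulate`) — multi-unit spike trains
   with known ground truth: Poisson spontaneous activity plus charge-dependent
   evoked responses, standing in for in-vivo data in recovery and calibration
   tests.
3. **Growth-function quantification** (`rampulse.growth`) — per-recording
   evoked firing rate vs. charge, and the four standard parameters
   (MaxFR, threshold, charge at MaxFR, dynamic range, plus DynRange80).
4. **Paired statistics** (`rampulse.stats`) — Wilcoxon signed-rank comparison
   of each ramped shape against the rectangular reference, restricted to
   recordings significant under both shapes.

## The model

**Charge.** The charge level Q is the total biphasic charge magnitude. For a
triangular phase of peak amplitude A and duration t, each phase carries
A·t/2, so Q = A·t; for a rectangle, Q = 2·A·t (units: µA, µs, nC;
1 µA·µs = 1 pC). Fixed-amplitude families solve t = Q/A; fixed-slope families
solve t = √(Q/s), A = √(Q·s) with s = tan(slope angle) in µA/µs. These closed
forms reproduce the printed geometry: 4–42 µs phases at 750 µA and 6–63 µs at
500 µA over 3–31.5 nC.

**Quantification.** Evoked firing rate FR(Q) is counted in a [9, 45) ms
window after pulse onset (spikes earlier than the 9 ms cortical onset floor
are discarded) and averaged over 32 repetitions; spontaneous activity comes
from the last 100 ms of the 250 ms inter-pulse interval. A level is
*significant* when FR(Q) > spontaneous mean + 3 SD; the **threshold** is the
lowest significant level confirmed by the next two consecutive levels.
**MaxFR** = max(FR) − spontaneous mean; **dynamic range** = charge at MaxFR −
threshold; **DynRange80** uses the first level reaching 80 % of MaxFR.

**Statistics.** Two-tailed Wilcoxon signed-rank (zeros dropped, average
ranks; exact null distribution for n ≤ 25, tie-corrected normal approximation
above), at α = 0.05, plus above/below-diagonal counts for paired scattergrams.

## Worked example

```python
from rampulse import (RecordingGroundTruth, ShapeEffect, build_growth_function,
                      count_windows, extract_params, make_schedule,
                      simulate_recording)

schedule = make_schedule()              # 20 levels, 3-31.5 nC, 32 reps at 4 Hz
gt = RecordingGroundTruth(spont_rate_Hz=10, Rmax_Hz=60, Q50_nC=15, k_nC=2)
events = simulate_recording(gt, ShapeEffect(), schedule, seed=12345)
gf = build_growth_function(count_windows(events, schedule), schedule)
qr = extract_params(gf)
```

This prints (see `examples/02_growth_quantification.py`):

```
simulated 2375 spikes over 640 trials
spontaneous: 9.72 +/- 9.52 Hz (mean +/- SD)
MaxFR          : 63.2 AP/s  (true asymptote 60 Hz)
charge at MaxFR: 27.0 nC
threshold      : 15.0 nC  (lowest level > spont + 3 SD, confirmed by two successors)
dynamic range  : 12.0 nC   DynRange80: 6.0 nC
```

The estimated MaxFR (63.2 AP/s) recovers the 60 Hz ground-truth asymptote to
within the sampling precision of 32 repetitions, and the 15 nC threshold sits
at the schedule level where the sigmoid first clears the 3-SD criterion
(true half-max charge 15 nC). `examples/03_cohort_comparison.py` runs the
paired cohort comparison: with the calibrated ramp effect (threshold
2.3 nC lower, MaxFR ×1.22), MaxFR lands above the identity diagonal for
essentially every recording and thresholds below it, with signed-rank
p < 0.0001 — while the dynamic range shows no systematic difference.

The other examples cover pulse synthesis (`01`) and the config-driven
end-to-end pipeline (`04`). A thin CLI wraps the same functions:

```sh
rampulse synth --shape FA750-C --charge 31.5 --quantize --out fa750.tsv
rampulse all --seed 7 --out results_dir
```

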