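"""Synthesize charge-balanced biphasic pulses across the charge schedule.

Solves the phase geometry of each pulse family at the extremes of the
3-31.5 nC schedule and synthesizes the device-quantised staircase for the
750 uA fixed-amplitude ramp.
"""

from rampulse import PROTOCOL_SHAPES, make_schedule, solve_phase, synthesize, total_charge

schedule = make_schedule()  # 20 levels, 3-31.5 nC, 32 reps at 4 Hz
print(f"schedule: {schedule.n_levels} levels, "
      f"{schedule.levels_nC[0]}-{schedule.levels_nC[-1]} nC "
      f"(step {schedule.levels_nC[1] - schedule.levels_nC[0]} nC)")

for stem in ("FA750", "FA500", "FS80", "Rec"):
    spec = PROTOCOL_SHAPES[stem]
    for q in (3.0, 31.5):
        s = solve_phase(spec, q)
        print(f"{spec.label:8s} Q={q:5.1f} nC -> peak {s.peak_amplitude_uA:7.1f} uA, "
              f"phase {s.phase_duration_us:6.2f} us")

# device quantisation: the ramp is a 25 uA staircase, dwell-renormalised to charge
w = synthesize(PROTOCOL_SHAPES["FA750"], 31.5, quantize=True)
print(f"\nFA750-C at 31.5 nC, quantized: {w.n_staircase_levels} staircase levels "
      f"of 25 uA, realized {total_charge(w):.4f} nC, "
      f"imbalance {w.charge_imbalance_nC:.2e} nC")
# peak amplitude and duration rise with charge; the realized charge always
# matches the schedule level, so charge is the only varying stimulus quantity.
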