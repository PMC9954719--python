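"""Pulse-family solving, synthesis, quantisation and charge accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from rampulse.pulses import (
    PROTOCOL_SHAPES,
    DegenerateWaveformError,
    Family,
    Polarity,
    PulseDomainError,
    PulseShapeSpec,
    ScheduleError,
    make_schedule,
    parse_shape_label,
    signed_charge,
    solve_phase,
    synthesize,
    total_charge,
    Waveform,
)

ALL_SPECS = [
    spec.with_polarity(pol)
    for spec in PROTOCOL_SHAPES.values()
    for pol in (Polarity.CATHODIC, Polarity.ANODIC)
]


class TestSchedule:
    def test_reference_protocol(self):
        sch = make_schedule(3, 31.5, 20, 32, 4)
        assert sch.levels_nC[0] == 3.0
        assert sch.levels_nC[-1] == 31.5
        assert sch.n_levels == 20
        steps = np.diff(sch.levels_nC)
        assert np.allclose(steps, 1.5)  # (31.5 - 3) / 19
        assert sch.inter_pulse_interval_ms == 250.0

    def test_two_level_endpoints(self):
        sch = make_schedule(0, 10, 2, 1, 1)
        assert sch.levels_nC == (0.0, 10.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(min_nC=5, max_nC=3),
            dict(n_levels=1),
            dict(n_repetitions=0),
            dict(rate_Hz=0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ScheduleError):
            make_schedule(**{**dict(min_nC=3, max_nC=31.5, n_levels=20,
                                    n_repetitions=32, rate_Hz=4), **kwargs})


class TestSpec:
    def test_wrong_parameter_for_family_rejected(self):
        with pytest.raises(PulseDomainError):
            PulseShapeSpec(Family.FIXED_SLOPE, peak_amplitude_uA=750.0)
        with pytest.raises(PulseDomainError):
            PulseShapeSpec(Family.FIXED_AMPLITUDE, peak_amplitude_uA=500.0,
                           slope_angle_deg=80.0)
        with pytest.raises(PulseDomainError):
            PulseShapeSpec(Family.FIXED_SLOPE, slope_angle_deg=95.0)

    def test_labels_round_trip(self):
        for label in ("Rec-C", "FS85-A", "FS80-C", "FA750-A", "FA500-C"):
            assert parse_shape_label(label).label == label
        with pytest.raises(PulseDomainError):
            parse_shape_label("FS75-C")


class TestSolvePhase:
    @pytest.mark.parametrize(
        "stem, Q_nC, expected_t_us",
        [
            ("FA750", 31.5, 42.0),
            ("FA500", 31.5, 63.0),
            ("FA750", 3.0, 4.0),
            ("FA500", 3.0, 6.0),
        ],
    )
    def test_fixed_amplitude_durations(self, stem, Q_nC, expected_t_us):
        """The fixed-amplitude families span exactly the printed durations."""
        sol = solve_phase(PROTOCOL_SHAPES[stem], Q_nC)
        assert sol.phase_duration_us == pytest.approx(expected_t_us, abs=1e-12)
        assert sol.peak_amplitude_uA == float(stem[2:])

    @pytest.mark.parametrize("angle", [85.0, 80.0])
    @pytest.mark.parametrize("Q_nC", [3.0, 12.0, 31.5])
    def test_fixed_slope_matches_root_find(self, angle, Q_nC):
        """Closed form t = sqrt(Q/s) agrees with a numeric root find of A*t = Q."""
        s = math.tan(math.radians(angle))
        sol = solve_phase(PulseShapeSpec(Family.FIXED_SLOPE, slope_angle_deg=angle), Q_nC)
        t_root = brentq(lambda t: (s * t) * t - Q_nC * 1000.0, 1e-6, 1e4)
        assert sol.phase_duration_us == pytest.approx(t_root, rel=1e-9)
        assert sol.peak_amplitude_uA == pytest.approx(s * sol.phase_duration_us, rel=1e-12)
        assert sol.peak_amplitude_uA * sol.phase_duration_us == pytest.approx(
            Q_nC * 1000.0, rel=1e-12
        )

    def test_rectangular_amplitude(self):
        spec = PulseShapeSpec(Family.RECTANGULAR, rect_phase_duration_us=10.0)
        sol = solve_phase(spec, 2.0)  # 2 nC over two 10 us phases
        assert sol.peak_amplitude_uA == pytest.approx(100.0)

    def test_per_phase_convention_doubles_charge(self):
        spec = PROTOCOL_SHAPES["FA750"]
        total = solve_phase(spec, 10.0).phase_duration_us
        per_phase = solve_phase(spec, 5.0, charge_convention="per_phase").phase_duration_us
        assert per_phase == pytest.approx(total)

    def test_nonpositive_charge_rejected(self):
        with pytest.raises(PulseDomainError):
            solve_phase(PROTOCOL_SHAPES["FA750"], 0.0)

    def test_subquantum_flag_warns_not_fails(self):
        sol = solve_phase(PROTOCOL_SHAPES["FS80"], 0.01)
        assert sol.subquantum
        assert sol.phase_duration_us > 0


class TestSynthesize:
    def test_continuous_charge_is_exact(self):
        w = synthesize(PROTOCOL_SHAPES["FA750"], 31.5, sample_period_us=0.1)
        assert w.realized_charge_nC == pytest.approx(31.5, rel=1e-12)

    def test_staircase_level_count(self):
        # 750 uA peak / 25 uA step -> 30 staircase levels
        w = synthesize(PROTOCOL_SHAPES["FA750"], 31.5, quantize=True, current_step_uA=25.0)
        assert w.n_staircase_levels == 30
        assert len(np.unique(np.abs(w.samples_uA))) == 30
        steps = np.abs(w.samples_uA) / 25.0
        assert np.allclose(steps, np.round(steps))

    def test_cathodic_first_sign_structure(self):
        w = synthesize(PROTOCOL_SHAPES["Rec"], 6.0)
        n = len(w.samples_uA) // 2
        assert np.all(w.samples_uA[:n] < 0)
        assert np.all(w.samples_uA[n:] > 0)
        assert signed_charge(w) == pytest.approx(0.0, abs=1e-12)

    def test_dwell_cap_flags_constraint_violation(self):
        # 30 steps cannot fit a 4 us phase at the device dwell resolution
        w = synthesize(PROTOCOL_SHAPES["FA750"], 3.0, quantize=True, min_dwell_us=3.5)
        assert w.constraint_violation
        assert w.realized_charge_nC == pytest.approx(3.0, rel=5e-3)

    def test_phase_shorter_than_sample_is_degenerate(self):
        with pytest.raises(DegenerateWaveformError):
            synthesize(PROTOCOL_SHAPES["FA750"], 3.0, sample_period_us=10.0)

    def test_mirrored_second_phase_reverses_time(self):
        w = synthesize(PROTOCOL_SHAPES["FS80"], 12.0, mirrored_second_phase=True)
        n = len(w.samples_uA) // 2
        assert np.allclose(w.samples_uA[n:], -w.samples_uA[:n][::-1])
        assert signed_charge(w) == pytest.approx(0.0, abs=1e-12)


class TestTotalCharge:
    def test_fa500_triangle(self):
        w = synthesize(PROTOCOL_SHAPES["FA500"], 31.5, sample_period_us=0.1)
        assert total_charge(w) == pytest.approx(31.5, rel=1e-9)

    def test_rectangle_by_hand(self):
        # 100 uA for 10 us per phase -> 2 * 1000 uA*us = 2 nC
        spec = PulseShapeSpec(Family.RECTANGULAR, rect_phase_duration_us=10.0)
        w = synthesize(spec, 2.0, sample_period_us=0.5)
        assert np.max(np.abs(w.samples_uA)) == pytest.approx(100.0)
        assert total_charge(w) == pytest.approx(2.0, rel=1e-12)

    def test_all_zero_waveform(self):
        w = Waveform(1.0, np.zeros(10), 0.0, 0.0)
        assert total_charge(w) == 0.0


class TestInvariants:
    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
    def test_round_trip_charge_all_levels(self, spec, schedule):
        for q in schedule.levels_nC:
            w = synthesize(spec, q, sample_period_us=0.5)
            assert total_charge(w) == pytest.approx(q, rel=1e-9)
            assert abs(signed_charge(w)) < 1e-9

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
    def test_quantized_charge_within_half_percent(self, spec, schedule):
        for q in schedule.levels_nC:
            w = synthesize(spec, q, quantize=True, sample_period_us=0.5)
            assert abs(w.realized_charge_nC - q) <= 0.005 * q
            # imbalance bounded by one quantisation unit (step x sample period)
            unit_nC = w.current_step_uA * w.sample_period_us / 1000.0
            assert abs(w.charge_imbalance_nC) <= unit_nC

    @pytest.mark.parametrize("stem", ["FS85", "FS80", "FA750", "FA500", "Rec"])
    def test_geometry_monotone_in_charge(self, stem, schedule):
        sols = [solve_phase(PROTOCOL_SHAPES[stem], q) for q in schedule.levels_nC]
        if stem.startswith("FA") or stem.startswith("FS"):
            durs = [s.phase_duration_us for s in sols]
            assert all(b > a for a, b in zip(durs, durs[1:]))
        if stem.startswith("FS") or stem == "Rec":
            amps = [s.peak_amplitude_uA for s in sols]
            assert all(b > a for a, b in zip(amps, amps[1:]))

    @given(
        q=st.floats(min_value=1.0, max_value=40.0),
        stem=st.sampled_from(["Rec", "FS85", "FS80", "FA750", "FA500"]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_polarity_mirror(self, q, stem):
        """Anodic-first equals the negated cathodic-first waveform."""
        spec = PROTOCOL_SHAPES[stem]
        wc = synthesize(spec.with_polarity(Polarity.CATHODIC), q)
        wa = synthesize(spec.with_polarity(Polarity.ANODIC), q)
        assert np.array_equal(wc.samples_uA, -wa.samples_uA)
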