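"""Charge-balanced biphasic pulse families and their synthesis.

Cochlear implants deliver charge-balanced biphasic current pulses: two
consecutive phases of opposite polarity whose signed charges cancel, so no
net charge is injected into the tissue.  This module defines the three
parametric families used to sweep stimulus intensity (total biphasic charge
``Q``) on a fixed schedule:

``rectangular``
    Constant-current phases of fixed duration; the amplitude is solved from
    the requested charge.
``fixed_slope``
    Each phase ramps linearly from 0 to a peak at a constant slope (given as
    an angle, with ``tan(angle)`` read in µA/µs); charge is increased by
    lengthening the ramp, which raises both duration and peak together.
``fixed_amplitude``
    Each phase ramps linearly from 0 to a fixed peak; charge is increased by
    lengthening the ramp, which lowers the slope.

Unit system throughout: current in µA, time in µs, charge in nC
(1 µA·µs = 1 pC, so 1 nC = 1000 µA·µs).

Charge convention
-----------------
"Charge level" is the *total biphasic* charge magnitude: for triangular
phases each phase carries ``A·t/2``, so ``Q = A·t``; for rectangular phases
``Q = 2·A·t``.  This is the only convention consistent with the standard
protocol figures (a 750 µA peak spanning 4–42 µs phase durations across a
3–31.5 nC schedule, and 500 µA spanning 6–63 µs).  A per-phase convention is
available via ``charge_convention="per_phase"``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Family",
    "Polarity",
    "PulseShapeSpec",
    "ChargeSchedule",
    "PhaseSolution",
    "Waveform",
    "PROTOCOL_SHAPES",
    "make_schedule",
    "parse_shape_label",
    "solve_phase",
    "synthesize",
    "total_charge",
    "signed_charge",
    "ScheduleError",
    "PulseDomainError",
    "DegenerateWaveformError",
]

UAUS_PER_NC = 1000.0  # 1 nC = 1000 µA·µs

#: Device current-quantization step, µA.
DEFAULT_CURRENT_STEP_UA = 25.0
#: Shortest dwell time the stimulator can realise, µs (device resolution 3-4 µs).
DEFAULT_MIN_DWELL_US = 3.5
#: Default phase duration for rectangular pulses, µs (charge is then the only
#: varying quantity, mirroring the ramp families).
DEFAULT_RECT_PHASE_US = 21.0


class ScheduleError(ValueError):
    """Invalid charge-schedule parameters."""


class PulseDomainError(ValueError):
    """Pulse parameters outside the solvable domain."""


class DegenerateWaveformError(ValueError):
    """Requested waveform cannot be represented on the sample grid."""


class Family(str, enum.Enum):
    RECTANGULAR = "rectangular"
    FIXED_SLOPE = "fixed_slope"
    FIXED_AMPLITUDE = "fixed_amplitude"


class Polarity(str, enum.Enum):
    CATHODIC = "cathodic"
    ANODIC = "anodic"

    @property
    def first_phase_sign(self) -> int:
        return -1 if self is Polarity.CATHODIC else +1

    @property
    def suffix(self) -> str:
        return "C" if self is Polarity.CATHODIC else "A"


@dataclass(frozen=True)
class PulseShapeSpec:
    """Parametric description of one pulse family/polarity.

    Exactly the parameter matching ``family`` must be set:
    ``slope_angle_deg`` for fixed-slope ramps (in (0, 90)),
    ``peak_amplitude_uA`` for fixed-amplitude ramps (> 0), and
    ``rect_phase_duration_us`` for rectangular pulses (> 0).
    """

    family: Family
    polarity_first: Polarity = Polarity.CATHODIC
    slope_angle_deg: float | None = None
    peak_amplitude_uA: float | None = None
    rect_phase_duration_us: float | None = None

    def __post_init__(self) -> None:
        fam = Family(self.family)
        pol = Polarity(self.polarity_first)
        object.__setattr__(self, "family", fam)
        object.__setattr__(self, "polarity_first", pol)
        required = {
            Family.FIXED_SLOPE: "slope_angle_deg",
            Family.FIXED_AMPLITUDE: "peak_amplitude_uA",
            Family.RECTANGULAR: "rect_phase_duration_us",
        }[fam]
        for name in ("slope_angle_deg", "peak_amplitude_uA", "rect_phase_duration_us"):
            val = getattr(self, name)
            if name == required:
                if val is None:
                    raise PulseDomainError(f"{fam.value} spec requires {name}")
            elif val is not None:
                raise PulseDomainError(f"{name} is not a parameter of family {fam.value}")
        if fam is Family.FIXED_SLOPE and not 0.0 < self.slope_angle_deg < 90.0:
            raise PulseDomainError("slope_angle_deg must lie in (0, 90)")
        if fam is Family.FIXED_AMPLITUDE and self.peak_amplitude_uA <= 0:
            raise PulseDomainError("peak_amplitude_uA must be positive")
        if fam is Family.RECTANGULAR and self.rect_phase_duration_us <= 0:
            raise PulseDomainError("rect_phase_duration_us must be positive")

    @property
    def slope_uA_per_us(self) -> float | None:
        """Ramp slope ``tan(angle)`` in µA/µs (fixed-slope family only)."""
        if self.family is Family.FIXED_SLOPE:
            return math.tan(math.radians(self.slope_angle_deg))
        return None

    @property
    def label(self) -> str:
        """Conventional shape label, e.g. ``FS80-C`` or ``Rec-A``."""
        if self.family is Family.RECTANGULAR:
            stem = "Rec"
        elif self.family is Family.FIXED_SLOPE:
            stem = f"FS{self.slope_angle_deg:g}"
        else:
            stem = f"FA{self.peak_amplitude_uA:g}"
        return f"{stem}-{self.polarity_first.suffix}"

    def with_polarity(self, polarity: Polarity | str) -> "PulseShapeSpec":
        return replace(self, polarity_first=Polarity(polarity))


#: The five stimulus families of the standard protocol (cathodic-first).
PROTOCOL_SHAPES: dict[str, PulseShapeSpec] = {
    "Rec": PulseShapeSpec(Family.RECTANGULAR, rect_phase_duration_us=DEFAULT_RECT_PHASE_US),
    "FS85": PulseShapeSpec(Family.FIXED_SLOPE, slope_angle_deg=85.0),
    "FS80": PulseShapeSpec(Family.FIXED_SLOPE, slope_angle_deg=80.0),
    "FA750": PulseShapeSpec(Family.FIXED_AMPLITUDE, peak_amplitude_uA=750.0),
    "FA500": PulseShapeSpec(Family.FIXED_AMPLITUDE, peak_amplitude_uA=500.0),
}


def parse_shape_label(label: str) -> PulseShapeSpec:
    """Parse a shape label like ``"FS80-C"`` or ``"Rec-A"`` into a spec."""
    stem, sep, suffix = label.partition("-")
    if stem not in PROTOCOL_SHAPES:
        raise PulseDomainError(
            f"unknown shape {label!r}; known stems: {sorted(PROTOCOL_SHAPES)}"
        )
    spec = PROTOCOL_SHAPES[stem]
    if sep:
        if suffix not in ("C", "A"):
            raise PulseDomainError(f"unknown polarity suffix {suffix!r} in {label!r}")
        spec = spec.with_polarity(Polarity.CATHODIC if suffix == "C" else Polarity.ANODIC)
    return spec


@dataclass(frozen=True)
class ChargeSchedule:
    """Ordered charge levels with the repetition structure of the protocol.

    The reference configuration is 20 levels spanning 3-31.5 nC, 32
    repetitions per level, pulses presented at 4 Hz (250 ms inter-pulse
    interval).
    """

    levels_nC: tuple[float, ...]
    n_repetitions: int = 32
    stim_rate_Hz: float = 4.0

    def __post_init__(self) -> None:
        levels = tuple(float(q) for q in self.levels_nC)
        if len(levels) < 1:
            raise ScheduleError("schedule needs at least one level")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ScheduleError("charge levels must be strictly increasing")
        if self.n_repetitions < 1:
            raise ScheduleError("n_repetitions must be positive")
        if self.stim_rate_Hz <= 0:
            raise ScheduleError("stim_rate_Hz must be positive")
        object.__setattr__(self, "levels_nC", levels)

    @property
    def n_levels(self) -> int:
        return len(self.levels_nC)

    @property
    def inter_pulse_interval_ms(self) -> float:
        return 1000.0 / self.stim_rate_Hz


def make_schedule(
    min_nC: float = 3.0,
    max_nC: float = 31.5,
    n_levels: int = 20,
    n_repetitions: int = 32,
    rate_Hz: float = 4.0,
) -> ChargeSchedule:
    """Build a uniformly spaced charge schedule from ``min_nC`` to ``max_nC``.

    Defaults reproduce the reference protocol: 20 levels from 3 to 31.5 nC
    (1.5 nC step), 32 repetitions per level, 4 Hz presentation.
    """
    if n_levels < 2:
        raise ScheduleError("n_levels must be at least 2")
    if not min_nC < max_nC:
        raise ScheduleError("min_nC must be below max_nC")
    levels = np.linspace(min_nC, max_nC, n_levels)
    return ChargeSchedule(tuple(levels), n_repetitions=n_repetitions, stim_rate_Hz=rate_Hz)


@dataclass(frozen=True)
class PhaseSolution:
    """Single-phase geometry realising a requested total biphasic charge.

    ``subquantum`` flags solutions whose amplitude falls below one current
    step or whose duration falls below the device dwell resolution; such
    pulses are representable only approximately on the hardware.
    """

    peak_amplitude_uA: float
    phase_duration_us: float
    slope_uA_per_us: float
    subquantum: bool = False


def solve_phase(
    spec: PulseShapeSpec,
    Q_nC: float,
    *,
    charge_convention: str = "total",
    current_step_uA: float = DEFAULT_CURRENT_STEP_UA,
    min_dwell_us: float = DEFAULT_MIN_DWELL_US,
) -> PhaseSolution:
    """Solve peak amplitude and phase duration for a target charge level.

    With the default ``"total"`` convention ``Q_nC`` is the total biphasic
    charge magnitude: ``Q = A·t`` for triangular phases and ``Q = 2·A·t``
    for rectangular phases.  ``"per_phase"`` reads ``Q_nC`` as the charge of
    a single phase instead.

    Closed forms (Q in µA·µs):

    - fixed amplitude:  ``t = Q / A``
    - fixed slope:      ``t = sqrt(Q / s)``, ``A = sqrt(Q·s)`` with
      ``s = tan(angle)`` in µA/µs
    - rectangular:      ``A = Q / (2·t)`` at the configured phase duration
    """
    if Q_nC <= 0:
        raise PulseDomainError(f"charge must be positive, got {Q_nC} nC")
    if charge_convention not in ("total", "per_phase"):
        raise PulseDomainError(f"unknown charge convention {charge_convention!r}")
    q = Q_nC * UAUS_PER_NC  # µA·µs, total biphasic
    if charge_convention == "per_phase":
        q *= 2.0

    if spec.family is Family.FIXED_AMPLITUDE:
        amp = spec.peak_amplitude_uA
        dur = q / amp
        slope = amp / dur
    elif spec.family is Family.FIXED_SLOPE:
        slope = spec.slope_uA_per_us
        dur = math.sqrt(q / slope)
        amp = slope * dur
    else:  # rectangular
        dur = spec.rect_phase_duration_us
        amp = q / (2.0 * dur)
        slope = math.inf
    subquantum = amp < current_step_uA or dur < min_dwell_us
    return PhaseSolution(
        peak_amplitude_uA=amp,
        phase_duration_us=dur,
        slope_uA_per_us=slope,
        subquantum=subquantum,
    )


@dataclass
class Waveform:
    """Sampled biphasic current trace with its realised charge.

    ``samples_uA`` holds signed currents (negative = cathodic) on a uniform
    grid of ``sample_period_us``; ``realized_charge_nC`` is the integral of
    |i(t)| and ``charge_imbalance_nC`` the signed integral (zero for a
    charge-balanced pulse).  When quantisation is on, sample magnitudes are
    multiples of ``current_step_uA`` and ``constraint_violation`` marks
    pulses whose staircase could not honour the device dwell resolution.
    """

    sample_period_us: float
    samples_uA: np.ndarray
    realized_charge_nC: float
    charge_imbalance_nC: float
    current_step_uA: float | None = None
    quantized: bool = False
    constraint_violation: bool = False
    n_staircase_levels: int | None = None
    spec: PulseShapeSpec | None = None
    target_charge_nC: float | None = None

    @property
    def times_us(self) -> np.ndarray:
        """Midpoint sample times, µs."""
        n = len(self.samples_uA)
        return (np.arange(n) + 0.5) * self.sample_period_us

    @property
    def duration_us(self) -> float:
        return len(self.samples_uA) * self.sample_period_us


def _phase_profile(spec: PulseShapeSpec, sol: PhaseSolution, n: int) -> np.ndarray:
    """Unsigned single-phase current at the n midpoint sample times."""
    if spec.family is Family.RECTANGULAR:
        return np.full(n, sol.peak_amplitude_uA)
    # linear ramp 0 -> peak; midpoint sampling integrates the triangle exactly
    return sol.peak_amplitude_uA * (np.arange(n) + 0.5) / n


def synthesize(
    spec: PulseShapeSpec,
    Q_nC: float,
    *,
    sample_period_us: float = 1.0,
    current_step_uA: float = DEFAULT_CURRENT_STEP_UA,
    quantize: bool = False,
    min_dwell_us: float | None = None,
    mirrored_second_phase: bool = False,
    charge_convention: str = "total",
) -> Waveform:
    """Synthesize the sampled biphasic waveform for one charge level.

    The two phases are mirrored in amplitude (the first phase's sign follows
    the spec's polarity); for ramp families each phase independently ramps
    from 0 to the peak, unless ``mirrored_second_phase`` reverses the second
    phase in time (a ramp-down).  Samples are taken at interval midpoints,
    which integrates both the rectangle and the triangle exactly, so the
    continuous waveform's realised charge equals ``Q_nC`` to rounding error.

    With ``quantize=True`` the ramp becomes a staircase whose levels are
    multiples of ``current_step_uA`` (``ceil(peak/step)`` levels); the
    sample period is then uniformly rescaled - equivalently, every step
    dwell is scaled - so the staircase still integrates to ``Q_nC``, which
    preserves the printed peak amplitudes.  If the staircase would need
    steps dwelling shorter than ``min_dwell_us`` (default: one sample
    period; set 3.5 µs to enforce the device timing resolution on dwells)
    the step count is capped at a coarser effective step and
    ``constraint_violation`` is set - this bites at the shortest phases,
    where tens of 25 µA steps cannot fit a few-µs ramp.
    """
    if sample_period_us <= 0:
        raise PulseDomainError("sample_period_us must be positive")
    if min_dwell_us is None:
        min_dwell_us = sample_period_us
    sol = solve_phase(
        spec,
        Q_nC,
        charge_convention=charge_convention,
        current_step_uA=current_step_uA,
    )
    t = sol.phase_duration_us
    if t < sample_period_us:
        raise DegenerateWaveformError(
            f"phase duration {t:.3g} µs shorter than sample period "
            f"{sample_period_us:.3g} µs"
        )
    n = max(1, round(t / sample_period_us))
    dt = t / n  # effective period so the phase spans exactly t
    phase = _phase_profile(spec, sol, n)

    violation = False
    n_levels = None
    if quantize:
        eff_step = current_step_uA
        n_levels = math.ceil(sol.peak_amplitude_uA / eff_step)
        n_cap = max(1, math.floor(t / min_dwell_us))
        if n_levels > n_cap:
            eff_step = current_step_uA * math.ceil(
                sol.peak_amplitude_uA / (current_step_uA * n_cap)
            )
            n_levels = math.ceil(sol.peak_amplitude_uA / eff_step)
            violation = True
        phase = eff_step * np.ceil(phase / eff_step - 1e-12)
        # uniform dwell rescaling: staircase integrates to exactly Q/2 per phase
        area = float(phase.sum()) * dt  # µA·µs
        target = Q_nC * UAUS_PER_NC / 2.0
        if charge_convention == "per_phase":
            target = Q_nC * UAUS_PER_NC
        if area > 0:
            dt *= target / area

    second = phase[::-1] if mirrored_second_phase else phase
    sign = spec.polarity_first.first_phase_sign
    samples = np.concatenate([sign * phase, -sign * second])

    realized = float(np.abs(samples).sum()) * dt / UAUS_PER_NC
    imbalance = float(samples.sum()) * dt / UAUS_PER_NC
    return Waveform(
        sample_period_us=dt,
        samples_uA=samples,
        realized_charge_nC=realized,
        charge_imbalance_nC=imbalance,
        current_step_uA=current_step_uA if quantize else None,
        quantized=quantize,
        constraint_violation=violation,
        n_staircase_levels=n_levels,
        spec=spec,
        target_charge_nC=Q_nC,
    )


def total_charge(w: Waveform) -> float:
    """Total absolute charge of a waveform in nC: ``Σ|i|·Δt``."""
    if len(w.samples_uA) == 0:
        raise PulseDomainError("waveform is empty")
    return float(np.abs(w.samples_uA).sum()) * w.sample_period_us / UAUS_PER_NC


def signed_charge(w: Waveform) -> float:
    """Signed (net) charge of a waveform in nC; ~0 for balanced pulses."""
    if len(w.samples_uA) == 0:
        raise PulseDomainError("waveform is empty")
    return float(w.samples_uA.sum()) * w.sample_period_us / UAUS_PER_NC
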