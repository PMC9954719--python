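"""Growth-function quantification of evoked multi-unit activity.

For each recording x pulse-shape the evoked discharge at every charge level
is quantified over a 45 ms window starting at pulse onset; spikes earlier
than 9 ms are excluded (responses with shorter latency than the acoustic
onset floor of guinea-pig primary auditory cortex are treated as artefact),
so the default evoked window is [9, 45) ms.  Spontaneous activity is taken
from the last 100 ms of the 250 ms inter-pulse interval, [150, 250) ms.
Counts are converted to firing rates (AP/s) by the window duration and
averaged across the 32 repetitions of each level.

Four parameters summarise each growth function:

- ``MaxFR``: maximal mean evoked rate minus the spontaneous mean;
- the charge level at which MaxFR occurs (lowest charge on ties);
- ``Threshold``: the lowest charge whose raw evoked rate exceeds the
  spontaneous mean plus three across-trial SDs of the spontaneous rate,
  confirmed by the next two consecutive levels also being significant;
- ``Dynamic range``: charge at MaxFR minus threshold; ``DynRange80``
  substitutes the first charge reaching 80% of MaxFR for the MaxFR charge.

The three-SD multiplier and both windows are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pulses import ChargeSchedule
from .simulate import EVOKED_WINDOW_MS, SPONT_WINDOW_MS

__all__ = [
    "GrowthFunction",
    "QuantResult",
    "InputFormatError",
    "IncompleteProtocolError",
    "count_windows",
    "build_growth_function",
    "detect_threshold",
    "extract_params",
    "quantify_events",
    "filter_early_onset_recordings",
]


class InputFormatError(ValueError):
    """Spike-event table violates the expected format."""


class IncompleteProtocolError(ValueError):
    """Trial grid does not cover the full schedule."""


@dataclass
class GrowthFunction:
    """Per-level evoked firing rates of one recording under one shape.

    ``mean_rate_Hz`` is the raw (not baseline-subtracted) mean evoked-window
    rate per level; ``subtracted_rate_Hz`` removes the spontaneous mean.
    Spontaneous statistics are pooled over all trials of the recording x
    shape (the protocol gives n_levels x n_repetitions baseline windows).
    """

    levels_nC: np.ndarray
    mean_rate_Hz: np.ndarray
    sd_rate_Hz: np.ndarray
    spont_mean_Hz: float
    spont_sd_Hz: float
    evoked_window_ms: tuple[float, float] = EVOKED_WINDOW_MS
    spont_window_ms: tuple[float, float] = SPONT_WINDOW_MS
    n_repetitions: int | None = None
    recording_id: str | None = None
    shape_id: str | None = None

    @property
    def subtracted_rate_Hz(self) -> np.ndarray:
        return self.mean_rate_Hz - self.spont_mean_Hz

    @property
    def n_levels(self) -> int:
        return len(self.levels_nC)


@dataclass
class QuantResult:
    """The four growth-function parameters plus DynRange80.

    ``threshold_nC`` and both dynamic ranges are NaN when the recording
    never produced a confirmed significant response (``significant`` False).
    """

    max_fr_Hz: float
    charge_at_max_nC: float
    threshold_nC: float
    dyn_range_nC: float
    dyn_range80_nC: float
    significant: bool
    max_fr_sem_Hz: float = np.nan
    spont_mean_Hz: float = np.nan
    spont_sd_Hz: float = np.nan
    recording_id: str | None = None
    shape_id: str | None = None


PARAM_NAMES = ("max_fr_Hz", "threshold_nC", "charge_at_max_nC", "dyn_range_nC")


def _validate_events(events: pd.DataFrame, ipi_ms: float) -> None:
    needed = {"recording_id", "shape_id", "level_index", "trial_index", "spike_time_ms"}
    missing = needed - set(events.columns)
    if missing:
        raise InputFormatError(f"spike-event table missing columns: {sorted(missing)}")
    t = events["spike_time_ms"].to_numpy()
    if len(t) and (np.min(t) < 0 or np.max(t) >= ipi_ms):
        raise InputFormatError(
            f"spike times must lie in [0, {ipi_ms}) ms relative to pulse onset"
        )


def count_windows(
    events: pd.DataFrame,
    schedule: ChargeSchedule,
    evoked_window_ms: tuple[float, float] = EVOKED_WINDOW_MS,
    spont_window_ms: tuple[float, float] = SPONT_WINDOW_MS,
) -> pd.DataFrame:
    """Count spikes per trial in the evoked and spontaneous windows.

    Returns one row per (recording_id, shape_id, level_index, trial_index)
    over the complete schedule grid - trials without spikes appear with zero
    counts - with the counts converted to rates in Hz by the respective
    window durations.
    """
    ipi = schedule.inter_pulse_interval_ms
    _validate_events(events, ipi)
    for name, (lo, hi) in (("evoked", evoked_window_ms), ("spontaneous", spont_window_ms)):
        if not (0 <= lo < hi <= ipi):
            raise InputFormatError(f"{name} window {lo, hi} outside [0, {ipi}] ms")

    L, T = schedule.n_levels, schedule.n_repetitions
    lev = events["level_index"].to_numpy(dtype=np.int64)
    tri = events["trial_index"].to_numpy(dtype=np.int64)
    if len(lev) and (lev.min() < 1 or lev.max() > L or tri.min() < 1 or tri.max() > T):
        raise InputFormatError("level_index/trial_index outside the schedule grid")

    groups, group_keys = pd.factorize(
        events["recording_id"].astype(str) + "\x1f" + events["shape_id"].astype(str),
        sort=True,
    )
    G = max(len(group_keys), 1)
    idx = groups * (L * T) + (lev - 1) * T + (tri - 1)
    t = events["spike_time_ms"].to_numpy(dtype=float)

    def window_counts(lo: float, hi: float) -> np.ndarray:
        mask = (t >= lo) & (t < hi)
        return np.bincount(idx[mask], minlength=G * L * T)

    ev = window_counts(*evoked_window_ms)
    sp = window_counts(*spont_window_ms)
    ev_dur_s = (evoked_window_ms[1] - evoked_window_ms[0]) / 1000.0
    sp_dur_s = (spont_window_ms[1] - spont_window_ms[0]) / 1000.0

    keys = [k.split("\x1f") for k in group_keys] or [["", ""]]
    rec = np.repeat([k[0] for k in keys], L * T)
    shp = np.repeat([k[1] for k in keys], L * T)
    lev_g = np.tile(np.repeat(np.arange(1, L + 1), T), G)
    tri_g = np.tile(np.arange(1, T + 1), G * L)
    return pd.DataFrame(
        {
            "recording_id": rec,
            "shape_id": shp,
            "level_index": lev_g,
            "trial_index": tri_g,
            "evoked_count": ev,
            "spont_count": sp,
            "evoked_rate_Hz": ev / ev_dur_s,
            "spont_rate_Hz": sp / sp_dur_s,
        }
    )


def build_growth_function(
    counts: pd.DataFrame,
    schedule: ChargeSchedule,
    *,
    recording_id: str | None = None,
    shape_id: str | None = None,
) -> GrowthFunction:
    """Average per-trial rates into one recording's growth function.

    ``counts`` must be the complete trial grid of a single recording x shape
    (as produced by :func:`count_windows`); the spontaneous mean and SD are
    pooled over all its trials.
    """
    sub = counts
    if recording_id is not None:
        sub = sub[sub["recording_id"] == recording_id]
    if shape_id is not None:
        sub = sub[sub["shape_id"] == shape_id]
    if sub[["recording_id", "shape_id"]].drop_duplicates().shape[0] > 1:
        raise InputFormatError(
            "counts span several recording x shape groups; pass recording_id/shape_id"
        )
    present = np.sort(sub["level_index"].unique())
    if len(present) != schedule.n_levels or len(sub) != schedule.n_levels * schedule.n_repetitions:
        raise IncompleteProtocolError(
            f"expected the full {schedule.n_levels} x {schedule.n_repetitions} "
            f"trial grid, got {len(sub)} trials over {len(present)} levels"
        )
    rates = (
        sub.sort_values(["level_index", "trial_index"])["evoked_rate_Hz"]
        .to_numpy()
        .reshape(schedule.n_levels, schedule.n_repetitions)
    )
    spont = sub["spont_rate_Hz"].to_numpy()
    rid = sub["recording_id"].iloc[0] if len(sub) else recording_id
    sid = sub["shape_id"].iloc[0] if len(sub) else shape_id
    return GrowthFunction(
        levels_nC=np.asarray(schedule.levels_nC),
        mean_rate_Hz=rates.mean(axis=1),
        sd_rate_Hz=rates.std(axis=1, ddof=1),
        spont_mean_Hz=float(spont.mean()),
        spont_sd_Hz=float(spont.std(ddof=1)),
        n_repetitions=schedule.n_repetitions,
        recording_id=rid,
        shape_id=sid,
    )


def significance_pattern(gf: GrowthFunction, sd_multiplier: float = 3.0) -> np.ndarray:
    """Boolean per-level significance: raw rate > spont mean + m x spont SD."""
    return gf.mean_rate_Hz > gf.spont_mean_Hz + sd_multiplier * gf.spont_sd_Hz


def _first_confirmed(sig: np.ndarray) -> int:
    """Index of the first True followed by two consecutive Trues, else -1."""
    if len(sig) < 3:
        raise IncompleteProtocolError("threshold detection needs at least 3 levels")
    runs = sig[:-2] & sig[1:-1] & sig[2:]
    hits = np.flatnonzero(runs)
    return int(hits[0]) if len(hits) else -1


def detect_threshold(gf: GrowthFunction, sd_multiplier: float = 3.0) -> float | None:
    """Response threshold in nC, or ``None`` when never confirmed.

    Level ``L`` is significant when its raw evoked rate exceeds the
    spontaneous mean plus ``sd_multiplier`` spontaneous SDs; the threshold
    is the lowest significant level whose next two levels are also
    significant (the confirmation rule guards against isolated flukes, so
    a final-level or penultimate-level lone hit never counts).
    """
    i = _first_confirmed(significance_pattern(gf, sd_multiplier))
    return None if i < 0 else float(gf.levels_nC[i])


def extract_params(gf: GrowthFunction, sd_multiplier: float = 3.0) -> QuantResult:
    """Extract MaxFR, charge at MaxFR, threshold and both dynamic ranges.

    MaxFR is the maximum of the baseline-subtracted mean rates; ties take
    the lowest charge (the conservative choice for the dynamic range).
    Dynamic ranges are only defined when a threshold exists.  DynRange80 is
    the charge gap from threshold to the first level whose subtracted rate
    reaches 80% of MaxFR.
    """
    sub = gf.subtracted_rate_Hz
    i_max = int(np.argmax(sub))  # argmax returns the first (lowest-charge) tie
    max_fr = float(sub[i_max])
    charge_at_max = float(gf.levels_nC[i_max])
    thr = detect_threshold(gf, sd_multiplier)
    if thr is None:
        dyn = dyn80 = np.nan
    else:
        dyn = charge_at_max - thr
        at80 = np.flatnonzero(sub >= 0.8 * max_fr)
        dyn80 = float(gf.levels_nC[at80[0]]) - thr if len(at80) else np.nan
    return QuantResult(
        max_fr_Hz=max_fr,
        charge_at_max_nC=charge_at_max,
        threshold_nC=np.nan if thr is None else thr,
        dyn_range_nC=dyn,
        dyn_range80_nC=dyn80,
        significant=thr is not None,
        max_fr_sem_Hz=(
            float(gf.sd_rate_Hz[i_max]) / np.sqrt(gf.n_repetitions)
            if gf.n_repetitions
            else np.nan
        ),
        spont_mean_Hz=gf.spont_mean_Hz,
        spont_sd_Hz=gf.spont_sd_Hz,
        recording_id=gf.recording_id,
        shape_id=gf.shape_id,
    )


def quantify_events(
    events: pd.DataFrame,
    schedule: ChargeSchedule,
    *,
    sd_multiplier: float = 3.0,
    evoked_window_ms: tuple[float, float] = EVOKED_WINDOW_MS,
    spont_window_ms: tuple[float, float] = SPONT_WINDOW_MS,
) -> pd.DataFrame:
    """Quantify every recording x shape in a pooled spike-event table.

    Vectorised pipeline equivalent to running :func:`count_windows` ->
    :func:`build_growth_function` -> :func:`extract_params` per group;
    returns one row per (recording_id, shape_id) with the QuantResult
    fields.
    """
    ipi = schedule.inter_pulse_interval_ms
    _validate_events(events, ipi)
    L, T = schedule.n_levels, schedule.n_repetitions
    levels = np.asarray(schedule.levels_nC)

    groups, group_keys = pd.factorize(
        events["recording_id"].astype(str) + "\x1f" + events["shape_id"].astype(str),
        sort=True,
    )
    if len(group_keys) == 0:
        raise InputFormatError("empty spike-event table")
    G = len(group_keys)
    lev = events["level_index"].to_numpy(dtype=np.int64)
    tri = events["trial_index"].to_numpy(dtype=np.int64)
    if lev.min() < 1 or lev.max() > L or tri.min() < 1 or tri.max() > T:
        raise InputFormatError("level_index/trial_index outside the schedule grid")
    idx = groups * (L * T) + (lev - 1) * T + (tri - 1)
    t = events["spike_time_ms"].to_numpy(dtype=float)

    def grid_counts(lo: float, hi: float) -> np.ndarray:
        mask = (t >= lo) & (t < hi)
        return np.bincount(idx[mask], minlength=G * L * T).reshape(G, L, T)

    ev_dur_s = (evoked_window_ms[1] - evoked_window_ms[0]) / 1000.0
    sp_dur_s = (spont_window_ms[1] - spont_window_ms[0]) / 1000.0
    ev = grid_counts(*evoked_window_ms) / ev_dur_s  # (G, L, T) rates, Hz
    sp = grid_counts(*spont_window_ms).reshape(G, L * T) / sp_dur_s

    mean_raw = ev.mean(axis=2)  # (G, L)
    spont_mean = sp.mean(axis=1)
    spont_sd = sp.std(axis=1, ddof=1)
    sub = mean_raw - spont_mean[:, None]

    sig = mean_raw > (spont_mean + sd_multiplier * spont_sd)[:, None]
    runs = sig[:, :-2] & sig[:, 1:-1] & sig[:, 2:]
    has_thr = runs.any(axis=1)
    i_thr = np.argmax(runs, axis=1)
    thr = np.where(has_thr, levels[i_thr], np.nan)

    i_max = np.argmax(sub, axis=1)  # first max = lowest charge on ties
    max_fr = sub[np.arange(G), i_max]
    max_fr_sem = ev.std(axis=2, ddof=1)[np.arange(G), i_max] / np.sqrt(T)
    charge_at_max = levels[i_max]
    dyn = np.where(has_thr, charge_at_max - thr, np.nan)
    reach80 = sub >= 0.8 * max_fr[:, None]
    i_80 = np.argmax(reach80, axis=1)
    dyn80 = np.where(has_thr & reach80.any(axis=1), levels[i_80] - thr, np.nan)

    keys = [k.split("\x1f") for k in group_keys]
    return pd.DataFrame(
        {
            "recording_id": [k[0] for k in keys],
            "shape_id": [k[1] for k in keys],
            "max_fr_Hz": max_fr,
            "charge_at_max_nC": charge_at_max,
            "threshold_nC": thr,
            "dyn_range_nC": dyn,
            "dyn_range80_nC": dyn80,
            "significant": has_thr,
            "max_fr_sem_Hz": max_fr_sem,
            "spont_mean_Hz": spont_mean,
            "spont_sd_Hz": spont_sd,
        }
    )


def filter_early_onset_recordings(
    events: pd.DataFrame,
    schedule: ChargeSchedule,
    min_latency_ms: float = EVOKED_WINDOW_MS[0],
) -> pd.DataFrame:
    """Optionally drop recording x shape groups with early onset latency.

    The default analysis excludes *spikes* earlier than 9 ms via the evoked
    window; this alternative reading excludes whole recordings whose onset
    latency (median first-spike time within [0, 45) ms over the trials of
    the top charge level) falls below ``min_latency_ms``.
    """
    top = events[events["level_index"] == schedule.n_levels]
    early = top[(top["spike_time_ms"] >= 0) & (top["spike_time_ms"] < 45.0)]
    first = (
        early.groupby(["recording_id", "shape_id", "trial_index"])["spike_time_ms"]
        .min()
        .groupby(["recording_id", "shape_id"])
        .median()
    )
    drop = set(first[first < min_latency_ms].index)
    if not drop:
        return events
    key = list(zip(events["recording_id"], events["shape_id"]))
    keep = ~pd.Series(key, index=events.index).isin(drop)
    return events[keep].reset_index(drop=True)
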