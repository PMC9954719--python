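"""Window counting, growth functions, threshold rule and parameter extraction."""

import numpy as np
import pandas as pd
import pytest

from rampulse.growth import (
    GrowthFunction,
    IncompleteProtocolError,
    InputFormatError,
    build_growth_function,
    count_windows,
    detect_threshold,
    extract_params,
    quantify_events,
    significance_pattern,
)
from rampulse.pulses import make_schedule


def events_df(times_ms, level=1, trial=1, rec="r0", shape="Rec-C"):
    return pd.DataFrame(
        {
            "recording_id": rec,
            "shape_id": shape,
            "level_index": level,
            "trial_index": trial,
            "spike_time_ms": list(times_ms),
        }
    )


def make_gf(mean_rates, spont_mean=0.0, spont_sd=1.0, levels=None):
    mean_rates = np.asarray(mean_rates, dtype=float)
    if levels is None:
        levels = 3.0 + 1.5 * np.arange(len(mean_rates))
    return GrowthFunction(
        levels_nC=np.asarray(levels, dtype=float),
        mean_rate_Hz=mean_rates,
        sd_rate_Hz=np.zeros_like(mean_rates),
        spont_mean_Hz=spont_mean,
        spont_sd_Hz=spont_sd,
    )


@pytest.fixture(scope="module")
def small_schedule():
    return make_schedule(3, 9, 5, 2, 4)


class TestCountWindows:
    def test_evoked_window_inclusion(self, small_schedule):
        c = count_windows(events_df([10.0, 20.0, 44.0]), small_schedule)
        row = c[(c.level_index == 1) & (c.trial_index == 1)].iloc[0]
        assert row.evoked_count == 3
        assert row.evoked_rate_Hz == pytest.approx(3 / 0.036)

    def test_sub_9ms_spikes_discarded(self, small_schedule):
        c = count_windows(events_df([5.0, 8.9]), small_schedule)
        assert c["evoked_count"].sum() == 0

    def test_spontaneous_rate_conversion(self, small_schedule):
        c = count_windows(events_df([150.0, 175.0, 200.0, 249.9]), small_schedule)
        row = c[(c.level_index == 1) & (c.trial_index == 1)].iloc[0]
        assert row.spont_rate_Hz == pytest.approx(40.0)  # 4 spikes / 0.1 s

    def test_full_grid_emitted_with_zeros(self, small_schedule):
        c = count_windows(events_df([10.0]), small_schedule)
        assert len(c) == small_schedule.n_levels * small_schedule.n_repetitions
        assert (c["evoked_count"] == 0).sum() == len(c) - 1

    def test_out_of_range_times_rejected(self, small_schedule):
        with pytest.raises(InputFormatError):
            count_windows(events_df([-1.0]), small_schedule)
        with pytest.raises(InputFormatError):
            count_windows(events_df([250.0]), small_schedule)


class TestBuildGrowthFunction:
    def test_baseline_subtraction_arithmetic(self, small_schedule):
        # evoked counts {0,0,1,2,2} per trial, 2 baseline spikes per trial:
        # mean rates are counts/36 ms, baseline 20 Hz, subtraction is exact
        rows = []
        for li, n in enumerate([0, 0, 1, 2, 2], start=1):
            for ti in (1, 2):
                rows.append(events_df(np.linspace(10, 40, n), level=li, trial=ti))
                rows.append(events_df([160.0, 240.0], level=li, trial=ti))
        ev = pd.concat(rows, ignore_index=True)
        gf = build_growth_function(count_windows(ev, small_schedule), small_schedule)
        assert np.allclose(gf.mean_rate_Hz, np.array([0, 0, 1, 2, 2]) / 0.036)
        assert gf.spont_mean_Hz == pytest.approx(20.0)  # 2 spikes / 0.1 s
        assert np.allclose(gf.subtracted_rate_Hz, gf.mean_rate_Hz - 20.0)

    def test_all_zero_counts(self, small_schedule):
        c = count_windows(events_df([100.0]), small_schedule)  # outside both windows
        gf = build_growth_function(c, small_schedule)
        assert np.all(gf.mean_rate_Hz == 0)
        assert gf.spont_mean_Hz == 0.0

    def test_missing_levels_rejected(self, small_schedule):
        c = count_windows(events_df([10.0]), small_schedule)
        incomplete = c[c.level_index != 3]
        with pytest.raises(IncompleteProtocolError):
            build_growth_function(incomplete, small_schedule)

    def test_recovers_simulated_plateau(self, schedule, sim_events, ground_truth):
        gf = build_growth_function(count_windows(sim_events, schedule), schedule)
        plateau = gf.subtracted_rate_Hz[-5:].mean()
        assert plateau == pytest.approx(ground_truth.Rmax_Hz, rel=0.25)


class TestDetectThreshold:
    def test_first_confirmed_run(self):
        sig = [False] * 3 + [True] * 17
        gf = make_gf([10.0 if s else 0.0 for s in sig], spont_sd=1.0)
        assert detect_threshold(gf) == gf.levels_nC[3]

    def test_isolated_hits_do_not_count(self):
        pattern = [False, True, False, True, False, True, False, False]
        gf = make_gf([10.0 if s else 0.0 for s in pattern])
        assert detect_threshold(gf) is None

    def test_trailing_pair_needs_two_successors(self):
        pattern = [False] * 18 + [True, True]
        gf = make_gf([10.0 if s else 0.0 for s in pattern])
        assert detect_threshold(gf) is None

    def test_exhaustive_scan_oracle(self, rng):
        """Rule agrees with a brute-force scan on random significance patterns."""
        for _ in range(1000):
            n = int(rng.integers(3, 21))
            sig = rng.random(n) < rng.uniform(0.1, 0.9)
            gf = make_gf(np.where(sig, 10.0, 0.0), spont_sd=1.0)
            # oracle: scan every level for a run of three
            expect = None
            for i in range(n - 2):
                if sig[i] and sig[i + 1] and sig[i + 2]:
                    expect = gf.levels_nC[i]
                    break
            assert detect_threshold(gf) == expect

    def test_too_few_levels_rejected(self):
        with pytest.raises(IncompleteProtocolError):
            detect_threshold(make_gf([10.0, 10.0]))

    def test_significance_uses_spont_sd(self):
        gf = make_gf([4.5] * 5, spont_mean=1.0, spont_sd=1.0)
        assert significance_pattern(gf).all()
        gf2 = make_gf([4.5] * 5, spont_mean=1.0, spont_sd=2.0)
        assert not significance_pattern(gf2).any()


class TestExtractParams:
    def test_worked_example(self):
        # spont SD 2 -> criterion 6 Hz -> significance pattern F F T T T
        gf = make_gf([0, 5, 30, 50, 50], levels=[3, 4.5, 6, 7.5, 9], spont_sd=2.0)
        qr = extract_params(gf)
        assert qr.threshold_nC == 6.0  # first of three consecutive significant
        assert qr.max_fr_Hz == 50.0
        assert qr.charge_at_max_nC == 7.5  # lowest charge among tied maxima
        assert qr.dyn_range_nC == pytest.approx(1.5)
        assert qr.dyn_range80_nC == pytest.approx(1.5)  # first level >= 40 is 7.5
        assert qr.significant

    def test_flat_zero_function(self):
        qr = extract_params(make_gf([0.0] * 6))
        assert qr.max_fr_Hz == 0.0
        assert not qr.significant
        assert np.isnan(qr.threshold_nC)
        assert np.isnan(qr.dyn_range_nC) and np.isnan(qr.dyn_range80_nC)

    def test_monotone_function_dynrange80_precedes_max(self):
        gf = make_gf(np.linspace(0, 50, 20), spont_sd=0.5)
        qr = extract_params(gf)
        assert qr.dyn_range80_nC < qr.dyn_range_nC

    def test_shift_equivariance(self):
        rates = np.array([0, 0, 12, 30, 42, 48, 50, 50.0])
        gf = make_gf(rates, spont_mean=2.0, spont_sd=1.0)
        shifted = make_gf(rates + 7.0, spont_mean=9.0, spont_sd=1.0)
        a, b = extract_params(gf), extract_params(shifted)
        assert a.threshold_nC == b.threshold_nC
        assert a.dyn_range_nC == b.dyn_range_nC
        assert a.dyn_range80_nC == b.dyn_range80_nC
        assert b.max_fr_Hz == pytest.approx(a.max_fr_Hz)

    def test_maxfr_permutation_invariant_argmax_not(self, rng):
        rates = rng.uniform(0, 50, 10)
        rates[3] = rates[7] = 60.0  # tie
        gf = make_gf(rates)
        perm = rng.permutation(10)
        gf_p = make_gf(rates[perm])
        assert extract_params(gf_p).max_fr_Hz == extract_params(gf).max_fr_Hz
        assert extract_params(gf).charge_at_max_nC == gf.levels_nC[3]


class TestQuantifyEvents:
    def test_matches_per_recording_path(self, schedule, sim_events):
        table = quantify_events(sim_events, schedule)
        assert len(table) == 1
        gf = build_growth_function(count_windows(sim_events, schedule), schedule)
        qr = extract_params(gf)
        row = table.iloc[0]
        assert row.max_fr_Hz == pytest.approx(qr.max_fr_Hz)
        assert row.threshold_nC == pytest.approx(qr.threshold_nC)
        assert row.charge_at_max_nC == qr.charge_at_max_nC
        assert row.dyn_range_nC == pytest.approx(qr.dyn_range_nC)
        assert row.dyn_range80_nC == pytest.approx(qr.dyn_range80_nC)
        assert row.max_fr_sem_Hz == pytest.approx(qr.max_fr_sem_Hz)
        assert row.spont_sd_Hz == pytest.approx(qr.spont_sd_Hz)

    def test_empty_table_rejected(self, schedule):
        with pytest.raises(InputFormatError):
            quantify_events(events_df([]).iloc[0:0], schedule)
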