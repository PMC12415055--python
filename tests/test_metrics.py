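"""Windowed amplitudes, SI/DDI, latency/duration rules, z-scores,
repetition dynamics and group selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from culture_mmr import (
    PSTH,
    deviance_detection_index,
    index_time_course,
    make_oddball,
    peak_latency,
    repetition_dynamics,
    response_duration,
    select_best_group,
    ssa_index,
    window_amplitude,
    zscore_by_culture,
)
from culture_mmr.pipeline import Raster


def psth_from(rate, window=(-50.0, 150.0), bin_ms=1.0, n_trials=10, cond="standard"):
    return PSTH(
        rate=np.asarray(rate, dtype=float),
        bin_ms=bin_ms,
        window_ms=window,
        n_trials=n_trials,
        condition=cond,
    )


def flat_psth(value, window=(-50.0, 150.0)):
    n = int(window[1] - window[0])
    return psth_from(np.full(n, value), window)


pos_amp = st.floats(1e-3, 10.0, allow_nan=False)


class TestWindowAmplitude:
    def test_constant_psth_any_window(self):
        p = flat_psth(0.2)
        assert window_amplitude(p, (0, 10)) == pytest.approx(0.2)
        assert window_amplitude(p, (11, 150)) == pytest.approx(0.2)

    def test_late_window_mean_over_139_bins(self):
        # half-open bin-start convention: late = bins 11..149
        rate = np.zeros(200)
        rate[61:71] = 1.0  # bins 11..20 ms (window starts at -50)
        p = psth_from(rate)
        assert window_amplitude(p, (11, 150)) == pytest.approx(10 / 139)

    def test_boundary_bin_10_excluded_from_both_windows(self):
        rate = np.zeros(200)
        rate[60] = 1.0  # the 10 ms bin
        p = psth_from(rate)
        assert window_amplitude(p, (0, 10)) == 0.0
        assert window_amplitude(p, (11, 150)) == 0.0

    def test_all_zero_psth(self):
        assert window_amplitude(flat_psth(0.0), (11, 150)) == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_amplitude(flat_psth(1.0), (300, 400))


class TestIndices:
    @pytest.mark.parametrize(
        "r,r_std,expected",
        [(0.5, 0.5, 0.0), (3.0, 1.0, 0.5), (0.0, 2.0, -1.0)],
    )
    def test_ssa_index_examples(self, r, r_std, expected):
        assert ssa_index(r, r_std) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "r_dev,r_msc,expected",
        [(0.7, 0.7, 0.0), (1.0, 0.0, 1.0), (0.144, 0.0775, 0.30022573363431155)],
    )
    def test_ddi_examples(self, r_dev, r_msc, expected):
        # the 0.144/0.0775 pair reproduces baseline late-phase amplitudes
        assert deviance_detection_index(r_dev, r_msc) == pytest.approx(expected)

    def test_zero_denominator_flagged_undefined(self):
        assert np.isnan(ssa_index(0.0, 0.0))
        assert np.isnan(deviance_detection_index(0.0, 0.0))

    @settings(max_examples=200, derandomize=True)
    @given(a=pos_amp, b=pos_amp)
    def test_antisymmetry(self, a, b):
        assert ssa_index(a, b) == pytest.approx(-ssa_index(b, a))
        assert deviance_detection_index(a, b) == pytest.approx(
            -deviance_detection_index(b, a)
        )

    @settings(max_examples=200, derandomize=True)
    @given(a=pos_amp, b=pos_amp, c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, a, b, c):
        assert ssa_index(c * a, c * b) == pytest.approx(ssa_index(a, b))

    @settings(max_examples=100, derandomize=True)
    @given(a=pos_amp, b=pos_amp)
    def test_bounded_in_unit_interval(self, a, b):
        assert -1.0 <= ssa_index(a, b) <= 1.0


class TestPeakLatency:
    def test_single_elevated_bin(self):
        rate = np.zeros(200)
        rate[50 + 24] = 1.0
        assert peak_latency(psth_from(rate), (11, 150)) == 24.0

    def test_tie_breaks_to_earliest(self):
        rate = np.zeros(200)
        rate[50 + 14] = rate[50 + 30] = 1.0
        assert peak_latency(psth_from(rate), (11, 150)) == 14.0

    def test_flat_nonzero_gives_window_start(self):
        assert peak_latency(flat_psth(0.5), (11, 150)) == 11.0

    def test_all_zero_window_undefined(self):
        assert np.isnan(peak_latency(flat_psth(0.0), (11, 150)))


class TestResponseDuration:
    def test_flat_equal_to_baseline_gives_zero(self):
        assert response_duration(flat_psth(0.3)) == 0.0

    def test_zero_baseline_counts_any_positive_bin(self):
        rate = np.zeros(200)
        rate[80:110] = 0.5  # 30 elevated bins
        assert response_duration(psth_from(rate)) == 30.0

    def test_noisy_baseline_threshold_rule(self):
        rng = np.random.default_rng(0)
        rate = np.zeros(200)
        rate[:50] = 1.0 + 0.01 * rng.standard_normal(50)  # baseline sigma ~ 0.01
        rate[50:] = 1.0
        rate[61:111] = 1.0 + 5 * 0.01  # bins 11..60: +5 sigma
        assert response_duration(psth_from(rate)) == 50.0

    def test_contiguous_mode_stops_at_first_gap(self):
        rate = np.zeros(200)
        rate[55:60] = 1.0
        rate[70:80] = 1.0
        assert response_duration(psth_from(rate), mode="total") == 15.0
        assert response_duration(psth_from(rate), mode="contiguous") == 5.0

    def test_monotone_in_super_threshold_bins(self):
        durations = []
        for k in (5, 10, 20, 40):
            rate = np.zeros(200)
            rate[60 : 60 + k] = 1.0
            durations.append(response_duration(psth_from(rate)))
        assert durations == sorted(durations)

    def test_missing_baseline_rejected(self):
        p = psth_from(np.zeros(150), window=(0.0, 150.0))
        with pytest.raises(ValueError):
            response_duration(p)


class TestIndexTimeCourse:
    def test_identical_conditions_give_zero_indices(self):
        p = flat_psth(0.4)
        tc = index_time_course({"standard": p, "deviant": p, "msc": p})
        assert np.allclose(tc["si_dev"], 0)
        assert np.allclose(tc["ddi"], 0)

    def test_deviant_elevation_confined_to_one_bin(self):
        base = flat_psth(0.2)
        rate = np.full(200, 0.2)
        rate[70:80] = 0.6  # 20-30 ms
        dev = psth_from(rate)
        tc = index_time_course({"standard": base, "deviant": dev, "msc": base})
        hot = tc["bin_start_ms"] == 20.0
        assert (tc.loc[hot, "ddi"] > 0).all()
        assert np.allclose(tc.loc[~hot, "ddi"], 0)

    def test_bins_partition_span_without_gaps(self):
        p = flat_psth(0.1)
        tc = index_time_course({"standard": p, "deviant": p, "msc": p})
        assert tc["bin_start_ms"].iloc[0] == 0.0
        assert tc["bin_end_ms"].iloc[-1] == 150.0
        assert np.allclose(
            tc["bin_start_ms"].iloc[1:].to_numpy(), tc["bin_end_ms"].iloc[:-1].to_numpy()
        )


class TestZScore:
    def test_two_values_hand_computed(self):
        df = pd.DataFrame({"culture": ["a", "a"], "value": [1.0, 3.0]})
        z = zscore_by_culture(df)["z"].to_numpy()
        assert np.allclose(z, [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_per_culture_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "culture": np.repeat(["a", "b", "c"], 20),
                "value": rng.normal(size=60) + np.repeat([0, 5, -3], 20),
            }
        )
        out = zscore_by_culture(df)
        for _, g in out.groupby("culture"):
            assert g["z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert g["z"].std(ddof=1) == pytest.approx(1.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=10)
        df1 = pd.DataFrame({"culture": "a", "value": v})
        df2 = pd.DataFrame({"culture": "a", "value": v + 100.0})
        assert np.allclose(
            zscore_by_culture(df1)["z"], zscore_by_culture(df2)["z"]
        )

    def test_zero_spread_rejected_naming_culture(self):
        df = pd.DataFrame({"culture": ["bad", "bad"], "value": [1.0, 1.0]})
        with pytest.raises(ValueError, match="bad"):
            zscore_by_culture(df)


def _raster_with_trial_amps(cond, amps, window=(11.0, 150.0)):
    """Raster with a controlled late-window count per trial (one channel)."""
    rows = []
    for trial, a in enumerate(amps):
        for k in range(int(a)):
            rows.append((cond, trial, 0, 0, 20.0 + 0.1 * k))
    df = pd.DataFrame(rows, columns=["condition", "trial", "col", "row", "t_ms"])
    return Raster(
        spikes=df, n_trials={cond: len(amps)}, window_ms=(-50.0, 150.0),
        channels=[(0, 0)],
    )


class TestRepetitionDynamics:
    def test_first_halves_last_means(self):
        seq = make_oddball(((0, 0), (1, 0)), 40, 0.1, 0.5, seed=0)
        # overwrite roles: use 4 deviant trials with known amplitudes
        raster = _raster_with_trial_amps("deviant", [4, 3, 2, 1])
        seq4 = seq  # only the role column matters for condition discovery
        out = repetition_dynamics(raster, seq4)
        row = out[out.condition == "deviant"].iloc[0]
        scale = 139.0  # counts -> spikes/ms over the late window
        assert row["first"] * scale == pytest.approx(4)
        assert row["first_half"] * scale == pytest.approx(3.5)
        assert row["second_half"] * scale == pytest.approx(1.5)
        assert row["last"] * scale == pytest.approx(1)

    def test_single_trial_condition_flagged(self):
        raster = _raster_with_trial_amps("deviant", [2])
        seq = make_oddball(((0, 0), (1, 0)), 10, 0.1, 0.5, seed=0)
        out = repetition_dynamics(raster, seq)
        row = out[out.condition == "deviant"].iloc[0]
        assert row["flagged"]
        assert row["first"] == row["last"]
        assert np.isnan(row["first_half"])

    def test_constant_amplitudes_equalize_summaries(self):
        raster = _raster_with_trial_amps("deviant", [3, 3, 3, 3])
        seq = make_oddball(((0, 0), (1, 0)), 40, 0.1, 0.5, seed=0)
        row = repetition_dynamics(raster, seq).set_index("condition").loc["deviant"]
        assert row["first"] == row["first_half"] == row["second_half"] == row["last"]

    def test_simulated_standard_adapts_first_half_exceeds_second(
        self, simulated_oddball, oddball_seq
    ):
        _, raster = simulated_oddball
        row = (
            repetition_dynamics(raster, oddball_seq)
            .set_index("condition")
            .loc["standard"]
        )
        assert row["first_half"] > row["second_half"]


class TestBestGroup:
    def test_argmax_selection(self):
        assert select_best_group({"g1": 0.1, "g2": 0.3, "g3": 0.2}) == "g2"

    def test_single_group(self):
        assert select_best_group({"only": 0.5}) == "only"

    def test_tie_breaks_to_lowest_id(self):
        assert select_best_group({"g2": 0.3, "g1": 0.3}) == "g1"

    def test_sequence_values_averaged(self):
        assert select_best_group({"g1": [0.1, 0.2], "g2": [0.4, 0.0]}) == "g2"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_group({})
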