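"""Trace -> MO2 -> SMR/MMR/AS estimators, against hand arithmetic and
brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefphys import respirometry as resp
from reefphys.synthetic import CycleSpec, generate_o2_trace

from conftest import make_mo2_series, replace


def _trace(times, o2, phase="measure"):
    return pd.DataFrame(
        {
            "time_min": times,
            "o2_mg_per_l": o2,
            "temp_c": 27.0,
            "phase": phase,
            "chamber_id": "ch1",
        }
    )


class TestSegmentation:
    def test_labeled_cycles_found_in_order(self, noiseless_config):
        trace = generate_o2_trace(noiseless_config, 1.4, 27.0, seed=0)
        windows = resp.segment_cycles(trace)
        assert len(windows) == int(noiseless_config.duration_h * 6)  # 10-min cycles
        starts = [w["time_min"].iloc[0] for w in windows]
        assert starts == sorted(starts)

    def test_degenerate_window_dropped(self, noiseless_config):
        trace = generate_o2_trace(noiseless_config, 1.4, 27.0, seed=0)
        # mislabel: leave only a single "measure" sample in the second cycle
        mask = (trace["time_min"] >= 10.0) & (trace["time_min"] < 16.0)
        trace.loc[trace.index[mask][1:], "phase"] = "flush"
        windows = resp.segment_cycles(trace)
        assert len(windows) == int(noiseless_config.duration_h * 6) - 1

    def test_schedule_fallback_matches_cycle_arithmetic(self):
        t = np.arange(0, 30, 0.5)
        trace = _trace(t, np.full_like(t, 6.8), phase="unknown")
        windows = resp.segment_cycles(trace, CycleSpec(10.0, 4.0, 6.0))
        starts = [w["time_min"].iloc[0] for w in windows]
        assert starts == [0.0, 10.0, 20.0]
        assert all(w["time_min"].iloc[-1] < s + 4.0 for w, s in zip(windows, starts))

    def test_no_measure_windows_is_an_error(self):
        t = np.arange(0, 10, 0.5)
        with pytest.raises(ValueError):
            resp.segment_cycles(_trace(t, np.full_like(t, 6.8), phase="flush"))


class TestSlopeAndMO2:
    def test_exact_linear_decline(self):
        t = np.arange(0, 6, 1 / 6)
        fit = resp.fit_slope(_trace(t, 6.8 - 0.01 * t))
        assert fit.slope == pytest.approx(-0.01, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_o2_reports_zero_slope_nan_r2(self):
        t = np.arange(0, 6, 1 / 6)
        fit = resp.fit_slope(_trace(t, np.full_like(t, 6.8)))
        assert fit.slope == 0.0 and math.isnan(fit.r2)

    def test_noisy_slope_within_2se_of_closed_form_ols(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 6, 1 / 6)
        y = 6.8 - 0.01 * t + rng.normal(0, 0.005, t.size)
        fit = resp.fit_slope(_trace(t, y))
        # independent closed-form OLS on the same numbers
        sxx = np.sum((t - t.mean()) ** 2)
        slope = np.sum((t - t.mean()) * (y - y.mean())) / sxx
        resid = y - y.mean() - slope * (t - t.mean())
        se = math.sqrt(resid @ resid / (len(t) - 2) / sxx)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert abs(fit.slope - (-0.01)) < 2 * se

    def test_mo2_hand_arithmetic(self):
        assert resp.compute_mo2(0.0, 1.2, 32.4) == 0.0
        # (0.01 * (1.2 - 0.0324) * 60) / 0.0324
        assert resp.compute_mo2(-0.01, 1.2, 32.4) == pytest.approx(21.622, abs=1e-3)
        assert resp.compute_mo2(+0.01, 1.2, 32.4) < 0  # sign convention kept

    def test_fish_filling_chamber_is_an_error(self):
        with pytest.raises(ValueError):
            resp.compute_mo2(-0.01, 0.175, 175.0)


class TestMMR:
    def test_first_cycle_rule(self):
        assert resp.estimate_mmr(make_mo2_series([500, 400, 300])) == 500
        assert resp.estimate_mmr(make_mo2_series([400, 500, 300])) == 400
        assert resp.estimate_mmr(make_mo2_series([400, 500, 300]),
                                 use_max_cycle=True) == 500

    def test_empty_series_error(self):
        with pytest.raises(ValueError):
            resp.estimate_mmr(make_mo2_series([]))


def _quantile_oracle(values, q):
    """Brute-force sort-and-interpolate quantile (h = (n-1)q + 1)."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


class TestSMR:
    def test_constant_series(self):
        series = make_mo2_series([100.0] * 40, np.arange(40) * 10 + 300)
        assert resp.estimate_smr(series) == 100.0

    def test_linear_interpolation_quantile_fixture(self):
        series = make_mo2_series(np.arange(1, 21), np.arange(20) * 10 + 300)
        assert resp.estimate_smr(series) == pytest.approx(4.8)

    def test_short_trial_is_an_error(self):
        series = make_mo2_series([100.0] * 24)  # 4 h of 10-min cycles
        with pytest.raises(ValueError):
            resp.estimate_smr(series)

    def test_boundary_cycle_at_exactly_5h_is_included(self):
        # half-open rule: the cycle starting exactly at 300 min is kept
        times = np.arange(300.0, 410.0, 10.0)
        vals = np.arange(1.0, 12.0)  # quantile of 1..11 differs from 2..11
        series = make_mo2_series(vals, times)
        assert resp.estimate_smr(series, min_cycles=5) == pytest.approx(3.0)
        times_out = times.copy()
        times_out[0] = 299.9  # nudge the first cycle just before the cut
        series_out = make_mo2_series(vals, times_out)
        assert resp.estimate_smr(series_out, min_cycles=5) == pytest.approx(3.8)

    def test_mean_lowest_alternative(self):
        series = make_mo2_series(np.arange(1, 21), np.arange(20) * 10 + 300)
        # lowest 20% of 20 values = {1,2,3,4}; mean 2.5
        assert resp.estimate_smr(series, method="mean_lowest") == pytest.approx(2.5)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(min_value=1.0, max_value=1e3), min_size=10,
                      max_size=120),
        q=st.floats(min_value=0.05, max_value=0.95),
    )
    def test_matches_brute_force_oracle(self, vals, q):
        series = make_mo2_series(vals, np.arange(len(vals)) * 10 + 300)
        got = resp.estimate_smr(series, q=q)
        assert got == pytest.approx(_quantile_oracle(vals, q), rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(min_value=1.0, max_value=1e3), min_size=10,
                      max_size=60),
        extra=st.floats(min_value=0.0, max_value=1e3),
        dq=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_monotonicity(self, vals, extra, dq):
        """Adding a cycle at or above the current maximum never lowers SMR
        (an interpolated quantile *can* drop when a value lands just above
        it, so the safe monotone statement is about the upper tail);
        raising q never lowers SMR."""
        series = make_mo2_series(vals, np.arange(len(vals)) * 10 + 300)
        smr = resp.estimate_smr(series, q=0.2)
        bigger = make_mo2_series(vals + [max(vals) + extra],
                                 np.arange(len(vals) + 1) * 10 + 300)
        assert resp.estimate_smr(bigger, q=0.2) >= smr - 1e-12
        assert resp.estimate_smr(series, q=min(0.2 + dq, 0.95)) >= smr - 1e-12


class TestBackgroundAndScope:
    def test_zero_background_leaves_traits_unchanged(self):
        mmr_c, smr_c, *_ = resp.correct_background(500, 110, 0.0, 0.0, 0.175, 1.4)
        assert (mmr_c, smr_c) == (500, 110)

    def test_post_background_subtracts_from_smr(self):
        # choose a post slope whose mass-specific equivalent is 10 units
        slope = -10 * (1.4 / 1000) / (0.175 * 60)
        _, smr_c, _, bg_post, _ = resp.correct_background(
            500, 110, 0.0, slope, 0.175, 1.4
        )
        assert bg_post == pytest.approx(10.0)
        assert smr_c == pytest.approx(100.0)

    def test_background_correction_reduces_bias(self, noiseless_config):
        """With generative background drift, corrected SMR is closer to the
        generative truth than the uncorrected estimate."""
        cfg = replace(noiseless_config, background_slope_pre=-2e-4,
                      background_slope_post=-4e-4, duration_h=12.0)
        trace = generate_o2_trace(cfg, 1.4, 27.0, seed=0,
                                  smr_true=100.0, mmr_true=500.0)
        t = resp.extract_traits(
            trace, 1.4, 0.175, bg_pre_slope=cfg.background_slope_pre,
            bg_post_slope=cfg.background_slope_post,
        )
        assert abs(t.smr_corrected - 100.0) < abs(t.smr_raw - 100.0)

    def test_aerobic_scope_identity_and_flags(self):
        assert resp.aerobic_scope(500, 100) == 400
        assert resp.aerobic_scope(100, 100) == 0
        with pytest.raises(ValueError):
            resp.aerobic_scope(float("nan"), 100)

    def test_noiseless_cohort_scope_identity(self, noiseless_config):
        from reefphys.synthetic import generate_cohort

        for f in generate_cohort(replace(noiseless_config,
                                         acclimation_temps=(27.0,)), 0):
            t = resp.extract_traits(f.trace, f.mass, f.chamber_volume)
            assert t.aerobic_scope == t.mmr_corrected - t.smr_corrected  # exact
            assert t.aerobic_scope == pytest.approx(f.as_true, rel=1e-9)
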