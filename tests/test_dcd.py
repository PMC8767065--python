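import numpy as np
import pytest

import excitoq as xq
from excitoq.dcd import (
    DCDConfig,
    DegenerateGeometryError,
    PhaseBounds,
    results_frame,
)


def make_two_line_trace(m1, b1, m2, b2, t_end=900.0, dt=5.0):
    """Piecewise-linear trace whose two segments ARE the tangents.

    With m2 > m1 the trace max(line1, line2) has its kink exactly at the
    analytic intersection of the two lines.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    v = np.maximum(b1 + m1 * t, b2 + m2 * t)
    t_star = (b1 - b2) / (m2 - m1)
    return xq.RatioTrace("pl", t, v), t_star


def phases_for(t_star, t_end=900.0):
    return PhaseBounds(
        plateau_window=(10.0, t_star - 10.0), rise_window=(t_star + 10.0, t_end - 10.0)
    )


TWO_LINE_EVENTS = xq.EventSchedule({"glu_on": 0.0, "glu_off": 900.0})


class TestClassification:
    def test_monophasic_trace_is_negative(self, step_trace_factory, simple_events):
        tr = step_trace_factory([(0.0, 1.0), (100.0, 2.0)])
        has, _ = xq.classify_dcd(tr, simple_events)
        assert not has

    def test_synthetic_cohort_matches_ground_truth(self, cortical_small, cortical_results):
        est = results_frame(cortical_results).set_index("cell_id")["has_dcd"]
        truth = cortical_small.truth.set_index("cell_id")["has_dcd"]
        assert (est == truth).mean() >= 0.95

    def test_rise_exactly_at_threshold_is_negative(self, step_trace_factory, simple_events):
        # noiseless: threshold = plateau + 10% of the first-phase amplitude;
        # a secondary step of exactly that size must NOT count (strict rule)
        at_threshold = step_trace_factory([(0.0, 1.0), (100.0, 2.0), (250.0, 2.1)])
        above = step_trace_factory([(0.0, 1.0), (100.0, 2.0), (250.0, 2.3)])
        assert not xq.classify_dcd(at_threshold, simple_events)[0]
        assert xq.classify_dcd(above, simple_events)[0]

    def test_transient_rise_is_negative(self, step_trace_factory, simple_events):
        # rises but returns before washout: not sustained deregulation
        tr = step_trace_factory([(0.0, 1.0), (100.0, 2.0), (220.0, 2.6), (300.0, 2.0)])
        assert not xq.classify_dcd(tr, simple_events)[0]

    def test_short_glu_window_rejected(self, step_trace_factory):
        events = xq.EventSchedule({"glu_on": 100.0, "glu_off": 190.0})
        tr = step_trace_factory([(0.0, 1.0)])
        with pytest.raises(ValueError, match="shorter"):
            xq.classify_dcd(tr, events)


class TestLagEstimation:
    def test_flat_plateau_and_ramp(self):
        # tangent1: y = 1; tangent2: y = 1 + 0.01 (t - 300) -> onset at 300 s
        tr, t_star = make_two_line_trace(0.0, 1.0, 0.01, 1.0 - 3.0)
        assert t_star == pytest.approx(300.0)
        lag, tan1, tan2, clamped = xq.estimate_lag_dcd(
            tr, TWO_LINE_EVENTS, phases_for(t_star)
        )
        assert lag == pytest.approx(300.0, abs=1e-9)
        assert not clamped
        assert tan1.slope == pytest.approx(0.0, abs=1e-12)
        assert tan2.slope == pytest.approx(0.01)

    def test_sloped_tangents_analytic_intersection(self):
        # y1 = 0.5 - 0.0002 t, y2 = 0.01 t - 2.5 -> t* = 3 / 0.0102
        tr, t_star = make_two_line_trace(-0.0002, 0.5, 0.01, -2.5)
        assert t_star == pytest.approx(3.0 / 0.0102)
        lag, *_ = xq.estimate_lag_dcd(tr, TWO_LINE_EVENTS, phases_for(t_star))
        assert lag == pytest.approx(t_star, abs=1e-6)

    def test_randomized_piecewise_linear_oracle(self):
        """Tangent intersection equals the 2x2 linear solve on 200 random traces."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            m1 = rng.uniform(-5e-4, 5e-4)
            m2 = rng.uniform(5e-3, 2e-2)
            b1 = rng.uniform(0.8, 1.5)
            t_star = rng.uniform(200.0, 600.0)
            b2 = b1 + (m1 - m2) * t_star
            tr, t_check = make_two_line_trace(m1, b1, m2, b2)
            assert t_check == pytest.approx(t_star)
            lag, *_ = xq.estimate_lag_dcd(tr, TWO_LINE_EVENTS, phases_for(t_star))
            assert abs(lag - t_star) <= 5.0  # one sample interval

    def test_parallel_tangents_rejected(self):
        t = np.arange(0.0, 901.0, 5.0)
        tr = xq.RatioTrace("p", t, 1.0 + 0.001 * t)
        with pytest.raises(DegenerateGeometryError):
            xq.estimate_lag_dcd(
                tr,
                TWO_LINE_EVENTS,
                PhaseBounds(plateau_window=(10, 300), rise_window=(400, 880)),
            )

    def test_intersection_before_glu_on_is_clamped(self):
        events = xq.EventSchedule({"glu_on": 400.0, "glu_off": 900.0})
        tr, t_star = make_two_line_trace(0.0, 1.0, 0.01, 1.0 - 3.0)  # t* = 300
        lag, _, _, clamped = xq.estimate_lag_dcd(tr, events, phases_for(t_star))
        assert clamped and lag == 0.0

    def test_cohort_median_lag_within_ten_percent(self, cortical_small, cortical_results):
        lags = results_frame(cortical_results)["lag_dcd_s"].dropna()
        assert np.median(lags) == pytest.approx(
            cortical_small.truth["lag_true_s"].dropna().median(), rel=0.10
        )

    def test_error_grows_with_noise(self):
        """Lag-estimate accuracy degrades monotonically with trace noise."""
        errs = []
        for sd in (0.01, 0.15):
            p = xq.SynthCohortParams(n_cells=40, seed=5, noise_sd=sd, p_dcd=1.0)
            cohort = xq.gen_calcium_cohort(p)
            res = results_frame(
                xq.analyze_cohort(cohort.traces, cohort.events)
            ).merge(cohort.truth, on="cell_id")
            both = res[res["has_dcd_x"] & res["has_dcd_y"]]
            errs.append(np.nanmean(np.abs(both["lag_dcd_s"] - both["lag_true_s"])))
        assert errs[0] < errs[1]


class TestRecoveryIndex:
    @pytest.mark.parametrize(
        "end_level,expected", [(1.0, 100.0), (3.0, 0.0), (2.0, 50.0)]
    )
    def test_anchored_formula(self, step_trace_factory, simple_events, end_level, expected):
        # baseline 1 before glu_on, 3 at washout, end_level at the horizon
        tr = step_trace_factory([(0.0, 1.0), (100.0, 3.0), (420.0, end_level)])
        x = xq.recovery_index(tr, simple_events)
        assert x == pytest.approx(expected, abs=1e-9)

    def test_no_elevation_is_undefined(self, step_trace_factory, simple_events):
        tr = step_trace_factory([(0.0, 1.0)])
        assert xq.recovery_index(tr, simple_events) is None

    def test_affine_invariance(self, step_trace_factory, simple_events):
        tr = step_trace_factory([(0.0, 1.0), (100.0, 3.0), (420.0, 1.8)])
        x1 = xq.recovery_index(tr, simple_events)
        tr2 = tr.with_values(4.0 * tr.values - 2.0)
        assert x1 == pytest.approx(xq.recovery_index(tr2, simple_events), rel=1e-12)

    def test_estimates_track_ground_truth(self, cortical_small, cortical_results):
        df = results_frame(cortical_results).merge(cortical_small.truth, on="cell_id")
        ok = df[df["recovery_defined"]]
        assert np.nanmedian(ok["recovery_index_pct"]) == pytest.approx(
            ok["recovery_true_pct"].iloc[0], abs=5.0
        )


class TestSisterControlNormalization:
    def test_basic_ratio(self):
        out = xq.normalize_to_sister_control([150.0], [100.0, 200.0, 300.0])
        assert out[0] == pytest.approx(0.75)

    def test_control_normalized_by_itself_has_unit_median(self):
        ctrl = np.array([3.0, 9.0, 5.0, 7.0])
        assert np.median(xq.normalize_to_sister_control(ctrl, ctrl)) == 1.0

    def test_zero_median_rejected(self):
        with pytest.raises(ZeroDivisionError):
            xq.normalize_to_sister_control([1.0], [0.0, 0.0, 0.0])

    def test_lps_cohort_normalized_recovery_below_one(self):
        """Slowed-recovery cohort sits below its sister control (direction check)."""
        rec = {}
        for label, f in (("control", 1.0), ("lps", 0.7)):
            p = xq.SynthCohortParams(n_cells=40, seed=19, lps_recovery_factor=f)
            cohort = xq.gen_calcium_cohort(p)
            df = results_frame(xq.analyze_cohort(cohort.traces, cohort.events))
            rec[label] = df["recovery_index_pct"].dropna().to_numpy()
        norm = xq.normalize_to_sister_control(rec["lps"], rec["control"])
        assert np.median(norm) < 1.0


class TestCohortSummary:
    def test_single_cell_median_equals_value(self):
        res = [
            xq.DCDResult("a", True, lag_dcd_s=120.0, recovery_index_pct=80.0)
        ]
        s = xq.summarize_cohort(res)
        assert s["lag_dcd_s"]["median"] == 120.0
        assert s["recovery_index_pct"]["median"] == 80.0

    def test_duplicated_cohort_identical_summary(self, cortical_results):
        a = xq.summarize_cohort(cortical_results)
        b = xq.summarize_cohort(list(cortical_results) + list(cortical_results))
        for key in ("median", "q1", "q3"):
            assert a["lag_dcd_s"][key] == b["lag_dcd_s"][key]
            assert a["recovery_index_pct"][key] == b["recovery_index_pct"][key]
        assert a["dcd_fraction"] == b["dcd_fraction"]

    def test_quantiles_match_independent_computation(self, cortical_results):
        s = xq.summarize_cohort(cortical_results)
        lags = sorted(
            r.lag_dcd_s for r in cortical_results if r.has_dcd and r.lag_dcd_s is not None
        )
        # independent linear-interpolation quantile
        def quantile(sorted_x, q):
            h = (len(sorted_x) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_x) - 1)
            return sorted_x[lo] + (h - lo) * (sorted_x[hi] - sorted_x[lo])

        assert s["lag_dcd_s"]["median"] == pytest.approx(quantile(lags, 0.5))
        assert s["lag_dcd_s"]["q1"] == pytest.approx(quantile(lags, 0.25))
        assert s["lag_dcd_s"]["q3"] == pytest.approx(quantile(lags, 0.75))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            xq.summarize_cohort([])

    def test_exclusion_counts_reported(self, cortical_results):
        s = xq.summarize_cohort(cortical_results)
        assert "n_recovery_undefined" in s and "n_clamped" in s
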