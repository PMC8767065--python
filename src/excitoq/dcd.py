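"""Delayed calcium deregulation (DCD): detection, onset lag, recovery.

During a prolonged excitotoxic glutamate exposure most neurons show a
biphasic cytosolic-Ca²⁺ response: a fast first-phase rise to a plateau,
followed in a subpopulation by a delayed secondary rise (DCD) that predicts
cell death.  This module

* classifies each trace as DCD / no-DCD (:func:`classify_dcd`),
* estimates the onset lag geometrically, as the intersection of two
  least-squares tangents — one to the first-phase plateau, one to the
  steepest segment of the secondary rise (:func:`estimate_lag_dcd`),
* quantifies post-washout recovery as the percentage of the glutamate-evoked
  elevation that has relaxed by a fixed horizon (:func:`recovery_index`),
* normalizes per-cell metrics to a paired sister-culture control cohort
  (:func:`normalize_to_sister_control`).

The recovery index here is an explicit reconstruction:
X = 100 (R_off − R_end) / (R_off − R_base), anchored at the washout level
R_off, the level R_end at a fixed horizon before the FCCP pulse, and the
pre-glutamate baseline R_base; 100% means full return to baseline, 0% no
recovery.  Cells whose washout level does not exceed baseline have no
elevation to recover from and are flagged undefined, never imputed; cohort
summaries always report exclusion counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traces import EventSchedule, RatioTrace, smooth_trace, value_at

__all__ = [
    "DCDConfig",
    "TangentFit",
    "PhaseBounds",
    "DCDResult",
    "DegenerateGeometryError",
    "classify_dcd",
    "fit_tangent",
    "estimate_lag_dcd",
    "recovery_index",
    "normalize_to_sister_control",
    "analyze_cohort",
    "summarize_cohort",
]


class DegenerateGeometryError(ValueError):
    """Tangents too close to parallel for a stable intersection."""


@dataclass(frozen=True)
class DCDConfig:
    """Tunable windows and thresholds of the DCD estimators.

    threshold_k:
        Secondary rise must exceed the plateau by more than ``threshold_k``
        robust (MAD-based) noise sds ...
    min_rise_fraction:
        ... and by at least this fraction of the first-phase amplitude, to
        separate DCD from slow drift.
    settle_margin_s:
        Dead time after glutamate addition before the plateau search starts,
        letting the first phase settle.
    smooth_window_s:
        Moving-average width used for plateau/derivative estimation only;
        tangents are always fit to the raw trace.
    plateau_span_s / rise_window_s:
        Widths of the tangent-fit windows on the plateau and on the
        maximal-slope segment of the secondary rise.
    elevated_fraction:
        Fraction of post-onset samples that must stay above threshold up to
        washout for the rise to count as sustained deregulation.
    min_glu_window_s:
        Shortest admissible glutamate exposure.
    """

    threshold_k: float = 5.0
    min_rise_fraction: float = 0.10
    settle_margin_s: float = 40.0
    smooth_window_s: float = 20.0
    plateau_span_s: float = 90.0
    plateau_backoff_s: float = 10.0
    rise_window_s: float = 60.0
    elevated_fraction: float = 0.90
    min_glu_window_s: float = 120.0
    noise_window_s: float = 60.0
    anchor_halfwidth_s: float = 10.0
    horizon_margin_s: float = 15.0
    parallel_tol: float = 1e-9


@dataclass(frozen=True)
class TangentFit:
    """Least-squares line over a time window of one trace."""

    window: tuple[float, float]
    slope: float
    intercept: float
    rmse: float
    n: int

    def __call__(self, t):
        return self.intercept + self.slope * np.asarray(t)


@dataclass(frozen=True)
class PhaseBounds:
    """Phase boundaries returned by classification, consumed by the lag fit."""

    plateau_window: tuple[float, float]
    rise_window: tuple[float, float]
    plateau_level: float = math.nan
    threshold: float = math.nan
    crossing_time_s: float = math.nan


@dataclass(frozen=True)
class DCDResult:
    """Per-cell DCD endpoints."""

    cell_id: str
    has_dcd: bool
    lag_dcd_s: float | None = None
    recovery_index_pct: float | None = None
    recovery_defined: bool = True
    tangent_first: TangentFit | None = None
    tangent_secondary: TangentFit | None = None
    clamped: bool = False
    normalized_lag: float | None = None
    normalized_recovery: float | None = None


def _baseline(trace: RatioTrace, events: EventSchedule) -> float:
    mask = trace.time < events["glu_on"]
    if not mask.any():
        raise ValueError("trace has no samples before glu_on")
    return float(trace.values[mask].mean())


def classify_dcd(
    trace: RatioTrace, events: EventSchedule, config: DCDConfig = DCDConfig()
) -> tuple[bool, PhaseBounds | None]:
    """Decide whether a trace shows a sustained secondary Ca²⁺ rise.

    After the first-phase plateau (located as the minimum of the smoothed
    signal in the glutamate window, past a settle margin), the cell is
    DCD-positive iff the smoothed signal rises *strictly* above
    plateau + max(threshold_k × robust sd, min_rise_fraction × first-phase
    amplitude) and remains elevated until washout.  A rise exactly at the
    threshold does not count.

    Returns the flag and, for positive cells, the plateau / secondary-rise
    windows used by :func:`estimate_lag_dcd`.
    """
    events.require("glu_on", "glu_off")
    glu_on, glu_off = events["glu_on"], events["glu_off"]
    if glu_off - glu_on < config.min_glu_window_s:
        raise ValueError(
            f"glutamate window {glu_off - glu_on:g} s shorter than the "
            f"minimum {config.min_glu_window_s:g} s"
        )
    if trace.time[0] > glu_on or trace.time[-1] < glu_off:
        raise ValueError("trace does not cover the glutamate window")

    base = _baseline(trace, events)
    sm = smooth_trace(trace, config.smooth_window_s)
    region = (trace.time >= glu_on + config.settle_margin_s) & (trace.time <= glu_off)
    t_r = trace.time[region]
    s_r = sm.values[region]
    i_min = int(np.argmin(s_r))
    plateau_level = float(s_r[i_min])
    t_plateau = float(t_r[i_min])

    # robust noise sd from raw-minus-smoothed residuals near the plateau
    near = (trace.time >= t_plateau - config.noise_window_s) & (
        trace.time <= t_plateau + config.noise_window_s
    )
    resid = trace.values[near] - sm.values[near]
    robust_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))

    amp1 = plateau_level - base
    threshold = plateau_level + max(
        config.threshold_k * robust_sd, config.min_rise_fraction * max(amp1, 0.0)
    )

    after = t_r > t_plateau
    above = s_r > threshold  # strict: a rise exactly at threshold is not DCD
    cand = np.flatnonzero(after & above)
    if cand.size == 0:
        return False, None
    i_cross = int(cand[0])
    # sustained elevation until washout
    tail = above[i_cross:]
    if tail.mean() < config.elevated_fraction or not above[-1]:
        return False, None
    t_cross = float(t_r[i_cross])

    plateau_hi = t_cross - config.plateau_backoff_s
    plateau_lo = max(glu_on + config.settle_margin_s, plateau_hi - config.plateau_span_s)
    dt = float(np.median(np.diff(trace.time)))
    if plateau_hi - plateau_lo < 2 * dt:  # guard: keep >= 3 samples in the fit
        plateau_lo = glu_on + config.settle_margin_s
        plateau_hi = max(plateau_hi, plateau_lo + 2 * dt)
    bounds = PhaseBounds(
        plateau_window=(plateau_lo, plateau_hi),
        rise_window=(t_cross, glu_off),
        plateau_level=plateau_level,
        threshold=threshold,
        crossing_time_s=t_cross,
    )
    return True, bounds


def fit_tangent(trace: RatioTrace, window: tuple[float, float]) -> TangentFit:
    """Least-squares line to the raw trace over ``window`` (inclusive)."""
    t0, t1 = window
    mask = (trace.time >= t0) & (trace.time <= t1)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"tangent window [{t0:g}, {t1:g}] has {n} samples (< 2)")
    t = trace.time[mask]
    v = trace.values[mask]
    slope, intercept = np.polyfit(t, v, 1)
    rmse = float(np.sqrt(np.mean((intercept + slope * t - v) ** 2)))
    return TangentFit((float(t0), float(t1)), float(slope), float(intercept), rmse, n)


def estimate_lag_dcd(
    trace: RatioTrace,
    events: EventSchedule,
    phases: PhaseBounds,
    config: DCDConfig = DCDConfig(),
) -> tuple[float, TangentFit, TangentFit, bool]:
    """Onset lag by tangent intersection.

    Tangent 1 is the least-squares line over the first-phase plateau window;
    tangent 2 the least-squares line over the maximal-slope segment (width
    ``rise_window_s``) of the secondary rise, located on the smoothed
    derivative.  The lag is the intersection time minus ``glu_on``, clamped
    to the glutamate window (a clamp sets the returned warning flag).
    Near-parallel tangents raise :class:`DegenerateGeometryError`.

    Returns ``(lag_s, tangent_first, tangent_secondary, clamped)``.
    """
    events.require("glu_on", "glu_off")
    glu_on, glu_off = events["glu_on"], events["glu_off"]

    tan1 = fit_tangent(trace, phases.plateau_window)

    r0, r1 = phases.rise_window
    sm = smooth_trace(trace, config.smooth_window_s)
    mask = (trace.time >= r0) & (trace.time <= r1)
    if mask.sum() < 3:
        raise ValueError("secondary-rise window has fewer than 3 samples")
    t_rise = trace.time[mask]
    dv = np.gradient(sm.values[mask], t_rise)
    # cap the search at the secondary peak so the falling flank is excluded
    i_peak = int(np.argmax(sm.values[mask]))
    i_max = int(np.argmax(dv[: i_peak + 1])) if i_peak > 0 else int(np.argmax(dv))
    half = config.rise_window_s / 2.0
    w0 = max(r0, t_rise[i_max] - half)
    w1 = min(r1, t_rise[i_max] + half)
    tan2 = fit_tangent(trace, (w0, w1))

    dm = tan2.slope - tan1.slope
    scale = max(abs(tan1.slope), abs(tan2.slope), 1.0)
    if abs(dm) <= config.parallel_tol * scale:
        raise DegenerateGeometryError(
            f"tangent slopes {tan1.slope:g} and {tan2.slope:g} are parallel "
            "within tolerance"
        )
    t_star = (tan1.intercept - tan2.intercept) / dm
    clamped = False
    if t_star < glu_on:
        t_star, clamped = glu_on, True
    elif t_star > glu_off:
        t_star, clamped = glu_off, True
    return float(t_star - glu_on), tan1, tan2, clamped


def recovery_index(
    trace: RatioTrace,
    events: EventSchedule,
    washout_horizon_s: float | None = None,
    config: DCDConfig = DCDConfig(),
) -> float | None:
    """Percent recovery X of the glutamate-evoked elevation after washout.

    X = 100 (R_off − R_end) / (R_off − R_base), with R_base the pre-glutamate
    baseline mean, R_off the level at washout and R_end the level at
    ``glu_off + washout_horizon_s`` (default: just before the FCCP pulse);
    anchors are local means over ±``anchor_halfwidth_s``.  Returns ``None``
    (undefined) when R_off ≤ R_base: there is no elevation to recover from.
    """
    events.require("glu_on", "glu_off")
    glu_off = events["glu_off"]
    if washout_horizon_s is None:
        if "fccp_on" not in events:
            raise ValueError("no horizon given and no fccp_on event to anchor it")
        washout_horizon_s = (
            events["fccp_on"] - glu_off - config.horizon_margin_s
        )
    if "fccp_on" in events and glu_off + washout_horizon_s > events["fccp_on"]:
        raise ValueError("washout horizon reaches past the FCCP pulse")
    if washout_horizon_s <= 0:
        raise ValueError("washout horizon must be positive")
    r_base = _baseline(trace, events)
    r_off = value_at(trace, glu_off, config.anchor_halfwidth_s)
    r_end = value_at(trace, glu_off + washout_horizon_s, config.anchor_halfwidth_s)
    if r_off <= r_base:
        return None
    return 100.0 * (r_off - r_end) / (r_off - r_base)


def normalize_to_sister_control(values, control_values) -> np.ndarray:
    """Express values in units of the paired sister-culture control median.

    The control median maps to 1 exactly, so a normalized median < 1 reads
    directly as "smaller than control".
    """
    control = np.asarray(control_values, dtype=float)
    control = control[np.isfinite(control)]
    if control.size == 0:
        raise ValueError("control cohort is empty")
    med = float(np.median(control))
    if med == 0.0:
        raise ZeroDivisionError("control median is zero; cannot normalize")
    return np.asarray(values, dtype=float) / med


def analyze_cohort(
    traces,
    events: EventSchedule,
    config: DCDConfig = DCDConfig(),
    washout_horizon_s: float | None = None,
) -> list[DCDResult]:
    """Run classification, lag estimation and recovery on every trace."""
    results = []
    for tr in traces:
        has, bounds = classify_dcd(tr, events, config)
        lag = tan1 = tan2 = None
        clamped = False
        if has:
            lag, tan1, tan2, clamped = estimate_lag_dcd(tr, events, bounds, config)
        rec = recovery_index(tr, events, washout_horizon_s, config)
        results.append(
            DCDResult(
                cell_id=tr.cell_id,
                has_dcd=has,
                lag_dcd_s=lag,
                recovery_index_pct=rec,
                recovery_defined=rec is not None,
                tangent_first=tan1,
                tangent_secondary=tan2,
                clamped=clamped,
            )
        )
    return results


def results_frame(results: list[DCDResult]) -> pd.DataFrame:
    """Per-cell results as a tidy DataFrame (one row per cell)."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in results],
            "has_dcd": [r.has_dcd for r in results],
            "lag_dcd_s": [r.lag_dcd_s if r.lag_dcd_s is not None else np.nan for r in results],
            "recovery_index_pct": [
                r.recovery_index_pct if r.recovery_index_pct is not None else np.nan
                for r in results
            ],
            "recovery_defined": [r.recovery_defined for r in results],
            "clamped": [r.clamped for r in results],
        }
    )


def summarize_cohort(results: list[DCDResult]) -> dict:
    """Cohort summary: n, DCD fraction, median (Q1–Q3) of lag and recovery.

    Medians and quartiles (linear-interpolation convention) are computed on
    defined values only; the counts of excluded cells are always reported.
    """
    if not results:
        raise ValueError("empty cohort")
    df = results_frame(results)
    lags = df.loc[df["has_dcd"], "lag_dcd_s"].dropna().to_numpy()
    recs = df.loc[df["recovery_defined"], "recovery_index_pct"].dropna().to_numpy()

    def _mq(x):
        if x.size == 0:
            return {"n": 0, "median": None, "q1": None, "q3": None}
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"n": int(x.size), "median": float(med), "q1": float(q1), "q3": float(q3)}

    return {
        "n_cells": int(len(df)),
        "n_dcd": int(df["has_dcd"].sum()),
        "dcd_fraction": float(df["has_dcd"].mean()),
        "lag_dcd_s": _mq(lags),
        "recovery_index_pct": _mq(recs),
        "n_recovery_undefined": int((~df["recovery_defined"]).sum()),
        "n_clamped": int(df["clamped"].sum()),
    }
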