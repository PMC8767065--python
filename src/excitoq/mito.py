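"""Mitochondrial-potential (Rh123 F/F0) recovery metrics.

Rhodamine 123 reports mitochondrial depolarization as a fluorescence rise
(dequenching).  Two per-cell endpoints quantify how well the potential
recovers after glutamate washout:

* the least-squares slope of F/F0 over the washout window — negative slope
  means recovery (fluorescence falling back toward 1);
* the ratio AUC_FCCP / AUC_post-glutamate of above-baseline areas under the
  curve: a cell that repolarized before the protonophore pulse shows a large
  FCCP transient and a small residual post-glutamate area, so a larger ratio
  means better recovery.

The module reports both metrics and leaves interpretation (recovery vs probe
redistribution) to the user.  The AUC baseline defaults to F/F0 = 1, the
pre-stimulus normalization level, and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import EventSchedule, RatioTrace
from .dcd import fit_tangent

__all__ = [
    "MitoRecoveryResult",
    "rh123_recovery_slope",
    "signal_auc",
    "auc_ratio",
    "analyze_mito_trace",
]


@dataclass(frozen=True)
class MitoRecoveryResult:
    cell_id: str
    slope_per_s: float
    slope_rmse: float
    auc_postglu: float
    auc_fccp: float
    auc_ratio: float | None  # None when the post-glutamate AUC is 0


def rh123_recovery_slope(
    trace: RatioTrace, washout_window: tuple[float, float]
) -> tuple[float, float]:
    """Slope (F/F0 per second) of the Rh123 decline after washout.

    Least squares over ``washout_window``; by the sign convention a negative
    slope is recovery.  Requires at least 3 samples in the window.
    """
    if trace.kind != "f_over_f0":
        raise ValueError("recovery slope is defined on F/F0 traces")
    t0, t1 = washout_window
    n = int(((trace.time >= t0) & (trace.time <= t1)).sum())
    if n < 3:
        raise ValueError(f"washout window [{t0:g}, {t1:g}] has {n} samples (< 3)")
    fit = fit_tangent(trace, washout_window)
    return fit.slope, fit.rmse


def signal_auc(
    trace: RatioTrace, window: tuple[float, float], baseline_level: float = 1.0
) -> float:
    """Trapezoidal area of max(signal − baseline, 0) over ``window``.

    Window endpoints are included by linear interpolation so the integral is
    exact for piecewise-linear signals sampled on the grid.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window [{t0:g}, {t1:g}]")
    if t0 < trace.time[0] or t1 > trace.time[-1]:
        raise ValueError("window outside trace span")
    inside = (trace.time > t0) & (trace.time < t1)
    t = np.concatenate([[t0], trace.time[inside], [t1]])
    v = np.interp(t, trace.time, trace.values)
    excess = np.clip(v - baseline_level, 0.0, None)
    return float(np.trapezoid(excess, t))


def auc_ratio(
    trace: RatioTrace,
    postglu_window: tuple[float, float],
    fccp_window: tuple[float, float],
    baseline_level: float = 1.0,
) -> tuple[float, float, float | None]:
    """(AUC_postglu, AUC_FCCP, AUC_FCCP / AUC_postglu).

    The windows must be disjoint with the post-glutamate window first.  The
    ratio is undefined (``None``) when the post-glutamate area is zero.
    """
    if postglu_window[1] > fccp_window[0]:
        raise ValueError("windows must be disjoint and ordered post-glutamate < FCCP")
    a_post = signal_auc(trace, postglu_window, baseline_level)
    a_fccp = signal_auc(trace, fccp_window, baseline_level)
    ratio = a_fccp / a_post if a_post > 0 else None
    return a_post, a_fccp, ratio


def analyze_mito_trace(
    trace: RatioTrace,
    events: EventSchedule,
    baseline_level: float = 1.0,
    washout_margin_s: float = 15.0,
) -> MitoRecoveryResult:
    """Both recovery endpoints with windows derived from the event schedule.

    Washout / post-glutamate window = [glu_off, fccp_on); FCCP window =
    [fccp_on, iono_on or end of trace).  A small margin keeps the FCCP rise
    out of the slope fit.
    """
    events.require("glu_off", "fccp_on")
    glu_off, fccp_on = events["glu_off"], events["fccp_on"]
    fccp_end = events["iono_on"] if "iono_on" in events else float(trace.time[-1])
    slope, rmse = rh123_recovery_slope(trace, (glu_off, fccp_on - washout_margin_s))
    a_post, a_fccp, ratio = auc_ratio(
        trace, (glu_off, fccp_on - washout_margin_s), (fccp_on, fccp_end), baseline_level
    )
    return MitoRecoveryResult(trace.cell_id, slope, rmse, a_post, a_fccp, ratio)
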