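"""Fluorescence-trace containers, I/O and generic kinetic utilities.

Single-cell fluorescence photometry produces, per cell, a signal sampled on a
common time grid.  Two signal families are handled:

* raw per-channel traces (:class:`FluorescenceTrace`), e.g. the 340 nm and
  380 nm excitation channels of a ratiometric ion indicator such as Fura-2 or
  SBFI;
* dimensionless traces (:class:`RatioTrace`), either a two-excitation ratio
  (F340/F380, proportional to the bound/free indicator fraction) or a
  single-channel signal normalized to its initial value (F/F0, used for
  Rhodamine 123, Fluo-5N or DiBAC probes).

Every window-based computation downstream is anchored on an
:class:`EventSchedule`: the named times at which agents were added or washed
out (e.g. ``glu_on``, ``glu_off``, ``fccp_on``).

Time is stored in seconds internally; loaders accept a units flag.
Missing samples are rejected rather than imputed — all downstream analyses
are window-based and an imputation rule would silently shift anchors.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FluorescenceTrace",
    "RatioTrace",
    "EventSchedule",
    "TraceFormatError",
    "AlignmentError",
    "read_trace_table",
    "write_trace_table",
    "compute_excitation_ratio",
    "normalize_to_initial",
    "smooth_trace",
    "recovery_halftime",
    "value_at",
]


class TraceFormatError(ValueError):
    """Malformed trace table: non-monotone time, duplicates, missing values."""


class AlignmentError(ValueError):
    """Two traces that must share a time grid / cell id do not."""


def _validate_time_values(time: np.ndarray, values: np.ndarray) -> None:
    if time.ndim != 1 or values.ndim != 1:
        raise TraceFormatError("time and values must be 1-D")
    if time.size != values.size:
        raise TraceFormatError(
            f"time ({time.size}) and values ({values.size}) differ in length"
        )
    if time.size < 2:
        raise TraceFormatError("a trace needs at least 2 samples")
    if not np.all(np.isfinite(time)):
        raise TraceFormatError("non-finite time points")
    if np.any(np.diff(time) <= 0):
        raise TraceFormatError("time must be strictly increasing")
    if np.any(~np.isfinite(values)):
        raise TraceFormatError("missing or non-finite values are rejected, not imputed")


@dataclass(frozen=True)
class FluorescenceTrace:
    """Per-cell fluorescence signal vs time for one excitation channel.

    Parameters
    ----------
    cell_id : str
        Cell identifier, unique within a cohort.
    time : ndarray
        Sample times in seconds, strictly increasing.
    values : ndarray
        Fluorescence in arbitrary camera units.
    channel : str
        Excitation/emission label, e.g. ``"f340"`` or ``"f380"``.
    """

    cell_id: str
    time: np.ndarray
    values: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _validate_time_values(self.time, self.values)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class RatioTrace:
    """Dimensionless per-cell signal: an excitation ratio or an F/F0 trace.

    ``kind`` is ``"excitation_ratio"`` for two-channel ratios (F340/F380) and
    ``"f_over_f0"`` for single-channel traces normalized to their initial
    baseline, in which case the baseline-window mean is 1 by construction.
    """

    cell_id: str
    time: np.ndarray
    values: np.ndarray
    kind: str = "excitation_ratio"
    channel: str = ""

    _KINDS = ("excitation_ratio", "f_over_f0")

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        _validate_time_values(self.time, self.values)
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")

    def __len__(self) -> int:
        return self.time.size

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "RatioTrace":
        return dataclasses.replace(
            self, values=np.asarray(values, dtype=float), kind=kind or self.kind
        )


class EventSchedule(Mapping[str, float]):
    """Ordered map of event name -> time (s); times strictly increasing.

    Anchors every window-based computation: e.g. the post-glutamate washout
    window runs from ``glu_off`` to ``fccp_on``.
    """

    def __init__(self, events: Mapping[str, float] | Iterable[tuple[str, float]]):
        items = list(events.items()) if isinstance(events, Mapping) else list(events)
        times = [float(t) for _, t in items]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"event times must be strictly increasing, got {items}")
        self._events: dict[str, float] = {str(k): float(t) for k, t in items}
        if len(self._events) != len(items):
            raise ValueError("duplicate event names")

    def __getitem__(self, key: str) -> float:
        return self._events[key]

    def __iter__(self):
        return iter(self._events)

    def __len__(self) -> int:
        return len(self._events)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={t:g}" for k, t in self._events.items())
        return f"EventSchedule({inner})"

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self._events]
        if missing:
            raise KeyError(f"event schedule is missing {missing}; has {list(self)}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"events": dict(self._events)}, sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EventSchedule":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(doc["events"] if isinstance(doc, dict) and "events" in doc else doc)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TIME_FACTORS = {"s": 1.0, "sec": 1.0, "seconds": 1.0, "min": 60.0, "minutes": 60.0}


def read_trace_table(
    path: str | Path,
    layout: str = "long",
    time_units: str = "s",
    channel: str = "",
) -> list[FluorescenceTrace]:
    """Read a cohort of traces from CSV.

    ``layout="long"`` expects columns ``cell_id, time_s, value`` and optionally
    ``channel``; ``layout="wide"`` expects a first time column followed by one
    column per cell.  ``time_units`` ("s" or "min") is applied on load; time is
    always seconds in memory.
    """
    df = pd.read_csv(path)
    factor = _TIME_FACTORS.get(time_units)
    if factor is None:
        raise ValueError(f"unknown time units {time_units!r}")
    traces: list[FluorescenceTrace] = []
    if layout == "long":
        required = {"cell_id", "time_s", "value"}
        if not required.issubset(df.columns):
            raise TraceFormatError(
                f"long layout needs columns {sorted(required)}, got {list(df.columns)}"
            )
        if "channel" not in df.columns:
            df = df.assign(channel=channel)
        dup = df.duplicated(subset=["cell_id", "time_s", "channel"])
        if dup.any():
            raise TraceFormatError("duplicate (cell_id, time, channel) rows")
        for (cid, chan), grp in df.groupby(["cell_id", "channel"], sort=False):
            grp = grp.sort_values("time_s")
            traces.append(
                FluorescenceTrace(
                    cell_id=str(cid),
                    time=grp["time_s"].to_numpy(float) * factor,
                    values=grp["value"].to_numpy(float),
                    channel=str(chan),
                )
            )
    elif layout == "wide":
        time_col = df.columns[0]
        t = df[time_col].to_numpy(float) * factor
        if pd.Series(t).duplicated().any():
            raise TraceFormatError("duplicated timestamp in wide table")
        for col in df.columns[1:]:
            traces.append(
                FluorescenceTrace(
                    cell_id=str(col),
                    time=t,
                    values=df[col].to_numpy(float),
                    channel=channel,
                )
            )
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    return traces


def write_trace_table(
    traces: Iterable[FluorescenceTrace | RatioTrace], path: str | Path
) -> None:
    """Write traces as a long-format CSV (cell_id, time_s, value, channel)."""
    rows = []
    for tr in traces:
        chan = tr.channel or getattr(tr, "kind", "")
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "time_s": tr.time,
                    "value": tr.values,
                    "channel": chan,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Signal construction
# ---------------------------------------------------------------------------


def compute_excitation_ratio(
    f340: FluorescenceTrace, f380: FluorescenceTrace
) -> RatioTrace:
    """Pointwise two-excitation ratio F340/F380 for one cell.

    Both channels must share the cell id and the exact time grid.  A zero in
    the denominator channel is an error naming the offending sample.
    """
    if f340.cell_id != f380.cell_id:
        raise AlignmentError(
            f"cell ids differ: {f340.cell_id!r} vs {f380.cell_id!r}"
        )
    if f340.time.size != f380.time.size or not np.array_equal(f340.time, f380.time):
        raise AlignmentError("time grids of the two channels do not match")
    zero = np.flatnonzero(f380.values == 0.0)
    if zero.size:
        raise ZeroDivisionError(
            f"denominator channel is zero at sample index {int(zero[0])} "
            f"(t={f380.time[zero[0]]:g} s)"
        )
    return RatioTrace(
        cell_id=f340.cell_id,
        time=f340.time.copy(),
        values=f340.values / f380.values,
        kind="excitation_ratio",
        channel=f"{f340.channel}/{f380.channel}".strip("/"),
    )


def normalize_to_initial(
    trace: FluorescenceTrace | RatioTrace, baseline_window: tuple[float, float]
) -> RatioTrace:
    """Divide a trace by its mean over ``baseline_window`` -> F/F0 trace.

    The window (t0, t1], in seconds, should precede the first stimulus so that
    F0 is the resting fluorescence.
    """
    t0, t1 = baseline_window
    mask = (trace.time >= t0) & (trace.time <= t1)
    if not mask.any():
        raise ValueError(f"baseline window [{t0}, {t1}] contains no samples")
    f0 = float(trace.values[mask].mean())
    if f0 == 0.0:
        raise ZeroDivisionError("baseline mean is zero")
    return RatioTrace(
        cell_id=trace.cell_id,
        time=trace.time.copy(),
        values=trace.values / f0,
        kind="f_over_f0",
        channel=trace.channel,
    )


def smooth_trace(trace, window_width: float):
    """Centered moving average with window ``window_width`` seconds.

    Endpoints use truncated (one-sided) windows so the output has the same
    length as the input; ``window_width=0`` is the identity.  Used to
    pre-condition traces before derivative/tangent estimation.
    """
    if window_width < 0:
        raise ValueError("window width must be >= 0")
    if window_width == 0:
        return trace
    half = window_width / 2.0
    t = trace.time
    v = trace.values
    # cumulative-sum windowed mean on a possibly non-uniform grid
    out = np.empty_like(v)
    left = np.searchsorted(t, t - half, side="left")
    right = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    out = (csum[right] - csum[left]) / (right - left)
    if isinstance(trace, RatioTrace):
        return trace.with_values(out)
    return dataclasses.replace(trace, values=out)


def value_at(trace, t: float, half_width: float = 0.0) -> float:
    """Signal level at time ``t``: local mean over ±half_width, or linear
    interpolation when ``half_width`` is 0."""
    if half_width > 0:
        mask = (trace.time >= t - half_width) & (trace.time <= t + half_width)
        if mask.any():
            return float(trace.values[mask].mean())
    return float(np.interp(t, trace.time, trace.values))


def recovery_halftime(
    trace,
    washout_window: tuple[float, float],
    baseline_level: float,
    start_level: float,
) -> float | None:
    """Time to half-recovery after washout, or ``None`` if never reached.

    Returns the first time within ``washout_window`` at which the signal
    crosses ``(start_level + baseline_level) / 2`` downward, minus the window
    start, with linear interpolation between samples.  Later re-crossings are
    ignored (washout recovery is assumed monotone apart from noise).
    """
    if start_level <= baseline_level:
        raise ValueError("start_level must exceed baseline_level")
    t0, t1 = washout_window
    if t0 < trace.time[0] or t1 > trace.time[-1] or t1 <= t0:
        raise ValueError(
            f"washout window [{t0}, {t1}] outside trace span "
            f"[{trace.time[0]}, {trace.time[-1]}]"
        )
    half = 0.5 * (start_level + baseline_level)
    mask = (trace.time >= t0) & (trace.time <= t1)
    t = trace.time[mask]
    v = trace.values[mask]
    below = v <= half
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(t[0] - t0)
    # interpolate the crossing between samples i-1 and i
    frac = (v[i - 1] - half) / (v[i - 1] - v[i])
    t_cross = t[i - 1] + frac * (t[i] - t[i - 1])
    return float(t_cross - t0)
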