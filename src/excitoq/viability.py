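"""Viability endpoints: live/dead survival index and MTT initial rate.

Two complementary viability readouts:

* morphological — counts of live (Syto-13-positive, EthD-1-negative) and
  dead (EthD-1-positive) cells; survival is the live/dead ratio normalized
  to the same ratio in control cultures;
* biochemical — the MTT assay in its kinetic variant: the initial slope of
  background-corrected absorbance at 550 nm after MTT addition, proportional
  to dehydrogenase activity, normalized to the control wells' slope.

The background wavelength is carried as data (620 or 650 nm are both in
use); it is recorded in the result, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dcd import fit_tangent
from .traces import RatioTrace

__all__ = [
    "ViabilityCounts",
    "MTTKinetics",
    "survival_index",
    "mtt_initial_rate",
]


@dataclass(frozen=True)
class ViabilityCounts:
    """Live/dead cell counts for one condition (or one replicate)."""

    condition: str
    n_live: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.n_live < 0 or self.n_dead < 0:
            raise ValueError("counts must be non-negative")
        if self.n_live + self.n_dead == 0:
            raise ValueError("no cells counted")


@dataclass(frozen=True)
class MTTKinetics:
    """Two-wavelength absorbance kinetics from MTT addition onward."""

    time_min: np.ndarray
    a_signal: np.ndarray  # absorbance at 550 nm
    a_background: np.ndarray
    background_wavelength_nm: float = 650.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        s = np.asarray(self.a_signal, dtype=float)
        b = np.asarray(self.a_background, dtype=float)
        if not (t.size == s.size == b.size):
            raise ValueError("time and absorbance arrays differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "a_signal", s)
        object.__setattr__(self, "a_background", b)


def survival_index(counts: ViabilityCounts, control: ViabilityCounts) -> float | None:
    """(live/dead) normalized to the control (live/dead) ratio.

    Control against itself gives exactly 1.  Returns ``None`` (undefined)
    when either dead count is zero — the ratio does not exist and is
    reported as such, never imputed.
    """
    if counts.n_dead == 0 or control.n_dead == 0:
        return None
    return (counts.n_live / counts.n_dead) / (control.n_live / control.n_dead)


@dataclass(frozen=True)
class MTTRate:
    rate_od_per_min: float
    rmse: float
    normalized: float | None
    window_min: float
    background_wavelength_nm: float


def mtt_initial_rate(
    kinetics: MTTKinetics,
    window_min: float = 10.0,
    control_rate: float | None = None,
) -> MTTRate:
    """Initial formazan-formation rate: LS slope of (A550 − A_bg) vs time.

    Fit over [0, ``window_min``] minutes from MTT addition (needs ≥ 3
    samples).  If ``control_rate`` (OD/min) is given it must be positive and
    the normalized rate is reported alongside.
    """
    t = kinetics.time_min
    corrected = kinetics.a_signal - kinetics.a_background
    mask = (t >= 0) & (t <= window_min)
    if mask.sum() < 3:
        raise ValueError(
            f"initial-rate window 0–{window_min:g} min has {int(mask.sum())} samples (< 3)"
        )
    if control_rate is not None and control_rate <= 0:
        raise ValueError("control rate must be positive")
    tr = RatioTrace("mtt", t[mask] * 60.0, corrected[mask], kind="f_over_f0")
    fit = fit_tangent(tr, (float(tr.time[0]), float(tr.time[-1])))
    rate = fit.slope * 60.0  # per-second slope back to OD/min
    return MTTRate(
        rate_od_per_min=rate,
        rmse=fit.rmse,
        normalized=(rate / control_rate) if control_rate is not None else None,
        window_min=window_min,
        background_wavelength_nm=kinetics.background_wavelength_nm,
    )
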