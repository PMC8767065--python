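"""Synthetic cohorts emulating glutamate-excitotoxicity experiments.

The generators reproduce the *statistical structure* of a live-cell
excitotoxicity study so every downstream estimator can be scored against a
known ground truth:

* a cytosolic-Ca²⁺ imaging cohort in which prolonged glutamate evokes a fast
  first-phase rise in every neuron and, in a random subpopulation, a delayed
  secondary rise (delayed calcium deregulation, DCD) whose onset lag is
  log-normal across cells;
* a paired mitochondrial-potential (Rh123 F/F0) cohort whose depolarization
  is synchronized with each cell's DCD onset;
* single Na⁺ (ratiometric) and DiBAC (plasma-membrane potential) traces whose
  post-washout recovery is slower than the paired Ca²⁺ recovery;
* an extracellular-flux plate (well × measurement-cycle oxygen consumption
  rates with sequential injections and blank wells);
* endpoint tables: live/dead counts, MTT absorbance kinetics at two
  wavelengths, and per-cell contour pixel areas.

Bath lipopolysaccharide (LPS) is modeled as a multiplicative factor ≤ 1 on
the post-washout recovery rate — the minimal kinetic reading of its observed
effect (slower return of Ca²⁺, Na⁺ and ΔΨm toward baseline after washout).

Every generator is driven by a single integer seed and is bit-reproducible.
Each cohort ships a ground-truth table sufficient to score the estimators
without re-deriving it from the traces.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traces import EventSchedule, RatioTrace

__all__ = [
    "SynthCohortParams",
    "SynthPlateParams",
    "EndpointParams",
    "CalciumCohort",
    "MitoCohort",
    "preset",
    "gen_calcium_cohort",
    "gen_mito_cohort",
    "gen_ion_trace",
    "gen_ocr_plate",
    "gen_endpoint_tables",
]

_Z_QUARTILE = 0.6744897501960817  # standard-normal 75% quantile


@dataclass(frozen=True)
class SynthCohortParams:
    """Parameterization of the imaging-cohort generative model.

    The calibration presets (:func:`preset`) set the lag distribution to the
    cohort medians reported for cortical (180 s) and cerebellar (530 s)
    neurons; ``lag_log_sigma`` is derived from the reported interquartile
    ranges of those cohorts.

    Attributes
    ----------
    n_cells:
        Cohort size.
    sampling_interval:
        Imaging frame interval in seconds.
    glu_on, glu_off, fccp_on, iono_on, t_end:
        Event times (s): glutamate addition/washout, protonophore (FCCP)
        pulse, ionomycin saturation, end of recording. Strictly increasing.
    p_dcd:
        Probability that a cell develops DCD during the glutamate window.
    lag_log_median, lag_log_sigma:
        Median (s) and log-space sd of the log-normal DCD onset lag. Lags
        are resampled (truncated) to fit inside the glutamate window with a
        margin so the secondary rise is observable.
    first_phase_amplitude:
        Plateau height of the universal first-phase Ca²⁺ rise (ratio units).
    dcd_amplitude:
        Amplitude of the sigmoidal secondary rise (ratio units).
    dcd_tau:
        Logistic time constant (s) of the secondary rise; steeper rise for
        smaller values. The noiseless tangent-intersection onset of the
        modeled rise equals ``glu_on + lag`` exactly by construction.
    recovery_rate:
        Exponential post-washout recovery rate (1/s) toward baseline.
    lps_recovery_factor:
        Multiplier in (0, 1] on the recovery rate; < 1 models LPS-slowed
        recovery.
    noise_sd:
        Additive Gaussian noise sd in ratio units (default 2% of the
        first-phase amplitude).
    seed:
        RNG seed; identical seeds give bit-identical cohorts.
    """

    n_cells: int = 288
    sampling_interval: float = 5.0
    glu_on: float = 300.0
    glu_off: float = 1200.0
    fccp_on: float = 1800.0
    iono_on: float = 2100.0
    t_end: float = 2400.0
    p_dcd: float = 0.8
    lag_log_median: float = 180.0
    lag_log_sigma: float = 0.85
    first_phase_amplitude: float = 1.0
    dcd_amplitude: float = 2.0
    dcd_tau: float = 20.0
    rise_tau: float = 8.0
    recovery_rate: float = 0.004
    lps_recovery_factor: float = 1.0
    noise_sd: float = 0.02
    baseline: float = 1.0
    lag_margin: float = 120.0
    fccp_ca_amplitude: float = 0.5
    iono_amplitude: float = 4.0
    # Rh123 (mitochondrial-potential) coupling
    mito_amplitude: float = 1.5
    mito_nondcd_amplitude: float = 0.3
    mito_fccp_amplitude: float = 2.0
    # paired-ion traces
    sodium_amplitude: float = 0.8
    sodium_recovery_ratio: float = 0.4
    dibac_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_dcd <= 1.0:
            raise ValueError(f"p_dcd must be in [0, 1], got {self.p_dcd}")
        times = [0.0, self.glu_on, self.glu_off, self.fccp_on, self.iono_on, self.t_end]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"event times must be strictly increasing, got {times[1:]}")
        if self.recovery_rate <= 0:
            raise ValueError("recovery_rate must be > 0")
        if not 0.0 < self.lps_recovery_factor <= 1.0:
            raise ValueError("lps_recovery_factor must be in (0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")

    @property
    def events(self) -> EventSchedule:
        return EventSchedule(
            {
                "glu_on": self.glu_on,
                "glu_off": self.glu_off,
                "fccp_on": self.fccp_on,
                "iono_on": self.iono_on,
            }
        )

    @property
    def effective_recovery_rate(self) -> float:
        return self.recovery_rate * self.lps_recovery_factor

    def time_grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.sampling_interval)) + 1
        return np.arange(n) * self.sampling_interval


def preset(name: str, **overrides) -> SynthCohortParams:
    """Calibrated cohort presets.

    ``"cortical"``: lag median 180 s (IQR 115–360 s in the calibration data),
    n = 288 cells, 15-min glutamate exposure.
    ``"cerebellar"``: lag median 530 s (IQR 290–760 s), n = 298 cells; the
    glutamate window is extended to 40 min so the slow right tail of the lag
    distribution remains observable.
    ``lag_log_sigma`` is ln(Q3/Q1) / (2 z₀.₇₅) for the quoted IQRs.
    """
    presets = {
        "cortical": dict(
            n_cells=288,
            lag_log_median=180.0,
            lag_log_sigma=float(np.log(360.0 / 115.0) / (2 * _Z_QUARTILE)),
        ),
        "cerebellar": dict(
            n_cells=298,
            lag_log_median=530.0,
            lag_log_sigma=float(np.log(760.0 / 290.0) / (2 * _Z_QUARTILE)),
            glu_on=300.0,
            glu_off=2700.0,
            fccp_on=3300.0,
            iono_on=3600.0,
            t_end=3900.0,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return SynthCohortParams(**kwargs)


# ---------------------------------------------------------------------------
# Calcium cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalciumCohort:
    """Generated Ca²⁺ traces + per-cell ground truth + the event schedule."""

    traces: list[RatioTrace]
    truth: pd.DataFrame
    events: EventSchedule
    params: SynthCohortParams

    def trace_map(self) -> dict[str, RatioTrace]:
        return {tr.cell_id: tr for tr in self.traces}


@dataclass(frozen=True)
class MitoCohort:
    """Generated Rh123 F/F0 traces paired cell-by-cell with a Ca²⁺ cohort."""

    traces: list[RatioTrace]
    truth: pd.DataFrame
    events: EventSchedule
    params: SynthCohortParams


def _bump(t: np.ndarray, onset: float, amp: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Normalized rise-then-decay transient starting at ``onset``."""
    dt = np.clip(t - onset, 0.0, None)
    shape = (1.0 - np.exp(-dt / tau_rise)) * np.exp(-dt / tau_decay)
    peak = shape.max()
    out = np.zeros_like(t)
    if peak > 0:
        out = amp * shape / peak
    out[t < onset] = 0.0
    return out


def _draw_lags(rng: np.random.Generator, n: int, p: SynthCohortParams) -> np.ndarray:
    """Log-normal lags truncated to fit inside the glutamate window."""
    mu = np.log(p.lag_log_median)
    lag_max = (p.glu_off - p.glu_on) - p.lag_margin
    if lag_max <= 0:
        raise ValueError("glutamate window too short for any observable DCD lag")
    lags = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.lognormal(mu, p.lag_log_sigma, remaining.size)
        ok = draw < lag_max
        lags[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return lags


def _calcium_clean(t: np.ndarray, p: SynthCohortParams, has_dcd: bool, lag: float) -> np.ndarray:
    """Noiseless Ca²⁺ ratio trace for one cell."""
    b = p.baseline
    m = np.full_like(t, b)
    glu = t >= p.glu_on
    # first phase: fast saturating rise, all cells
    m[glu] += p.first_phase_amplitude * (1.0 - np.exp(-(t[glu] - p.glu_on) / p.rise_tau))
    if has_dcd:
        # sigmoidal secondary rise; the tangent-intersection onset of a
        # logistic (plateau tangent vs max-slope tangent) sits 2 tau before
        # its midpoint, so placing the midpoint at glu_on + lag + 2 tau makes
        # the geometric onset equal glu_on + lag exactly.
        t_mid = p.glu_on + lag + 2.0 * p.dcd_tau
        m[glu] += p.dcd_amplitude / (1.0 + np.exp(-(t[glu] - t_mid) / p.dcd_tau))
    # washout: exponential relaxation of the whole elevation toward baseline
    level_off = float(np.interp(p.glu_off, t, m))
    wash = t >= p.glu_off
    k = p.effective_recovery_rate
    m[wash] = b + (level_off - b) * np.exp(-k * (t[wash] - p.glu_off))
    # FCCP releases mitochondrial Ca²⁺: a transient on top of the relaxation
    m += _bump(t, p.fccp_on, p.fccp_ca_amplitude, 10.0, 60.0)
    # ionomycin: saturation of the indicator
    iono = t >= p.iono_on
    if iono.any():
        level_iono = m[iono][0]
        sat = b + p.iono_amplitude
        m[iono] = sat - (sat - level_iono) * np.exp(-(t[iono] - p.iono_on) / 10.0)
    return m


def gen_calcium_cohort(params: SynthCohortParams) -> CalciumCohort:
    """Generate a ratiometric Ca²⁺ cohort with per-cell ground truth.

    Each trace: baseline plateau → first-phase rise at ``glu_on`` → (DCD
    cells) sigmoidal secondary rise with log-normal onset lag → exponential
    post-washout recovery at ``recovery_rate × lps_recovery_factor`` →
    FCCP transient → ionomycin saturation, plus additive Gaussian noise.

    The truth table carries, per cell: the DCD flag, the true onset lag, the
    trace level at washout and the analytic recovery fraction (%) at the
    pre-FCCP horizon — everything needed to score the estimators.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    t = p.time_grid()
    has_dcd = rng.random(p.n_cells) < p.p_dcd
    lags = _draw_lags(rng, p.n_cells, p)
    lags[~has_dcd] = np.nan

    k = p.effective_recovery_rate
    horizon = p.fccp_on - p.glu_off
    traces: list[RatioTrace] = []
    rows = []
    width = max(3, len(str(p.n_cells - 1)))
    for i in range(p.n_cells):
        cid = f"c{i:0{width}d}"
        clean = _calcium_clean(t, p, bool(has_dcd[i]), float(lags[i]) if has_dcd[i] else 0.0)
        noisy = clean + rng.normal(0.0, p.noise_sd, t.size)
        traces.append(RatioTrace(cid, t, noisy, kind="excitation_ratio", channel="f340/f380"))
        level_off = float(np.interp(p.glu_off, t, clean))
        rows.append(
            {
                "cell_id": cid,
                "has_dcd": bool(has_dcd[i]),
                "lag_true_s": float(lags[i]) if has_dcd[i] else np.nan,
                "level_glu_off": level_off,
                "recovery_rate_eff": k,
                "recovery_true_pct": 100.0 * (1.0 - np.exp(-k * horizon)),
            }
        )
    return CalciumCohort(traces, pd.DataFrame(rows), p.events, p)


# ---------------------------------------------------------------------------
# Coupled Rh123 cohort
# ---------------------------------------------------------------------------


def gen_mito_cohort(calcium_cohort: CalciumCohort, params: SynthCohortParams | None = None) -> MitoCohort:
    """Generate Rh123 F/F0 traces coupled to a Ca²⁺ cohort.

    Mitochondrial depolarization (F/F0 rise, probe dequenching) starts at
    each cell's ground-truth DCD onset and relaxes after washout at the same
    LPS-scaled recovery rate. Cells without DCD show only a small transient
    at glutamate addition that has decayed back to 1 before the FCCP pulse.
    The FCCP transient amplitude scales with the polarization remaining just
    before the pulse, so poorly recovered (still depolarized) cells give a
    small FCCP response.
    """
    p = params or calcium_cohort.params
    if {tr.cell_id for tr in calcium_cohort.traces} != set(calcium_cohort.truth["cell_id"]):
        raise ValueError("calcium cohort traces and ground truth disagree on cell ids")
    rng = np.random.default_rng(p.seed + 1)
    t = p.time_grid()
    k = p.effective_recovery_rate
    traces: list[RatioTrace] = []
    rows = []
    truth = calcium_cohort.truth.set_index("cell_id")
    for tr in calcium_cohort.traces:
        info = truth.loc[tr.cell_id]
        m = np.ones_like(t)
        if bool(info["has_dcd"]):
            t_mid = p.glu_on + float(info["lag_true_s"]) + 2.0 * p.dcd_tau
            glu = t >= p.glu_on
            m[glu] += p.mito_amplitude / (1.0 + np.exp(-(t[glu] - t_mid) / p.dcd_tau))
        else:
            m += _bump(t, p.glu_on, p.mito_nondcd_amplitude, 10.0, 100.0)
        level_off = float(np.interp(p.glu_off, t, m))
        wash = t >= p.glu_off
        m[wash] = 1.0 + (level_off - 1.0) * np.exp(-k * (t[wash] - p.glu_off))
        pre_fccp = float(np.interp(p.fccp_on - p.sampling_interval, t, m))
        polarization_left = float(np.clip(1.0 - (pre_fccp - 1.0) / p.mito_amplitude, 0.0, 1.0))
        fccp_amp = p.mito_fccp_amplitude * polarization_left
        m += _bump(t, p.fccp_on, fccp_amp, 10.0, 80.0)
        noisy = m + rng.normal(0.0, p.noise_sd, t.size)
        traces.append(RatioTrace(tr.cell_id, t, noisy, kind="f_over_f0", channel="rh123"))
        rows.append(
            {
                "cell_id": tr.cell_id,
                "has_dcd": bool(info["has_dcd"]),
                "depol_onset_s": (p.glu_on + float(info["lag_true_s"]))
                if bool(info["has_dcd"])
                else np.nan,
                "mito_level_glu_off": level_off,
                "recovery_slope_true": -(level_off - 1.0) * k,
                "fccp_amp_true": fccp_amp,
            }
        )
    return MitoCohort(traces, pd.DataFrame(rows), p.events, p)


# ---------------------------------------------------------------------------
# Paired ion traces
# ---------------------------------------------------------------------------


def gen_ion_trace(
    kind: str,
    params: SynthCohortParams,
    cell_id: str = "cell",
    glu: bool = True,
    rng: np.random.Generator | None = None,
) -> RatioTrace:
    """Single synthetic ion/potential trace.

    ``kind="sodium"``: ratiometric [Na⁺]ᵢ (SBFI-style F340/F380) rising at
    glutamate addition in every cell, with a post-washout recovery rate equal
    to ``sodium_recovery_ratio`` (< 1) times the Ca²⁺ recovery rate — Na⁺
    extrusion by the Na⁺/K⁺-ATPase lags the Ca²⁺ pumps after washout.
    ``kind="dibac"``: plasma-membrane potential probe; the signal rises on
    depolarization at glutamate addition and recovers like Na⁺.
    ``glu=False`` produces a no-stimulus control: flat baseline plus noise.
    """
    p = params
    if kind not in ("sodium", "dibac"):
        raise ValueError(f"kind must be 'sodium' or 'dibac', got {kind!r}")
    if rng is None:
        rng = np.random.default_rng(p.seed + (2 if kind == "sodium" else 3))
    t = p.time_grid()
    amp = p.sodium_amplitude if kind == "sodium" else p.dibac_amplitude
    m = np.full_like(t, p.baseline)
    if glu:
        on = t >= p.glu_on
        m[on] += amp * (1.0 - np.exp(-(t[on] - p.glu_on) / (3.0 * p.rise_tau)))
        level_off = float(np.interp(p.glu_off, t, m))
        wash = t >= p.glu_off
        k = p.effective_recovery_rate * p.sodium_recovery_ratio
        m[wash] = p.baseline + (level_off - p.baseline) * np.exp(-k * (t[wash] - p.glu_off))
    noisy = m + rng.normal(0.0, p.noise_sd, t.size)
    chan = "f340/f380" if kind == "sodium" else "dibac"
    kind_out = "excitation_ratio" if kind == "sodium" else "f_over_f0"
    return RatioTrace(cell_id, t, noisy, kind=kind_out, channel=chan)


# ---------------------------------------------------------------------------
# Extracellular-flux plate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthPlateParams:
    """Parameterization of the synthetic respirometry plate.

    The default protocol mirrors a 24-well extracellular-flux run: 4 wells
    without cells serve as blanks for instrument drift, basal well OCR is
    uniform on 100–200 pmol O₂/min, and each respirometry cycle is a 3-min
    mix, 2-min wait, 3-min measurement (cycle period 8 min). Injections are
    (agent, first cycle with the agent present): glutamate, then the
    protonophore FCCP (uncoupler, elicits maximal respiration,
    ``fccp_fold`` × basal), then antimycin A + rotenone (respiratory-chain
    block, leaving only non-mitochondrial OCR, ``nocr_fraction`` of the
    pre-injection OCR).
    """

    n_wells: int = 24
    n_blank_wells: int = 4
    n_cycles: int = 16
    basal_ocr_range: tuple[float, float] = (100.0, 200.0)
    injection_ports: tuple[tuple[str, int], ...] = (
        ("glu", 4),
        ("fccp", 8),
        ("antrot", 12),
    )
    cycle_structure: tuple[float, float, float] = (3.0, 2.0, 3.0)
    fccp_fold: float = 2.1
    nocr_fraction: float = 0.2
    acute_glu_fold: float = 1.7
    drift_amplitude: float = 8.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blank_wells < 1:
            raise ValueError("at least one blank well is required")
        if self.n_blank_wells >= self.n_wells:
            raise ValueError("blank wells must leave at least one sample well")
        lo, hi = self.basal_ocr_range
        if lo <= 0 or hi <= lo:
            raise ValueError("basal OCR range must be positive and increasing")
        cycles = [c for _, c in self.injection_ports]
        if any(c >= self.n_cycles or c < 1 for c in cycles):
            raise ValueError(
                f"injection cycles {cycles} must lie in [1, {self.n_cycles - 1}]"
            )
        if any(b <= a for a, b in zip(cycles, cycles[1:])):
            raise ValueError("injection cycles must be strictly increasing")

    def cycle_times(self) -> np.ndarray:
        """Mid-measurement times (min) of each cycle."""
        mix, wait, measure = self.cycle_structure
        period = mix + wait + measure
        return np.arange(self.n_cycles) * period + mix + wait + measure / 2.0


def gen_ocr_plate(params: SynthPlateParams):
    """Synthetic OCR plate + per-well ground-truth metrics.

    Sample wells follow a piecewise-constant segment model: pre-injection
    OCR = NOCR + basal respiration; glutamate segment = NOCR +
    ``acute_glu_fold`` × basal; FCCP segment = NOCR + ``fccp_fold`` × basal;
    antimycin/rotenone segment = NOCR. A slow sinusoidal instrument drift is
    shared by all wells (blanks included), so blank correction removes it
    exactly in the noiseless limit. Returned ground truth satisfies
    maximal = basal + spare capacity identically.
    """
    from .flux import FluxPlate  # local import to avoid a cycle

    p = params
    rng = np.random.default_rng(p.seed)
    times = p.cycle_times()
    agents = {agent: cyc for agent, cyc in p.injection_ports}
    if "fccp" not in agents or "antrot" not in agents:
        raise ValueError("default protocol requires 'fccp' and 'antrot' injections")
    lo, hi = p.basal_ocr_range
    n_sample = p.n_wells - p.n_blank_wells
    pre_total = rng.uniform(lo, hi, n_sample)
    nocr = p.nocr_fraction * pre_total
    basal = pre_total - nocr
    drift = p.drift_amplitude * np.sin(2 * np.pi * times / (times[-1] - times[0] + 1e-12))

    first_inj = min(agents.values())
    segments = sorted(agents.items(), key=lambda kv: kv[1])
    ocr = np.empty((p.n_wells, p.n_cycles))
    well_ids = []
    blank_flags = []
    rows = []
    w = 0
    for b in range(p.n_blank_wells):
        well_ids.append(f"blank{b:02d}")
        blank_flags.append(True)
        ocr[w] = drift + rng.normal(0.0, p.noise_sd, p.n_cycles)
        w += 1
    for i in range(n_sample):
        well_ids.append(f"w{i:02d}")
        blank_flags.append(False)
        level = np.empty(p.n_cycles)
        level[:first_inj] = nocr[i] + basal[i]
        for (agent, start), nxt in zip(
            segments, [c for _, c in segments[1:]] + [p.n_cycles]
        ):
            if agent == "glu":
                level[start:nxt] = nocr[i] + p.acute_glu_fold * basal[i]
            elif agent == "fccp":
                level[start:nxt] = nocr[i] + p.fccp_fold * basal[i]
            elif agent == "antrot":
                level[start:nxt] = nocr[i]
            else:  # unknown agent: no OCR effect
                level[start:nxt] = level[start - 1]
        ocr[w] = level + drift + rng.normal(0.0, p.noise_sd, p.n_cycles)
        w += 1
        maximal = p.fccp_fold * basal[i]
        rows.append(
            {
                "well": f"w{i:02d}",
                "nocr": nocr[i],
                "basal": basal[i],
                "maximal": maximal,
                "src": maximal - basal[i],
                "acute_glu": (p.acute_glu_fold - 1.0) * basal[i],
            }
        )
    plate = FluxPlate(
        wells=well_ids,
        blank=np.array(blank_flags),
        cycle_times_min=times,
        ocr=ocr,
        injections=tuple(p.injection_ports),
    )
    return plate, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Endpoint tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EndpointParams:
    """Parameterization of viability, MTT-kinetics and morphometry tables.

    Live/dead counts are binomial per condition at the stated survival
    probability (defaults chosen so the survival index, live/dead odds
    normalized to control, falls near 1.0 / 0.84 / 0.70 for control / LPS /
    glutamate). MTT formazan absorbance grows linearly over the initial-rate
    window and then saturates; a constant background channel is generated
    alongside. Contour areas are log-normal across cells with a
    multiplicative condition effect on the post-treatment area.
    """

    survival_probs: dict[str, float] = field(
        default_factory=lambda: {"control": 0.75, "lps": 0.716, "glu": 0.677}
    )
    n_cells_counted: int = 600
    n_replicates: int = 5
    mtt_rates: dict[str, float] = field(
        default_factory=lambda: {"control": 0.010, "lps": 0.0085, "glu": 0.0070}
    )
    mtt_a0: float = 0.20
    mtt_background: float = 0.05
    mtt_linear_span_min: float = 12.0
    mtt_saturation_tau_min: float = 25.0
    mtt_duration_min: float = 30.0
    mtt_dt_min: float = 0.5
    mtt_noise_sd: float = 0.0
    area_factors: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "glu": 1.427, "lps_glu": 1.22}
    )
    n_experiments: int = 6
    cells_per_experiment: int = 30
    area_mean_px: float = 200.0
    area_log_sd: float = 0.25
    area_noise_log_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, prob in self.survival_probs.items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"survival probability for {cond!r} outside [0, 1]")
        if any(f <= 0 for f in self.area_factors.values()):
            raise ValueError("area factors must be positive")


def gen_endpoint_tables(params: EndpointParams):
    """Generate (viability counts, MTT kinetics, contour areas) DataFrames.

    * viability: one row per (condition, replicate) with binomial
      ``n_live`` / ``n_dead`` out of ``n_cells_counted / n_replicates``;
    * MTT: long table (condition, time_min, a550, a_bg) with initial slope
      equal to the condition's ``mtt_rates`` entry over the linear span;
    * areas: long table (condition, experiment, cell_id, area_before_px,
      area_after_px) where E[after/before] equals the condition factor.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    via_rows = []
    per_rep = p.n_cells_counted // p.n_replicates
    for cond, prob in p.survival_probs.items():
        for rep in range(p.n_replicates):
            n_live = int(rng.binomial(per_rep, prob))
            via_rows.append(
                {
                    "condition": cond,
                    "replicate": rep,
                    "n_live": n_live,
                    "n_dead": per_rep - n_live,
                }
            )
    viability = pd.DataFrame(via_rows)

    t = np.arange(0.0, p.mtt_duration_min + 1e-9, p.mtt_dt_min)
    mtt_rows = []
    for cond, rate in p.mtt_rates.items():
        lin = t <= p.mtt_linear_span_min
        a = np.empty_like(t)
        a[lin] = p.mtt_a0 + rate * t[lin]
        a_knee = p.mtt_a0 + rate * p.mtt_linear_span_min
        # saturating continuation with matched value and slope at the knee
        a[~lin] = a_knee + rate * p.mtt_saturation_tau_min * (
            1.0 - np.exp(-(t[~lin] - p.mtt_linear_span_min) / p.mtt_saturation_tau_min)
        )
        a = a + rng.normal(0.0, p.mtt_noise_sd, t.size)
        bg = np.full_like(t, p.mtt_background) + rng.normal(0.0, p.mtt_noise_sd, t.size)
        mtt_rows.append(
            pd.DataFrame({"condition": cond, "time_min": t, "a550": a + bg, "a_bg": bg})
        )
    mtt = pd.concat(mtt_rows, ignore_index=True)

    area_rows = []
    for cond, factor in p.area_factors.items():
        for exp in range(p.n_experiments):
            before = p.area_mean_px * rng.lognormal(
                -0.5 * p.area_log_sd**2, p.area_log_sd, p.cells_per_experiment
            )
            # multiplicative noise with unit mean so E[after/before] = factor
            mult = rng.lognormal(
                -0.5 * p.area_noise_log_sd**2,
                p.area_noise_log_sd,
                p.cells_per_experiment,
            )
            after = before * factor * mult
            for j in range(p.cells_per_experiment):
                area_rows.append(
                    {
                        "condition": cond,
                        "experiment": exp,
                        "cell_id": f"{cond}_e{exp}_c{j:02d}",
                        "area_before_px": before[j],
                        "area_after_px": after[j],
                    }
                )
    areas = pd.DataFrame(area_rows)
    return viability, mtt, areas
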