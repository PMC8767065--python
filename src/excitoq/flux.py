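"""Extracellular-flux (oxygen consumption rate) plate metrics.

A respirometry run measures each well's oxygen consumption rate (OCR,
pmol O₂/min) once per mix/wait/measure cycle while agents are injected
sequentially: typically glutamate, then the uncoupler FCCP (maximal
respiration), then antimycin A + rotenone (respiratory-chain block).  Wells
without cells ("blank" wells) track instrument drift and are subtracted
cycle-by-cycle.

Derived metrics per well:

* NOCR — non-mitochondrial OCR: the minimum OCR after antimycin/rotenone;
* basal respiration — mean pre-injection OCR minus NOCR;
* maximal respiration — peak OCR during the FCCP segment minus NOCR;
* spare respiratory capacity (SRC) — maximal minus basal;
* acute response to an agent — the extremum of OCR over the agent's segment
  (whichever direction deviates more) minus the last pre-injection value.

Two normalization conventions are provided and reported explicitly, because
"normalize to basal" can mean dividing by basal respiration (basal → 1,
maximal = 1 + SRC) or by the raw pre-injection OCR (which still contains
NOCR); neither is silently preferred.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FluxPlate",
    "FluxMetrics",
    "blank_correct",
    "compute_flux_metrics",
    "acute_response",
    "normalize_to_basal",
    "read_plate",
    "write_plate",
]


@dataclass(frozen=True)
class FluxPlate:
    """Well × cycle OCR values with the injection schedule.

    ``injections`` is an ordered tuple of (agent, cycle index): the agent is
    present from that measurement cycle onward (until the next injection).
    """

    wells: list[str]
    blank: np.ndarray  # bool per well
    cycle_times_min: np.ndarray
    ocr: np.ndarray  # shape (n_wells, n_cycles)
    injections: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blank", np.asarray(self.blank, dtype=bool))
        object.__setattr__(
            self, "cycle_times_min", np.asarray(self.cycle_times_min, dtype=float)
        )
        object.__setattr__(self, "ocr", np.asarray(self.ocr, dtype=float))
        n_wells, n_cycles = self.ocr.shape
        if len(self.wells) != n_wells or self.blank.size != n_wells:
            raise ValueError("wells / blank flags / OCR rows disagree")
        if self.cycle_times_min.size != n_cycles:
            raise ValueError("cycle times and OCR columns disagree")
        if np.any(np.diff(self.cycle_times_min) <= 0):
            raise ValueError("cycle times must be strictly increasing")
        cycles = [c for _, c in self.injections]
        if any(not 0 < c < n_cycles for c in cycles):
            raise ValueError(f"injection cycles {cycles} outside plate range")
        if any(b <= a for a, b in zip(cycles, cycles[1:])):
            raise ValueError("injection cycles must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return self.ocr.shape[1]

    def segment(self, agent: str) -> tuple[int, int]:
        """Cycle range [start, stop) during which ``agent`` is the latest injection."""
        cycles = dict(self.injections)
        if agent not in cycles:
            raise KeyError(f"agent {agent!r} not among injections {list(cycles)}")
        start = cycles[agent]
        later = [c for _, c in self.injections if c > start]
        stop = min(later) if later else self.n_cycles
        return start, stop


@dataclass(frozen=True)
class FluxMetrics:
    """Per-well respiration metrics; ``maximal = basal + src`` identically."""

    table: pd.DataFrame  # columns: well, nocr, basal, maximal, src, acute_<agent>...
    normalized: bool = False
    normalization_mode: str | None = None


def blank_correct(plate: FluxPlate) -> FluxPlate:
    """Subtract the per-cycle mean of the blank wells; drop the blanks.

    Blank wells carry instrument drift only, so subtracting their cycle mean
    removes any drift shared across the plate.
    """
    if not plate.blank.any():
        raise ValueError("plate has no blank wells")
    blank_mean = plate.ocr[plate.blank].mean(axis=0)
    keep = ~plate.blank
    return dataclasses.replace(
        plate,
        wells=[w for w, k in zip(plate.wells, keep) if k],
        blank=np.zeros(int(keep.sum()), dtype=bool),
        ocr=plate.ocr[keep] - blank_mean,
    )


def _require_agents(plate: FluxPlate, *agents: str) -> None:
    have = {a for a, _ in plate.injections}
    missing = [a for a in agents if a not in have]
    if missing:
        raise ValueError(f"plate is missing required injection(s): {missing}")


def compute_flux_metrics(
    plate: FluxPlate, fccp_agent: str = "fccp", antrot_agent: str = "antrot"
) -> FluxMetrics:
    """Absolute per-well NOCR, basal, maximal and spare respiratory capacity.

    Expects a blank-corrected plate (blank wells, if still present, are
    ignored).  Acute responses for every injected agent are included as
    ``acute_<agent>`` columns.
    """
    _require_agents(plate, fccp_agent, antrot_agent)
    first_inj = min(c for _, c in plate.injections)
    if first_inj < 1:
        raise ValueError("no pre-injection cycles on this plate")
    fccp_seg = plate.segment(fccp_agent)
    antrot_seg = plate.segment(antrot_agent)
    rows = []
    sample = ~plate.blank
    for w, ocr in zip(
        [w for w, s in zip(plate.wells, sample) if s], plate.ocr[sample]
    ):
        nocr = float(ocr[antrot_seg[0] : antrot_seg[1]].min())
        basal = float(ocr[:first_inj].mean()) - nocr
        maximal = float(ocr[fccp_seg[0] : fccp_seg[1]].max()) - nocr
        row = {
            "well": w,
            "nocr": nocr,
            "basal": basal,
            "maximal": maximal,
            "src": maximal - basal,
            "pre_injection_ocr": float(ocr[:first_inj].mean()),
        }
        for agent, _ in plate.injections:
            row[f"acute_{agent}"] = _acute_one(plate, ocr, agent)
        rows.append(row)
    return FluxMetrics(pd.DataFrame(rows))


def _acute_one(plate: FluxPlate, ocr: np.ndarray, agent: str) -> float:
    start, stop = plate.segment(agent)
    seg = ocr[start:stop]
    if seg.size == 0:
        raise ValueError(f"agent {agent!r} has an empty measurement segment")
    ref = float(ocr[start - 1])
    lo, hi = float(seg.min()), float(seg.max())
    # direction of the acute response = the larger absolute deviation
    return hi - ref if abs(hi - ref) >= abs(lo - ref) else lo - ref


def acute_response(plate: FluxPlate, agent: str) -> pd.Series:
    """Per-well acute OCR response to ``agent`` (see module docstring)."""
    _require_agents(plate, agent)
    sample = ~plate.blank
    vals = {
        w: _acute_one(plate, ocr, agent)
        for w, ocr in zip([w for w, s in zip(plate.wells, sample) if s], plate.ocr[sample])
    }
    return pd.Series(vals, name=f"acute_{agent}")


def normalize_to_basal(metrics: FluxMetrics, mode: str = "basal_respiration") -> FluxMetrics:
    """Per-well normalization of all metrics.

    ``mode="basal_respiration"`` divides by basal respiration (NOCR already
    subtracted): basal maps to 1 and maximal − SRC = 1 exactly.
    ``mode="pre_injection_ocr"`` divides by the raw pre-injection OCR, which
    still includes NOCR.
    """
    if metrics.normalized:
        raise ValueError("metrics are already normalized")
    if mode not in ("basal_respiration", "pre_injection_ocr"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    div = (
        metrics.table["basal"]
        if mode == "basal_respiration"
        else metrics.table["pre_injection_ocr"]
    )
    if (div <= 0).any():
        bad = metrics.table.loc[div <= 0, "well"].tolist()
        raise ValueError(f"non-positive normalization divisor in wells {bad}")
    out = metrics.table.copy()
    for col in out.columns:
        if col in ("well", "pre_injection_ocr"):
            continue
        out[col] = out[col] / div
    out["pre_injection_ocr"] = metrics.table["pre_injection_ocr"] / div
    return FluxMetrics(out, normalized=True, normalization_mode=mode)


# ---------------------------------------------------------------------------
# I/O: long CSV (well, cycle, time_min, ocr, blank) + YAML injection schedule
# ---------------------------------------------------------------------------


def write_plate(plate: FluxPlate, csv_path: str | Path, schedule_path: str | Path) -> None:
    rows = []
    for w, is_blank, ocr in zip(plate.wells, plate.blank, plate.ocr):
        for c, (t, v) in enumerate(zip(plate.cycle_times_min, ocr)):
            rows.append(
                {"well": w, "cycle": c, "time_min": t, "ocr": v, "blank": bool(is_blank)}
            )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    Path(schedule_path).write_text(
        yaml.safe_dump(
            {"injections": [{"agent": a, "cycle": int(c)} for a, c in plate.injections]},
            sort_keys=False,
        )
    )


def read_plate(csv_path: str | Path, schedule_path: str | Path) -> FluxPlate:
    df = pd.read_csv(csv_path)
    doc = yaml.safe_load(Path(schedule_path).read_text())
    injections = tuple((d["agent"], int(d["cycle"])) for d in doc["injections"])
    wells = list(dict.fromkeys(df["well"]))
    cycles = np.sort(df["cycle"].unique())
    times = (
        df.drop_duplicates("cycle").set_index("cycle").loc[cycles, "time_min"].to_numpy(float)
    )
    ocr = np.full((len(wells), cycles.size), np.nan)
    blank = np.zeros(len(wells), dtype=bool)
    widx = {w: i for i, w in enumerate(wells)}
    for _, row in df.iterrows():
        ocr[widx[row["well"]], int(row["cycle"])] = row["ocr"]
        blank[widx[row["well"]]] = bool(row["blank"])
    if np.isnan(ocr).any():
        raise ValueError("plate table has missing (well, cycle) OCR values")
    return FluxPlate(wells, blank, times, ocr, injections)
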