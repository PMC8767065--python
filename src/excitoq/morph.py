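"""Soma morphometry: contour-area changes and spherical volume conversion.

Cell area is measured as the number of pixels inside the fluorescence
contour of the soma.  Because fold-changes are scale-free, pixel counts are
used as-is; no micron calibration is needed.  Under the assumption of a
spherical soma, projected area scales as r² and volume as r³, so a
fold-change ``a`` in area corresponds to ``a^(3/2)`` in volume — e.g. a
+42.7% area increase is a 1.70-fold volume increase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "area_change_percent",
    "volume_fold_from_area_fold",
    "area_fold_from_volume_fold",
    "summarize_area_changes",
]


def area_change_percent(before, after):
    """Percent change 100 (after − before) / before; element-wise on arrays."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if np.any(before <= 0):
        raise ValueError("areas before treatment must be positive")
    out = 100.0 * (after - before) / before
    return float(out) if out.ndim == 0 else out


def volume_fold_from_area_fold(area_fold):
    """Spherical-soma conversion: volume fold = area fold^(3/2)."""
    area_fold = np.asarray(area_fold, dtype=float)
    if np.any(area_fold <= 0):
        raise ValueError("area fold must be positive")
    out = area_fold**1.5
    return float(out) if out.ndim == 0 else out


def area_fold_from_volume_fold(volume_fold):
    """Inverse conversion: area fold = volume fold^(2/3)."""
    volume_fold = np.asarray(volume_fold, dtype=float)
    if np.any(volume_fold <= 0):
        raise ValueError("volume fold must be positive")
    out = volume_fold ** (2.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def summarize_area_changes(
    areas: pd.DataFrame, unit: str = "experiment"
) -> pd.DataFrame:
    """Per-condition mean ± SEM of percent area change, plus volume folds.

    ``areas`` is a long table with columns ``condition, experiment,
    area_before_px, area_after_px``.  With ``unit="experiment"`` per-cell
    changes are first averaged within each experiment and the mean/SEM taken
    across experiments (the usual unit of replication); ``unit="cell"`` pools
    all cells.
    """
    if unit not in ("experiment", "cell"):
        raise ValueError("unit must be 'experiment' or 'cell'")
    df = areas.copy()
    df["pct_change"] = area_change_percent(
        df["area_before_px"].to_numpy(), df["area_after_px"].to_numpy()
    )
    if unit == "experiment":
        per = df.groupby(["condition", "experiment"])["pct_change"].mean().reset_index()
        g = per.groupby("condition")["pct_change"]
    else:
        g = df.groupby("condition")["pct_change"]
    out = g.agg(["mean", "sem", "count"]).rename(
        columns={"mean": "mean_pct_change", "sem": "sem_pct_change", "count": "n"}
    )
    out["volume_fold"] = volume_fold_from_area_fold(1.0 + out["mean_pct_change"] / 100.0)
    return out.reset_index()
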