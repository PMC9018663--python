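"""Method-performance statistics for the screening workflow.

Covers matrix effect (ME%), intra-day precision (RSD%), calibration
linearity (ordinary least squares with Pearson r), method limit of detection
(MLOD, from peak-to-peak S/N versus concentration), and screening
false-positive / false-negative rates over the library panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationLevel",
    "CalibrationSeries",
    "ConfusionCounts",
    "matrix_effect_pct",
    "rsd_pct",
    "linear_fit",
    "estimate_mlod",
    "confusion_rates",
]


@dataclass(frozen=True)
class CalibrationLevel:
    concentration: float  # mg/L
    area: float           # counts * s
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass(frozen=True)
class CalibrationSeries:
    """Concentration-response series for one analyte (solvent or matrix)."""

    analyte: str
    levels: tuple[CalibrationLevel, ...]
    context: str = "solvent"

    def __post_init__(self) -> None:
        if self.context not in ("solvent", "matrix"):
            raise ValueError("context must be 'solvent' or 'matrix'")
        levels = tuple(self.levels)
        if len({lv.concentration for lv in levels}) < 2:
            raise ValueError("at least 2 distinct concentrations required")
        object.__setattr__(self, "levels", tuple(sorted(levels, key=lambda lv: lv.concentration)))

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([lv.concentration for lv in self.levels])

    @property
    def areas(self) -> np.ndarray:
        return np.array([lv.area for lv in self.levels])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def matrix_effect_pct(area_matrix: float, area_solvent: float) -> float:
    """ME% = 100 x (matrix area - solvent area) / solvent area.

    Negative values indicate ionization suppression by co-extracted matrix.
    """
    if area_solvent <= 0:
        raise ValueError("solvent area must be positive")
    return 100.0 * (area_matrix - area_solvent) / area_solvent


def rsd_pct(values: Iterable[float]) -> float:
    """Relative standard deviation in percent (sample SD / mean x 100)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("RSD requires at least 2 replicate values")
    mean = float(arr.mean())
    if mean == 0.0:
        raise ValueError("RSD undefined for zero mean")
    return 100.0 * float(arr.std(ddof=1)) / mean


def linear_fit(series: CalibrationSeries) -> tuple[float, float, float]:
    """Ordinary-least-squares calibration line.

    Returns (slope, intercept, r) where r is the Pearson correlation of
    concentration versus response area.
    """
    x = series.concentrations
    y = series.areas
    if x.size < 3:
        raise ValueError("linear fit requires at least 3 levels for a meaningful r")
    if np.unique(x).size < 2:
        raise ValueError("degenerate calibration: all concentrations identical")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def estimate_mlod(
    series: CalibrationSeries,
    snr_target: float = 3.0,
    n_levels: int = 3,
) -> float:
    """Method limit of detection from peak-to-peak S/N versus concentration.

    A line is fitted (OLS) through the lowest ``n_levels`` calibration levels
    carrying a finite S/N, and the MLOD is the concentration at which the
    fitted S/N reaches ``snr_target``, clipped to positive values.
    """
    pts = [(lv.concentration, lv.snr) for lv in series.levels
           if lv.snr is not None and np.isfinite(lv.snr)]
    if len(pts) < 2:
        raise ValueError("MLOD requires at least two levels with finite S/N")
    pts = pts[:max(2, n_levels)]
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    slope, intercept = np.polyfit(x, y, 1)
    # a numerically flat S/N trend is as non-estimable as a negative one
    if slope * (x.max() - x.min()) < 1e-6 * max(1.0, float(np.max(np.abs(y)))):
        raise ValueError("MLOD not estimable: S/N does not increase with concentration")
    mlod = (snr_target - intercept) / slope
    return float(max(mlod, 0.0))


def confusion_rates(
    truth: set[str] | Iterable[str],
    predicted: set[str] | Iterable[str],
    panel: Sequence[str],
) -> tuple[float, float, ConfusionCounts]:
    """Per-panel-compound screening error rates.

    FP% is counted over the non-spiked panel members (fp / (fp + tn)); FN%
    over the spiked members (fn / (fn + tp)).  ``predicted`` must be a
    subset of ``panel``.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty panel")
    truth = set(truth)
    predicted = set(predicted)
    stray = predicted - set(panel)
    if stray:
        raise ValueError(f"predictions outside panel: {sorted(stray)}")
    tp = len(truth & predicted)
    fn = len(truth - predicted)
    fp = len(predicted - truth)
    tn = len(set(panel) - truth - predicted)
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    fp_pct = 100.0 * fp / (fp + tn) if (fp + tn) else 0.0
    fn_pct = 100.0 * fn / (fn + tp) if (fn + tp) else 0.0
    return fp_pct, fn_pct, counts
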