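"""SIR chronogram processing and the hit-confirmation step.

A chronogram is the intensity-versus-time trace of one monitored m/z at the
lowest cone voltage (12 V); without chromatography its "peak" is the ~2 s
desorption event.  Library-matching hits are cross-checked by requiring a
detectable peak (peak-to-peak S/N above a cut, default 3) in the chronogram
at the compound's monitored m/z; confirmation can only remove detections,
never create them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .compounds import CompoundRecord
from .matching import MatchResult

__all__ = ["Chronogram", "PeakMeasure", "integrate_peak", "snr_peak_to_peak", "confirm_hits"]


@dataclass(frozen=True)
class Chronogram:
    """Time-intensity trace for one monitored m/z (nominal 10 Hz sampling)."""

    mz: int
    times: np.ndarray
    intensities: np.ndarray
    cone_voltage: int = 12

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or t.shape != y.shape or t.size < 2:
            raise ValueError("times and intensities must be equal-length vectors (>= 2 points)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class PeakMeasure:
    """Apex/height/area summary of a chronogram peak.

    ``n_points`` counts samples in the contiguous region around the apex with
    intensity >= 5% of the apex height.
    """

    apex_time: float
    height: float
    area: float
    n_points: int


def _peak_region(y: np.ndarray, apex: int, frac: float = 0.05) -> tuple[int, int]:
    """Contiguous index window [lo, hi] around ``apex`` with y >= frac * y[apex]."""
    cut = frac * y[apex]
    lo = apex
    while lo > 0 and y[lo - 1] >= cut:
        lo -= 1
    hi = apex
    while hi < y.size - 1 and y[hi + 1] >= cut:
        hi += 1
    return lo, hi


def integrate_peak(c: Chronogram, region_frac: float = 0.05) -> PeakMeasure:
    """Locate and integrate the chronogram peak.

    The apex is the global maximum (earliest sample on ties); the area is the
    trapezoid integral over the contiguous region above ``region_frac`` of
    the apex height, harmonized with the spectral 5% threshold.
    """
    y = c.intensities
    if float(np.ptp(y)) == 0.0:
        raise ValueError("no peak: flat trace")
    apex = int(np.argmax(y))  # argmax returns the first (earliest) maximum
    lo, hi = _peak_region(y, apex, region_frac)
    area = float(np.trapezoid(y[lo : hi + 1], c.times[lo : hi + 1]))
    return PeakMeasure(
        apex_time=float(c.times[apex]),
        height=float(y[apex]),
        area=area,
        n_points=hi - lo + 1,
    )


def snr_peak_to_peak(c: Chronogram, noise_window: tuple[float, float]) -> float:
    """Peak-to-peak signal-to-noise ratio.

    S/N = (peak height above the median of the noise window) divided by the
    peak-to-peak amplitude (max - min) of the noise window.  The window is a
    time interval that must exclude the peak region; a zero-amplitude window
    yields +inf.
    """
    t0, t1 = noise_window
    mask = (c.times >= t0) & (c.times <= t1)
    if not np.any(mask):
        raise ValueError("noise window contains no samples")
    noise = c.intensities[mask]
    baseline = float(np.median(noise))
    amplitude = float(np.max(noise) - np.min(noise))
    signal = float(np.max(c.intensities)) - baseline
    if amplitude == 0.0:
        return float("inf")
    return signal / amplitude


def default_noise_window(c: Chronogram, fraction: float = 0.25) -> tuple[float, float]:
    """The leading ``fraction`` of the trace, used as baseline when the
    desorption peak sits in the middle of the acquisition."""
    t = c.times
    return float(t[0]), float(t[0] + fraction * (t[-1] - t[0]))


def confirm_hits(
    report: Sequence[MatchResult],
    chronograms: Mapping[int, Chronogram],
    registry: Sequence[CompoundRecord],
    snr_min: float = 3.0,
    noise_window: tuple[float, float] | None = None,
) -> list[MatchResult]:
    """Set ``sir_confirmed`` on every hit in ``report``.

    A hit is confirmed iff the chronogram at the compound's monitored m/z
    has peak-to-peak S/N >= ``snr_min``.  A hit whose trace is missing is
    marked unconfirmed with a warning (not an error); non-hits keep
    ``sir_confirmed=None``.
    """
    by_abbr = {r.abbreviation: r for r in registry}
    out: list[MatchResult] = []
    for result in report:
        if not result.hit:
            out.append(result.with_confirmation(None))
            continue
        record = by_abbr.get(result.compound)
        if record is None:
            raise KeyError(f"hit for unknown compound {result.compound!r}")
        trace = chronograms.get(record.sir_mz)
        if trace is None:
            warnings.warn(
                f"no SIR chronogram at m/z {record.sir_mz} for hit "
                f"{result.compound!r}; marked unconfirmed",
                stacklevel=2,
            )
            out.append(result.with_confirmation(False))
            continue
        window = noise_window or default_noise_window(trace)
        snr = snr_peak_to_peak(trace, window)
        out.append(result.with_confirmation(bool(snr >= snr_min)))
    return out
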