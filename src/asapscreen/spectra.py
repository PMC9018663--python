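"""Spectrum containers and the preprocessing chain.

The same chain is applied to reference acquisitions at library-build time and
to query acquisitions at screening time: restrict to the acquired scan range
(m/z 50-600), bin centroids to nominal (integer) m/z, normalize to relative
intensity (base peak = 100), and discard peaks below the 5% relative
threshold.  No background subtraction is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "Spectrum",
    "MultiChannelSpectrum",
    "PreprocessParams",
    "CONE_VOLTAGES",
    "normalize_relative",
    "apply_threshold",
    "bin_nominal",
    "restrict_range",
    "preprocess",
    "read_scan_table",
    "write_scan_table",
]

#: The four in-source fragmentation channels acquired in one run.
CONE_VOLTAGES: tuple[int, ...] = (12, 20, 30, 40)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mz) and np.isfinite(self.intensity)):
            raise ValueError("peak m/z and intensity must be finite")
        if self.mz < 0 or self.intensity < 0:
            raise ValueError("peak m/z and intensity must be non-negative")


@dataclass(frozen=True)
class Spectrum:
    """A centroided peak list with acquisition metadata.

    ``mz`` and ``intensities`` are parallel arrays sorted by m/z.
    """

    mz: np.ndarray
    intensities: np.ndarray
    cone_voltage: int | None = None
    scan_range: tuple[float, float] = (50.0, 600.0)
    mode: str = "full_scan"
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if mz.ndim != 1 or inten.ndim != 1 or mz.shape != inten.shape:
            raise ValueError("mz and intensities must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(mz)) and np.all(np.isfinite(inten))):
            raise ValueError("spectrum values must be finite")
        if np.any(mz < 0) or np.any(inten < 0):
            raise ValueError("spectrum values must be non-negative")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensities", inten[order])
        if self.mode not in ("full_scan", "sir"):
            raise ValueError(f"unknown spectrum mode: {self.mode!r}")

    def __len__(self) -> int:
        return self.mz.size

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensities)]

    @property
    def base_peak_mz(self) -> float:
        if len(self) == 0:
            raise ValueError("empty spectrum has no base peak")
        return float(self.mz[int(np.argmax(self.intensities))])

    def with_peaks(self, mz: np.ndarray, intensities: np.ndarray) -> "Spectrum":
        return replace(self, mz=np.asarray(mz, float), intensities=np.asarray(intensities, float))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]], **kwargs) -> "Spectrum":
        pairs = list(pairs)
        mz = np.array([p[0] for p in pairs], dtype=float)
        inten = np.array([p[1] for p in pairs], dtype=float)
        return cls(mz=mz, intensities=inten, **kwargs)


class MultiChannelSpectrum:
    """Ordered map cone voltage -> :class:`Spectrum` for the four channels."""

    def __init__(self, channels: Mapping[int, Spectrum], voltages: Iterable[int] = CONE_VOLTAGES):
        voltages = tuple(sorted(voltages))
        missing = [v for v in voltages if v not in channels]
        if missing:
            raise ValueError(f"missing channel {missing[0]} V")
        extra = sorted(set(channels) - set(voltages))
        if extra:
            raise ValueError(f"unexpected channel {extra[0]} V")
        self.voltages = voltages
        self.channels: dict[int, Spectrum] = {v: channels[v] for v in voltages}

    def __getitem__(self, voltage: int) -> Spectrum:
        return self.channels[voltage]

    def __iter__(self) -> Iterator[int]:
        return iter(self.voltages)

    def items(self):
        return self.channels.items()

    def map(self, fn) -> "MultiChannelSpectrum":
        return MultiChannelSpectrum({v: fn(s) for v, s in self.items()}, self.voltages)


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the shared preprocessing chain.

    threshold_pct
        Relative-intensity cut in percent; peaks at exactly the threshold are
        kept (the 5% rule is read inclusively).
    """

    mz_low: float = 50.0
    mz_high: float = 600.0
    threshold_pct: float = 5.0

    def __post_init__(self) -> None:
        if not self.mz_low < self.mz_high:
            raise ValueError("mz_low must be below mz_high")
        if not (0.0 < self.threshold_pct <= 100.0):
            raise ValueError("threshold_pct must be in (0, 100]")


def normalize_relative(s: Spectrum) -> Spectrum:
    """Scale intensities so the base peak is 100 (ratios preserved)."""
    if len(s) == 0:
        raise ValueError("cannot normalize an empty spectrum")
    top = float(np.max(s.intensities))
    if top <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return s.with_peaks(s.mz, s.intensities * (100.0 / top))


def apply_threshold(s: Spectrum, threshold_pct: float = 5.0) -> Spectrum:
    """Keep peaks with relative intensity >= ``threshold_pct`` (inclusive)."""
    if not (0.0 < threshold_pct <= 100.0):
        raise ValueError("threshold_pct must be in (0, 100]")
    keep = s.intensities >= threshold_pct
    return s.with_peaks(s.mz[keep], s.intensities[keep])


def bin_nominal(s: Spectrum) -> Spectrum:
    """Round m/z to nearest integer (round-half-to-even) and sum intensities
    falling in the same integer bin."""
    if len(s) == 0:
        return s
    bins = np.rint(s.mz).astype(int)
    uniq, inverse = np.unique(bins, return_inverse=True)
    summed = np.zeros(uniq.size)
    np.add.at(summed, inverse, s.intensities)
    return s.with_peaks(uniq.astype(float), summed)


def restrict_range(s: Spectrum, low: float = 50.0, high: float = 600.0) -> Spectrum:
    """Keep peaks with low <= m/z <= high (boundaries inclusive)."""
    if not low < high:
        raise ValueError("low must be below high")
    keep = (s.mz >= low) & (s.mz <= high)
    return s.with_peaks(s.mz[keep], s.intensities[keep])


def preprocess(s: Spectrum, params: PreprocessParams | None = None) -> Spectrum:
    """Full chain: restrict_range -> bin_nominal -> normalize_relative ->
    apply_threshold.  Idempotent: re-running on its own output is a no-op."""
    params = params or PreprocessParams()
    out = restrict_range(s, params.mz_low, params.mz_high)
    out = bin_nominal(out)
    out = normalize_relative(out)
    out = apply_threshold(out, params.threshold_pct)
    return out


# ---------------------------------------------------------------------------
# Scan-table CSV interchange
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = ["channel_voltage", "scan_time_s", "mz", "intensity"]


def write_scan_table(acquisition: MultiChannelSpectrum, destination) -> None:
    """Write a full-scan acquisition as a scan-table CSV
    (columns ``channel_voltage,scan_time_s,mz,intensity``)."""
    rows = []
    for v, s in acquisition.items():
        t = float(s.metadata.get("scan_time_s", 0.0)) if s.metadata else 0.0
        for m, i in zip(s.mz, s.intensities):
            rows.append((v, t, float(m), float(i)))
    df = pd.DataFrame(rows, columns=_SCAN_COLUMNS)
    df.to_csv(destination, index=False)


def read_scan_table(source, voltages: Iterable[int] = CONE_VOLTAGES) -> MultiChannelSpectrum:
    """Read a scan-table CSV into a :class:`MultiChannelSpectrum`.

    Rows sharing (channel, m/z) across scan times are summed; centroid m/z
    values are kept as written (binning happens in :func:`preprocess`).
    """
    try:
        df = pd.read_csv(source)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse scan table: {exc}") from exc
    missing = [c for c in _SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scan table missing columns: {', '.join(missing)}")
    channels = {}
    for v, grp in df.groupby("channel_voltage"):
        agg = grp.groupby("mz", as_index=False)["intensity"].sum()
        channels[int(v)] = Spectrum(
            mz=agg["mz"].to_numpy(float),
            intensities=agg["intensity"].to_numpy(float),
            cone_voltage=int(v),
        )
    return MultiChannelSpectrum(channels, voltages)
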