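"""Voltage-resolved reference library built from single-standard acquisitions.

Each library entry stores the four preprocessed (range-restricted, nominally
binned, normalized, 5%-thresholded) channel spectra of one steroid ester.
Relative intensities are quantized to 0.1% steps at build time so that the
MSP serialization (integers on a 0-1000 scale) is lossless: a library
rebuilt from its own MSP file matches any query with identical scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .compounds import CompoundRecord, registry_lookup
from .msp_io import MspEntry, read_msp, write_msp
from .spectra import (
    CONE_VOLTAGES,
    MultiChannelSpectrum,
    PreprocessParams,
    Spectrum,
    apply_threshold,
    bin_nominal,
    normalize_relative,
    restrict_range,
)

__all__ = ["LibraryEntry", "Library", "build_entry", "build_library",
           "library_to_msp", "library_from_msp"]


def _quantize(s: Spectrum) -> Spectrum:
    return s.with_peaks(s.mz, np.round(s.intensities, 1))


@dataclass(frozen=True)
class LibraryEntry:
    """One compound's thresholded four-channel reference spectra."""

    compound: CompoundRecord
    channels: MultiChannelSpectrum

    @property
    def abbreviation(self) -> str:
        return self.compound.abbreviation


@dataclass
class Library:
    """Map abbreviation -> :class:`LibraryEntry`, plus the preprocessing
    parameters used to build it (queries must use the same parameters)."""

    entries: dict[str, LibraryEntry]
    build_params: PreprocessParams = field(default_factory=PreprocessParams)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("library must contain at least one entry")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, abbreviation: str) -> LibraryEntry:
        return self.entries[abbreviation]

    def __iter__(self):
        return iter(self.entries.values())

    @property
    def abbreviations(self) -> list[str]:
        return sorted(self.entries)


def build_entry(
    compound: CompoundRecord,
    acquisition: MultiChannelSpectrum | Sequence[MultiChannelSpectrum],
    params: PreprocessParams | None = None,
) -> LibraryEntry:
    """Preprocess a standard's acquisition into a library entry.

    If several acquisitions of the same standard are supplied, their
    preprocessed channels are averaged peak-wise before thresholding.
    """
    params = params or PreprocessParams()
    acqs = [acquisition] if isinstance(acquisition, MultiChannelSpectrum) else list(acquisition)
    if not acqs:
        raise ValueError("at least one acquisition required")
    channels: dict[int, Spectrum] = {}
    for v in acqs[0].voltages:
        pre_threshold = []
        for acq in acqs:
            s = restrict_range(acq[v], params.mz_low, params.mz_high)
            s = bin_nominal(s)
            s = normalize_relative(s)
            pre_threshold.append(s)
        if len(pre_threshold) == 1:
            merged = pre_threshold[0]
        else:
            all_mz = np.unique(np.concatenate([s.mz for s in pre_threshold]))
            stack = np.zeros((len(pre_threshold), all_mz.size))
            for i, s in enumerate(pre_threshold):
                idx = np.searchsorted(all_mz, s.mz)
                stack[i, idx] = s.intensities
            merged = Spectrum(mz=all_mz, intensities=stack.mean(axis=0), cone_voltage=v)
            merged = normalize_relative(merged)
        merged = apply_threshold(merged, params.threshold_pct)
        channels[v] = _quantize(merged)
    return LibraryEntry(compound=compound, channels=MultiChannelSpectrum(channels, acqs[0].voltages))


def build_library(
    acquisitions: Mapping[str, MultiChannelSpectrum | Sequence[MultiChannelSpectrum]],
    registry: Sequence[CompoundRecord] | None = None,
    params: PreprocessParams | None = None,
) -> Library:
    """Build a library from ``{abbreviation: acquisition(s)}``."""
    params = params or PreprocessParams()
    lookup = registry_lookup(registry)
    if not acquisitions:
        raise ValueError("no acquisitions supplied")
    entries = {}
    for abbr, acq in acquisitions.items():
        if abbr not in lookup:
            raise KeyError(f"unknown compound abbreviation: {abbr!r}")
        entries[abbr] = build_entry(lookup[abbr], acq, params)
    return Library(entries=entries, build_params=params)


def library_to_msp(library: Library, destination=None) -> str:
    """Serialize a library to MSP text (one entry per compound x voltage,
    intensities as integers 0-1000 = relative percent x 10)."""
    msp_entries = []
    for abbr in library.abbreviations:
        entry = library[abbr]
        for v in entry.channels.voltages:
            s = entry.channels[v]
            peaks = tuple(
                (int(round(m)), int(round(i * 10))) for m, i in zip(s.mz, s.intensities)
            )
            msp_entries.append(
                MspEntry(
                    name=f"{abbr}@{v}V",
                    comment_fields={"Compound": abbr, "ConeVoltage": f"{v}V"},
                    peaks=peaks,
                )
            )
    return write_msp(msp_entries, destination)


def library_from_msp(
    source,
    registry: Sequence[CompoundRecord] | None = None,
    params: PreprocessParams | None = None,
    voltages: Iterable[int] = CONE_VOLTAGES,
) -> Library:
    """Rebuild a :class:`Library` from its MSP serialization."""
    params = params or PreprocessParams()
    lookup = registry_lookup(registry)
    entries = read_msp(source)
    by_compound: dict[str, dict[int, Spectrum]] = {}
    for e in entries:
        abbr = e.compound
        if abbr not in lookup:
            raise KeyError(f"unknown compound abbreviation in MSP: {abbr!r}")
        mz = np.array([p[0] for p in e.peaks], dtype=float)
        inten = np.array([p[1] for p in e.peaks], dtype=float) / 10.0
        by_compound.setdefault(abbr, {})[e.cone_voltage] = Spectrum(
            mz=mz, intensities=inten, cone_voltage=e.cone_voltage,
            scan_range=(params.mz_low, params.mz_high),
        )
    lib_entries = {}
    for abbr, channels in by_compound.items():
        lib_entries[abbr] = LibraryEntry(
            compound=lookup[abbr],
            channels=MultiChannelSpectrum(channels, voltages),
        )
    return Library(entries=lib_entries, build_params=params)
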