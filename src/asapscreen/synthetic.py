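"""Seeded generator of synthetic ASAP-MS acquisitions.

Emulates the statistical structure the screening workflow assumes, so every
stage is testable without instrument data:

* voltage-dependent in-source fragmentation: at 12 V the protonated molecule
  is the base peak with only trace fragments; fragment abundance grows
  monotonically through 20/30/40 V (a parametric decay model -- real
  relative abundances are unpublished, so generated spectra are structurally,
  not quantitatively, faithful);
* additive mixture spectra (no chromatographic separation: a sample's
  spectrum is the concentration-weighted sum of its constituents' profiles);
* oil-matrix interference (dense, low-mass-biased, low-intensity ions);
* multiplicative lognormal detector noise and saturation clipping;
* ~2 s Gaussian SIR desorption peaks sampled at 10 Hz, reproducing the
  instrument's ~12 data points per peak.

All randomness flows from integer seeds through ``numpy.random.default_rng``
seed sequences; the same seed always reproduces the same acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .compounds import CompoundRecord, default_registry, registry_lookup
from .library import Library, build_library
from .sir import Chronogram
from .spectra import CONE_VOLTAGES, MultiChannelSpectrum, PreprocessParams, Spectrum

__all__ = [
    "FragmentationProfile",
    "SampleDefinition",
    "SimulationParams",
    "default_profiles",
    "simulate_channel",
    "simulate_acquisition",
    "generate_validation_set",
    "reference_library",
]


@dataclass(frozen=True)
class FragmentationProfile:
    """Per-compound map voltage -> {nominal m/z: relative intensity 0-100}."""

    compound: str
    channels: Mapping[int, Mapping[int, float]]

    def peaks_at(self, voltage: int) -> dict[int, float]:
        return dict(self.channels[voltage])


@dataclass(frozen=True)
class SampleDefinition:
    """What went on the probe: constituents (mg/L, pre-dilution), matrix,
    dilution factor, and the seed that reproduces the acquisition.

    An empty constituent map defines a blank.
    """

    constituents: Mapping[str, float]
    matrix: str = "none"
    dilution_factor: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.constituents.values()):
            raise ValueError("constituent concentrations must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.matrix not in ("none", "oil"):
            raise ValueError("matrix must be 'none' or 'oil'")
        object.__setattr__(self, "constituents", dict(self.constituents))


@dataclass(frozen=True)
class SimulationParams:
    """Generator knobs, with defaults fixed at the study conditions.

    response_per_mgl
        Detector response (counts) per mg/L of analyte after dilution; at
        the standard 100 mg/L spike and 100-fold dilution the base peak sits
        near 1e5 counts, far above noise and below saturation.
    noise_sigma
        Sigma of the multiplicative lognormal intensity noise.
    matrix_n_peaks / matrix_mean_intensity
        Oil interference: number of seeded peaks and the exponential mean of
        their absolute intensities (counts); m/z biased toward 100-300.
    saturation_cap
        Detector ceiling in counts; intensities are clipped here.
    sir_* / baseline_*
        SIR chronogram geometry: Gaussian peak (sigma 0.25 s) centred in a
        4 s trace sampled at 10 Hz over a noisy baseline.
    """

    response_per_mgl: float = 1.0e5
    noise_sigma: float = 0.05
    matrix_n_peaks: int = 80
    matrix_mean_intensity: float = 1000.0
    saturation_cap: float = 1.0e6
    sir_sigma_s: float = 0.25
    sir_rate_hz: float = 10.0
    sir_duration_s: float = 4.0
    sir_apex_time_s: float = 2.0
    baseline_level: float = 200.0
    baseline_sd: float = 50.0
    # fragmentation model: precursor relative intensity and fragment scale
    # per voltage, and the geometric decay across a compound's fragment list
    precursor_intensity: Mapping[int, float] = field(
        default_factory=lambda: {12: 100.0, 20: 100.0, 30: 75.0, 40: 45.0}
    )
    fragment_scale: Mapping[int, float] = field(
        default_factory=lambda: {12: 4.0, 20: 28.0, 30: 60.0, 40: 90.0}
    )
    fragment_decay: float = 0.85


def default_profiles(
    registry: Sequence[CompoundRecord] | None = None,
    params: SimulationParams | None = None,
) -> dict[str, FragmentationProfile]:
    """Build voltage-resolved fragmentation profiles from the registry.

    At 12 V the protonated molecule is the base peak (100) and fragments stay
    below the 5% reporting threshold; fragment intensity rises monotonically
    with voltage, so the number of >= 5% peaks never decreases from 12 to
    40 V.  Family members sharing registry fragments (e.g. the two estradiol
    esters sharing m/z 279/255/159/135/109) therefore produce confusable
    high-voltage spectra, as observed on the instrument.
    """
    registry = registry or default_registry()
    params = params or SimulationParams()
    profiles = {}
    for record in registry:
        channels: dict[int, dict[int, float]] = {}
        for v in CONE_VOLTAGES:
            peaks: dict[int, float] = {record.protonated_mz: params.precursor_intensity[v]}
            scale = params.fragment_scale[v]
            for j, frag in enumerate(record.fragments):
                inten = scale * params.fragment_decay**j
                peaks[frag.nominal_mz] = max(peaks.get(frag.nominal_mz, 0.0), inten)
            top = max(peaks.values())
            channels[v] = {mz: 100.0 * i / top for mz, i in sorted(peaks.items())}
        profiles[record.abbreviation] = FragmentationProfile(record.abbreviation, channels)
    return profiles


def _matrix_ions(rng: np.random.Generator, params: SimulationParams) -> dict[int, float]:
    """Seeded oil-matrix interference: dense low-mass-biased ions."""
    mz = (100.0 + 500.0 * rng.beta(1.2, 3.0, size=params.matrix_n_peaks)).astype(int)
    inten = rng.exponential(params.matrix_mean_intensity, size=params.matrix_n_peaks)
    out: dict[int, float] = {}
    for m, i in zip(mz, inten):
        out[int(m)] = out.get(int(m), 0.0) + float(i)
    return out


def _channel_counts(
    sample: SampleDefinition,
    voltage: int,
    profiles: Mapping[str, FragmentationProfile],
    params: SimulationParams,
) -> dict[int, float]:
    """Noise-free, matrix-free, unsaturated ion counts of one channel."""
    counts: dict[int, float] = {}
    for abbr, conc in sample.constituents.items():
        if abbr not in profiles:
            raise KeyError(f"no fragmentation profile for constituent {abbr!r}")
        response = (conc / sample.dilution_factor) * params.response_per_mgl
        for mz, rel in profiles[abbr].peaks_at(voltage).items():
            counts[mz] = counts.get(mz, 0.0) + response * rel / 100.0
    return counts


def simulate_channel(
    sample: SampleDefinition,
    voltage: int,
    profiles: Mapping[str, FragmentationProfile] | None = None,
    params: SimulationParams | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """One full-scan channel: additive constituent profiles, optional oil
    interference, lognormal noise, saturation clipping."""
    params = params or SimulationParams()
    profiles = profiles if profiles is not None else default_profiles(params=params)
    if rng is None:
        rng = np.random.default_rng([sample.seed, voltage])
    counts = _channel_counts(sample, voltage, profiles, params)
    if sample.matrix == "oil":
        for mz, i in _matrix_ions(rng, params).items():
            counts[mz] = counts.get(mz, 0.0) + i
    mz_arr = np.array(sorted(counts), dtype=float)
    inten = np.array([counts[m] for m in sorted(counts)], dtype=float)
    if params.noise_sigma > 0 and inten.size:
        inten = inten * rng.lognormal(0.0, params.noise_sigma, size=inten.size)
    inten = np.minimum(inten, params.saturation_cap)
    return Spectrum(mz=mz_arr, intensities=inten, cone_voltage=voltage, scan_range=(50.0, 600.0))


def _gaussian_trace(
    apex_height: float,
    rng: np.random.Generator,
    params: SimulationParams,
) -> tuple[np.ndarray, np.ndarray]:
    dt = 1.0 / params.sir_rate_hz
    times = np.arange(0.0, params.sir_duration_s + 0.5 * dt, dt)
    shape = np.exp(-0.5 * ((times - params.sir_apex_time_s) / params.sir_sigma_s) ** 2)
    y = params.baseline_level + apex_height * shape
    if params.baseline_sd > 0:
        y = y + rng.normal(0.0, params.baseline_sd, size=times.size)
    y = np.clip(y, 0.0, params.saturation_cap)
    return times, y


def simulate_acquisition(
    sample: SampleDefinition,
    params: SimulationParams | None = None,
    profiles: Mapping[str, FragmentationProfile] | None = None,
    registry: Sequence[CompoundRecord] | None = None,
) -> tuple[MultiChannelSpectrum, dict[int, Chronogram]]:
    """Full synthetic run: the four full-scan channels plus SIR chronograms
    for all 17 monitored m/z values (12 V).

    Each chronogram's apex is proportional to the sample's noise-free 12 V
    signal at that monitored m/z (a compound that produces no ion there --
    e.g. a blank, or testosterone isocaproate's discrepant monitored m/z --
    yields a baseline-only trace).  Deterministic under ``sample.seed``.
    """
    params = params or SimulationParams()
    registry = registry or default_registry()
    profiles = profiles if profiles is not None else default_profiles(registry, params)
    channels = {
        v: simulate_channel(sample, v, profiles, params) for v in CONE_VOLTAGES
    }
    acq = MultiChannelSpectrum(channels)
    clean12 = _channel_counts(sample, 12, profiles, params)
    chronograms: dict[int, Chronogram] = {}
    for record in registry:
        rng = np.random.default_rng([sample.seed, 12, record.sir_mz])
        apex = min(clean12.get(record.sir_mz, 0.0), params.saturation_cap)
        if params.noise_sigma > 0 and apex > 0:
            # run-to-run desorption/loading variability of the monitored response
            apex *= rng.lognormal(0.0, params.noise_sigma)
        times, y = _gaussian_trace(apex, rng, params)
        chronograms[record.sir_mz] = Chronogram(
            mz=record.sir_mz, times=times, intensities=y, cone_voltage=12
        )
    return acq, chronograms


def reference_library(
    registry: Sequence[CompoundRecord] | None = None,
    params: SimulationParams | None = None,
    preprocess_params: PreprocessParams | None = None,
    concentration: float = 100.0,
) -> Library:
    """The default synthetic library: each standard acquired individually in
    solvent, noise-free, at the standard 100 mg/L level."""
    registry = registry or default_registry()
    params = params or SimulationParams()
    clean = replace(params, noise_sigma=0.0)
    profiles = default_profiles(registry, params)
    acquisitions = {}
    for record in registry:
        sample = SampleDefinition(
            constituents={record.abbreviation: concentration}, matrix="none", seed=0
        )
        acq, _ = simulate_acquisition(sample, clean, profiles, registry)
        acquisitions[record.abbreviation] = acq
    return build_library(acquisitions, registry, preprocess_params)


def generate_validation_set(
    panel: Sequence[str] | None = None,
    n_samples: int = 100,
    mixture_sizes: Sequence[int] = (1, 3),
    concentration_range: tuple[float, float] = (100.0, 100.0),
    matrix: str = "oil",
    seed: int = 0,
    params: SimulationParams | None = None,
    registry: Sequence[CompoundRecord] | None = None,
) -> list[tuple[SampleDefinition, tuple[MultiChannelSpectrum, dict[int, Chronogram]]]]:
    """Reproducible labelled sample set for end-to-end evaluation.

    Each sample draws its mixture size from ``mixture_sizes`` (0 produces a
    blank), its constituents without replacement from ``panel``, and each
    concentration uniformly from ``concentration_range`` (mg/L,
    pre-dilution).  Ground truth is the sample's constituent map.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    registry = registry or default_registry()
    lookup = registry_lookup(registry)
    panel = list(panel) if panel is not None else sorted(lookup)
    unknown = [p for p in panel if p not in lookup]
    if unknown:
        raise KeyError(f"panel compounds not in registry: {unknown}")
    params = params or SimulationParams()
    profiles = default_profiles(registry, params)
    master = np.random.default_rng(seed)
    out = []
    for i in range(n_samples):
        size = int(master.choice(list(mixture_sizes)))
        chosen = list(master.choice(panel, size=size, replace=False)) if size else []
        constituents = {
            abbr: float(master.uniform(*concentration_range)) for abbr in chosen
        }
        sample_seed = int(master.integers(0, 2**31 - 1))
        sample = SampleDefinition(constituents=constituents, matrix=matrix, seed=sample_seed)
        out.append((sample, simulate_acquisition(sample, params, profiles, registry)))
    return out
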