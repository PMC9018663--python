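"""Per-channel spectral similarity, score fusion, and the hit decision rule.

The similarity is an open, documented replacement for the instrument
vendor's proprietary score on the same fixed 0-1000 scale: the cosine
between square-root-transformed intensity vectors over the union of nominal
m/z bins, scaled by 1000 and rounded half-up.  This is the de-facto standard
for unit-resolution library search.

A compound is reported as a hit when three conditions hold jointly:
channel 1 (12 V) score >= 850, each remaining channel >= 825, and the
weighted average of the four channel scores >= 800 (boundary values pass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .library import Library
from .spectra import MultiChannelSpectrum, PreprocessParams, Spectrum, bin_nominal, preprocess

__all__ = [
    "MatchCriteria",
    "MatchResult",
    "channel_score",
    "fuse_scores",
    "apply_criteria",
    "screen",
]


@dataclass(frozen=True)
class MatchCriteria:
    """Conjunctive hit thresholds and channel-fusion weights.

    Defaults are the screening method's optimized criteria: channel 1
    (12 V) >= 850, remaining channels >= 825, average >= 800, equal weights.
    """

    channel1_min: float = 850.0
    other_channels_min: float = 825.0
    average_min: float = 800.0
    weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        for t in (self.channel1_min, self.other_channels_min, self.average_min):
            if not (0.0 <= t <= 1000.0):
                raise ValueError("criteria thresholds must lie in [0, 1000]")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class MatchResult:
    """Scores of one library compound against one query acquisition."""

    compound: str
    channel_scores: Mapping[int, int]
    average_score: float
    hit: bool
    sir_confirmed: bool | None = None

    def with_confirmation(self, confirmed: bool | None) -> "MatchResult":
        return replace(self, sir_confirmed=confirmed)


def _sqrt_vectors(query: Spectrum, reference: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    """Square-root intensity vectors of both spectra on the union of their
    nominal m/z bins."""
    q = bin_nominal(query)
    r = bin_nominal(reference)
    union = np.union1d(q.mz, r.mz)
    qv = np.zeros(union.size)
    rv = np.zeros(union.size)
    qv[np.searchsorted(union, q.mz)] = np.sqrt(q.intensities)
    rv[np.searchsorted(union, r.mz)] = np.sqrt(r.intensities)
    return qv, rv


def channel_score(query: Spectrum, reference: Spectrum, kind: str = "cosine") -> int:
    """Similarity of two preprocessed spectra on a 0-1000 scale.

    kind="cosine" (default)
        Cosine between sqrt-intensity vectors on the union of nominal bins;
        symmetric, 1000 for identical spectra, 0 for disjoint peak sets.
    kind="reference"
        Cosine computed over the reference entry's bins only, ignoring query
        peaks at other m/z.  Tolerant of extra ions from co-desorbing
        compounds or matrix (a mixture still scores ~1000 against each pure
        constituent); asymmetric, intended for cocktail-heavy samples.
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("cannot score an empty spectrum")
    qv, rv = _sqrt_vectors(query, reference)
    if kind == "cosine":
        pass
    elif kind == "reference":
        qv = np.where(rv > 0, qv, 0.0)
        if not np.any(qv):
            return 0
    else:
        raise ValueError(f"unknown score kind: {kind!r}")
    denom = float(np.linalg.norm(qv) * np.linalg.norm(rv))
    if denom == 0.0:
        return 0
    cos = float(np.dot(qv, rv)) / denom
    return int(math.floor(1000.0 * cos + 0.5))  # round half-up


def fuse_scores(
    channel_scores: Mapping[int, int] | Sequence[float],
    weights: Sequence[float] | None = None,
) -> float:
    """Weighted arithmetic mean of the (rounded) channel scores."""
    if isinstance(channel_scores, Mapping):
        scores = [channel_scores[v] for v in sorted(channel_scores)]
    else:
        scores = list(channel_scores)
    if weights is None:
        weights = [1.0 / len(scores)] * len(scores)
    if len(weights) != len(scores):
        raise ValueError(
            f"{len(weights)} weights supplied for {len(scores)} channel scores"
        )
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("weights must be non-negative and sum to 1")
    return float(np.dot(w, np.asarray(scores, dtype=float)))


def apply_criteria(result: MatchResult, criteria: MatchCriteria | None = None) -> bool:
    """Evaluate the conjunctive hit rule on a complete result (>= semantics:
    boundary values pass)."""
    criteria = criteria or MatchCriteria()
    voltages = sorted(result.channel_scores)
    ch1 = result.channel_scores[voltages[0]]
    others = [result.channel_scores[v] for v in voltages[1:]]
    return (
        ch1 >= criteria.channel1_min
        and all(s >= criteria.other_channels_min for s in others)
        and result.average_score >= criteria.average_min
    )


def screen(
    query: MultiChannelSpectrum,
    library: Library,
    criteria: MatchCriteria | None = None,
    params: PreprocessParams | None = None,
    kind: str = "cosine",
) -> list[MatchResult]:
    """Score a query acquisition against every library entry.

    The query is preprocessed with the library's build parameters (the chain
    is idempotent, so already-preprocessed queries are unchanged).  Passing
    ``params`` different from the library's build parameters is an error.
    Results are sorted by average score descending, ties broken by
    abbreviation.
    """
    criteria = criteria or MatchCriteria()
    if params is not None and params != library.build_params:
        raise ValueError(
            f"query preprocessing {params} does not match library build "
            f"parameters {library.build_params}"
        )
    if len(library) == 0:
        raise ValueError("empty library")
    prepped = query.map(lambda s: preprocess(s, library.build_params))
    results = []
    for abbr in library.abbreviations:
        entry = library[abbr]
        scores = {
            v: channel_score(prepped[v], entry.channels[v], kind=kind)
            for v in entry.channels.voltages
        }
        avg = fuse_scores(scores, criteria.weights)
        result = MatchResult(compound=abbr, channel_scores=scores, average_score=avg, hit=False)
        results.append(replace(result, hit=apply_criteria(result, criteria)))
    return sorted(results, key=lambda r: (-r.average_score, r.compound))
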