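"""Scikit-learn-style estimator wrapping the library-match screening method.

``fit`` builds the voltage-resolved reference library from labelled standard
acquisitions; ``predict`` returns the multilabel hit matrix under the
conjunctive criteria; ``decision_function`` returns the fused average
scores.  The estimator composes with sklearn model selection and pipelines;
the module-level functions :func:`asapscreen.library.build_library` and
:func:`asapscreen.matching.screen` remain the thin functional interface.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .compounds import CompoundRecord, default_registry
from .library import Library, build_library
from .matching import MatchCriteria, MatchResult, screen
from .spectra import MultiChannelSpectrum, PreprocessParams

__all__ = ["LibraryMatchScreener"]


class LibraryMatchScreener(BaseEstimator):
    """Multilabel screening classifier over a spectral reference library.

    Parameters
    ----------
    threshold_pct, mz_low, mz_high
        Preprocessing applied identically at library build and query time.
    channel1_min, other_channels_min, average_min, weights
        Conjunctive hit criteria and channel-fusion weights.
    score_kind
        ``"cosine"`` (default, symmetric union-bin cosine) or
        ``"reference"`` (mixture-tolerant, reference-bin cosine).
    registry
        Compound panel; defaults to the built-in 17 steroid esters.

    Attributes
    ----------
    library_ : Library
        The reference library built by ``fit``.
    classes_ : ndarray of str
        Compound abbreviations, sorted; the column order of ``predict``.
    """

    def __init__(
        self,
        threshold_pct: float = 5.0,
        mz_low: float = 50.0,
        mz_high: float = 600.0,
        channel1_min: float = 850.0,
        other_channels_min: float = 825.0,
        average_min: float = 800.0,
        weights: tuple[float, ...] | None = None,
        score_kind: str = "cosine",
        registry: Sequence[CompoundRecord] | None = None,
    ):
        self.threshold_pct = threshold_pct
        self.mz_low = mz_low
        self.mz_high = mz_high
        self.channel1_min = channel1_min
        self.other_channels_min = other_channels_min
        self.average_min = average_min
        self.weights = weights
        self.score_kind = score_kind
        self.registry = registry

    # -- configuration helpers ------------------------------------------------

    def _preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(
            mz_low=self.mz_low, mz_high=self.mz_high, threshold_pct=self.threshold_pct
        )

    def _criteria(self) -> MatchCriteria:
        return MatchCriteria(
            channel1_min=self.channel1_min,
            other_channels_min=self.other_channels_min,
            average_min=self.average_min,
            weights=tuple(self.weights) if self.weights is not None else (0.25,) * 4,
        )

    # -- estimator API --------------------------------------------------------

    def fit(
        self,
        X: Sequence[MultiChannelSpectrum] | Mapping[str, MultiChannelSpectrum],
        y: Sequence[str] | None = None,
    ) -> "LibraryMatchScreener":
        """Build the reference library.

        ``X`` is either a mapping abbreviation -> acquisition (``y`` omitted)
        or a sequence of acquisitions with ``y`` the matching abbreviations.
        Repeated labels are averaged peak-wise before thresholding.
        """
        if isinstance(X, Mapping):
            grouped: dict[str, list[MultiChannelSpectrum]] = {k: [v] for k, v in X.items()}
        else:
            if y is None:
                raise ValueError("y (compound abbreviations) required when X is a sequence")
            if len(X) != len(y):
                raise ValueError("X and y must have equal length")
            grouped = {}
            for acq, label in zip(X, y):
                grouped.setdefault(str(label), []).append(acq)
        registry = self.registry if self.registry is not None else default_registry()
        self.library_ = build_library(grouped, registry, self._preprocess_params())
        self.classes_ = np.array(self.library_.abbreviations)
        return self

    def set_library(self, library: Library) -> "LibraryMatchScreener":
        """Adopt a prebuilt library (e.g. read from MSP) as the fitted state."""
        self.library_ = library
        self.classes_ = np.array(library.abbreviations)
        return self

    def screen_one(self, acquisition: MultiChannelSpectrum) -> list[MatchResult]:
        """Full per-compound match results for one acquisition."""
        check_is_fitted(self, "library_")
        return screen(
            acquisition, self.library_, self._criteria(), kind=self.score_kind
        )

    def decision_function(self, X: Sequence[MultiChannelSpectrum]) -> np.ndarray:
        """Fused average scores, shape (n_samples, n_compounds) in
        ``classes_`` order."""
        check_is_fitted(self, "library_")
        rows = []
        for acq in X:
            by_abbr = {r.compound: r.average_score for r in self.screen_one(acq)}
            rows.append([by_abbr[c] for c in self.classes_])
        return np.asarray(rows, dtype=float)

    def predict(self, X: Sequence[MultiChannelSpectrum]) -> np.ndarray:
        """Boolean hit-indicator matrix, shape (n_samples, n_compounds)."""
        check_is_fitted(self, "library_")
        rows = []
        for acq in X:
            by_abbr = {r.compound: r.hit for r in self.screen_one(acq)}
            rows.append([by_abbr[c] for c in self.classes_])
        return np.asarray(rows, dtype=bool)
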