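"""Allred scoring of ER/PR nuclear immunostaining.

Each detected nucleus gets an intensity class 0-3 from its mean DAB
concentration.  A region of interest is then summarized by the Allred system:

* Positivity Score (PS, 0-5) from the fraction of stained (class >= 1) cells:
  0 = none, 1 = up to 1/100, 2 = up to 1/10, 3 = up to 1/3, 4 = up to 2/3,
  5 = up to 100%.
* Intensity Score (IS, 0-3): 0 with no stained cell, otherwise the mean class
  of the stained cells rounded half-up.
* Total Score TS = PS + IS, range 0-8; the region is called positive when
  TS >= 3.

Note PS >= 1 forces IS >= 1, so attainable Total Scores are {0} ∪ {2..8}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "IntensityCutpoints",
    "ROIResult",
    "classify_intensity",
    "classify_objects",
    "positivity_score",
    "intensity_score",
    "score_roi",
    "AllredScorer",
]


@dataclass(frozen=True)
class IntensityCutpoints:
    """Mean-DAB-concentration thresholds separating intensity classes.

    Classes are lower-inclusive bins: class 0 below t1, class 1 in [t1, t2),
    class 2 in [t2, t3), class 3 at or above t3.  Units are DAB optical
    density (concentration) as produced by colour deconvolution.
    """

    t1: float = 0.15
    t2: float = 0.40
    t3: float = 0.70

    def __post_init__(self):
        if not 0.0 < self.t1 < self.t2 < self.t3:
            raise ValueError(
                f"cutpoints must satisfy 0 < t1 < t2 < t3, got "
                f"({self.t1}, {self.t2}, {self.t3})"
            )


@dataclass
class ROIResult:
    """Allred summary of one region of interest."""

    n_total: int
    n_by_class: tuple
    positive_fraction: float
    ps: int
    is_: int
    ts: int
    positive: bool
    empty: bool = False

    def __post_init__(self):
        assert sum(self.n_by_class) == self.n_total
        assert self.ts == self.ps + self.is_


def classify_intensity(mean_dab, cutpoints: IntensityCutpoints | None = None):
    """Intensity class 0-3 of a mean DAB concentration (scalar or array)."""
    if cutpoints is None:
        cutpoints = IntensityCutpoints()
    x = np.asarray(mean_dab, dtype=float)
    if np.any(x < 0):
        raise ValueError("mean DAB concentration must be >= 0")
    cls = np.digitize(x, [cutpoints.t1, cutpoints.t2, cutpoints.t3], right=False)
    return int(cls) if np.isscalar(mean_dab) else cls.astype(int)


def classify_objects(objects, cutpoints: IntensityCutpoints | None = None):
    """Set ``intensity_class`` on each nucleus from its ``mean_dab``; returns the list."""
    for obj in objects:
        obj.intensity_class = classify_intensity(obj.mean_dab, cutpoints)
    return objects


def positivity_score(positive_fraction: float) -> int:
    """Allred Positivity Score (0-5) from the fraction of stained cells.

    Bins are upper-inclusive at the anchor fractions 1/100, 1/10, 1/3, 2/3.
    """
    f = float(positive_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"positive fraction must be in [0, 1], got {f}")
    if f == 0.0:
        return 0
    if f <= 1.0 / 100.0:
        return 1
    if f <= 1.0 / 10.0:
        return 2
    if f <= 1.0 / 3.0:
        return 3
    if f <= 2.0 / 3.0:
        return 4
    return 5


def _classes_of(objects_or_classes) -> np.ndarray:
    items = list(objects_or_classes)
    if items and hasattr(items[0], "intensity_class"):
        cls = [o.intensity_class for o in items]
        if any(c is None for c in cls):
            raise ValueError("objects are not classified; run classify_objects first")
        items = cls
    cls = np.asarray(items, dtype=int)
    if cls.size and (cls.min() < 0 or cls.max() > 3):
        raise ValueError("intensity classes must be in 0..3")
    return cls


def intensity_score(objects_or_classes) -> int:
    """Allred Intensity Score: mean class of stained cells, rounded half-up."""
    cls = _classes_of(objects_or_classes)
    pos = cls[cls >= 1]
    if pos.size == 0:
        return 0
    mean = float(pos.mean())
    return int(min(3, max(1, math.floor(mean + 0.5))))


def score_roi(objects_or_classes) -> ROIResult:
    """Full Allred summary of a region from its (classified) nuclei.

    An empty region yields an all-zero, negative result flagged ``empty``.
    """
    cls = _classes_of(objects_or_classes)
    n = int(cls.size)
    if n == 0:
        warnings.warn("scoring an empty region of interest", stacklevel=2)
        return ROIResult(0, (0, 0, 0, 0), 0.0, 0, 0, 0, False, empty=True)
    counts = tuple(int((cls == k).sum()) for k in range(4))
    frac = float((cls >= 1).sum()) / n
    ps = positivity_score(frac)
    is_ = intensity_score(cls)
    ts = ps + is_
    return ROIResult(n, counts, frac, ps, is_, ts, ts >= 3)


class AllredScorer(BaseEstimator):
    """Estimator assigning intensity classes and Allred scores to regions.

    Parameters are the three DAB-concentration cutpoints; ``predict`` maps a
    list of detected nuclei (or one list per region) to :class:`ROIResult`.
    """

    def __init__(self, t1: float = 0.15, t2: float = 0.40, t3: float = 0.70):
        self.t1 = t1
        self.t2 = t2
        self.t3 = t3

    @property
    def cutpoints(self) -> IntensityCutpoints:
        return IntensityCutpoints(self.t1, self.t2, self.t3)

    def fit(self, X=None, y=None):
        self.cutpoints_ = self.cutpoints
        return self

    def predict(self, X):
        """Score one region (list of nuclei) or several (list of lists)."""
        if not hasattr(self, "cutpoints_"):
            self.fit()
        if X and isinstance(X[0], (list, tuple)):
            return [self._score_one(objs) for objs in X]
        return self._score_one(X)

    def _score_one(self, objects) -> ROIResult:
        classify_objects(objects, self.cutpoints_)
        return score_roi(objects)
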