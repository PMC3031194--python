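"""Calibration of the detector against manual cell annotations.

A pathologist encircles every cell in a set of regions; detection parameters
are then adjusted until the detector closely reproduces that manual marking,
and intensity cutpoints are tuned so algorithmic Allred Total Scores agree
with the pathologist's.  Agreement in cell detection is measured as the
Dice-style one-to-one match fraction 2|M| / (|A| + |D|).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Point, Polygon
from sklearn.base import BaseEstimator

from .allred import IntensityCutpoints, classify_intensity, intensity_score, positivity_score, score_roi
from .agreement import AgreementReport, agreement_report, quadratic_weighted_kappa
from .detect import DetectionParams, detect_nuclei
from .profiles import StainProfile
from .stains import deconvolve, rgb_to_od
from .wallis import wallis_filter

logger = logging.getLogger(__name__)

__all__ = [
    "ManualAnnotation",
    "MatchResult",
    "CalibrationROI",
    "CalibrationReport",
    "match_objects",
    "background_dab_level",
    "is_suitable",
    "calibrate",
    "evaluate_equivalence",
    "NuclearQuantifier",
]


@dataclass
class ManualAnnotation:
    """One manually encircled cell: a circle or polygon with a class label.

    ``label`` is the intensity class 0..3; class 0 means a stained-negative
    (counterstain only) cell.  For calibration purposes labels collapse to
    negative (0) vs positive (>= 1).
    """

    center: tuple
    radius: float = 0.0
    polygon: Polygon | None = None
    label: int = 0

    def __post_init__(self):
        if self.polygon is None and self.radius <= 0:
            raise ValueError("annotation needs a positive radius or a polygon")
        if self.polygon is not None and (self.polygon.is_empty or not self.polygon.is_valid):
            raise ValueError("degenerate annotation polygon")
        if self.label not in (0, 1, 2, 3):
            raise ValueError(f"label must be an intensity class 0..3, got {self.label}")

    @property
    def positive(self) -> bool:
        return self.label >= 1

    def contains(self, point) -> bool:
        if self.polygon is not None:
            return self.polygon.contains(Point(point[1], point[0]))
        dr = point[0] - self.center[0]
        dc = point[1] - self.center[1]
        return dr * dr + dc * dc <= self.radius * self.radius


@dataclass
class MatchResult:
    """One-to-one matching between manual annotations and detected objects."""

    matches: list
    unmatched_manual: list
    unmatched_detected: list
    detection_agreement: float
    class_agreement: float | None

    def __post_init__(self):
        assert 0.0 <= self.detection_agreement <= 1.0


def match_objects(manual, detected, max_dist: float) -> MatchResult:
    """Greedy nearest-centroid one-to-one matching.

    A (annotation, object) pair is eligible when the object centroid lies
    inside the annotation shape or within ``max_dist`` of its center; pairs
    are consumed in order of increasing distance (ties: smaller annotation
    index).  Detection agreement is the Dice fraction 2|M|/(|A|+|D|).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    n_a, n_d = len(manual), len(detected)
    candidates = []
    if n_a and n_d:
        centers = np.array([a.center for a in manual], dtype=float)
        cents = np.array([o.centroid for o in detected], dtype=float)
        d2 = ((centers[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        dist = np.sqrt(d2)
        for i, ann in enumerate(manual):
            reach = max(max_dist, ann.radius)
            for j in np.nonzero(dist[i] <= reach)[0]:
                if dist[i, j] <= max_dist or ann.contains(detected[j].centroid):
                    candidates.append((dist[i, j], i, int(j)))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a, used_d = set(), set()
    matches = []
    for _, i, j in candidates:
        if i in used_a or j in used_d:
            continue
        used_a.add(i)
        used_d.add(j)
        matches.append((manual[i], detected[j]))
    agreement = 2.0 * len(matches) / (n_a + n_d) if (n_a + n_d) else 1.0
    class_agr = None
    classified = [(a, o) for a, o in matches if o.intensity_class is not None]
    if classified:
        same = sum(1 for a, o in classified if a.positive == (o.intensity_class >= 1))
        class_agr = same / len(classified)
    return MatchResult(
        matches=matches,
        unmatched_manual=[a for i, a in enumerate(manual) if i not in used_a],
        unmatched_detected=[o for j, o in enumerate(detected) if j not in used_d],
        detection_agreement=agreement,
        class_agreement=class_agr,
    )


@dataclass
class CalibrationROI:
    """One annotated, pathologist-scored region used for calibration."""

    image: np.ndarray
    annotations: list
    ts: int | None = None  # pathologist Allred Total Score
    name: str = ""


def background_dab_level(img: np.ndarray, profile: StainProfile) -> float:
    """Median DAB concentration of the tile, a proxy for diffuse
    (cytoplasmic) background staining."""
    maps = deconvolve(rgb_to_od(img), profile.basis)
    return float(np.median(maps["DAB"]))


def is_suitable(img: np.ndarray, profile: StainProfile) -> bool:
    """Whether a region is suitable for quantification (background DAB below
    the profile threshold)."""
    return background_dab_level(img, profile) <= profile.max_background_dab


def _precompute(img: np.ndarray, profile: StainProfile):
    """Stain separation + Wallis normalization, reusable across detection
    parameter candidates (which touch neither)."""
    maps = deconvolve(rgb_to_od(img), profile.basis)
    h = maps.maps[profile.basis.index("hematoxylin")]
    d = maps.maps[profile.basis.index("DAB")]
    g = np.clip((h + d) / float(profile.intensity_scale), 0.0, 1.0)
    return wallis_filter(g, profile.wallis), d


def _median_radius(rois) -> float:
    radii = [a.radius for roi in rois for a in roi.annotations if a.radius > 0]
    return float(np.median(radii)) if radii else 8.0


def _mean_agreement(rois, profile, pre, max_dist):
    agr = []
    for roi, cached in zip(rois, pre):
        objs = detect_nuclei(roi.image, profile, precomputed=cached)
        agr.append(match_objects(roi.annotations, objs, max_dist).detection_agreement)
    return float(np.mean(agr)), agr


def _stage1_search(rois, profile, search_space, max_dist=None):
    """Coordinate descent over detection parameters maximizing mean
    detection agreement; best-so-far objective is non-decreasing."""
    rois = [roi if isinstance(roi, CalibrationROI) else CalibrationROI(*roi) for roi in rois]
    if max_dist is None:
        max_dist = _median_radius(rois)
    pre = [_precompute(roi.image, profile) for roi in rois]
    space = {k: list(v) for k, v in search_space.items() if k != "cutpoints"}
    for key in space:
        if key not in DetectionParams.__dataclass_fields__:
            raise ValueError(f"unknown detection parameter {key!r} in search space")
        if not space[key]:
            raise ValueError(f"empty search space for {key!r}")
    best = profile
    best_obj, _ = _mean_agreement(rois, best, pre, max_dist)
    history = [best_obj]
    for _sweep in range(3):
        improved = False
        for key, values in space.items():
            for value in values:
                if value == getattr(best.detection, key):
                    continue
                cand = best.with_detection(replace(best.detection, **{key: value}))
                obj, _ = _mean_agreement(rois, cand, pre, max_dist)
                if obj > best_obj + 1e-12:
                    best, best_obj = cand, obj
                    improved = True
            history.append(best_obj)
        if not improved:
            break
    return best, history


def _stage2_search(rois, profile, cut_space, pre):
    """Grid search over intensity cutpoints maximizing quadratic weighted
    kappa of algorithmic vs pathologist Total Scores."""
    scored = [roi for roi in rois if roi.ts is not None]
    if not scored:
        return profile, []
    per_roi_dab = []
    for roi, cached in zip(rois, pre):
        if roi.ts is None:
            continue
        objs = detect_nuclei(roi.image, profile, precomputed=cached)
        per_roi_dab.append(np.array([o.mean_dab for o in objs]))
    grids = [list(cut_space.get(k, [])) for k in ("t1", "t2", "t3")]
    if not all(grids):
        raise ValueError("cutpoint search space must list values for t1, t2 and t3")
    ref_ts = [roi.ts for roi in scored]
    categories = list(range(9))
    best_cut, best_obj = None, -np.inf
    history = []
    for t1, t2, t3 in itertools.product(*grids):
        if not t1 < t2 < t3:
            continue
        cut = IntensityCutpoints(t1, t2, t3)
        alg_ts = []
        for dabs in per_roi_dab:
            cls = classify_intensity(dabs, cut) if dabs.size else np.array([], dtype=int)
            alg_ts.append(score_roi(cls).ts)
        try:
            kw, _ = quadratic_weighted_kappa(ref_ts, alg_ts, categories)
        except Exception:
            kw = -np.inf
        history.append(((t1, t2, t3), kw))
        if kw > best_obj + 1e-12:
            best_cut, best_obj = cut, kw
    if best_cut is None:
        raise ValueError("cutpoint search space contains no valid (t1 < t2 < t3) triple")
    return profile.with_cutpoints(best_cut), history


@dataclass
class CalibrationReport:
    """Outcome of the two-stage calibration."""

    profile: StainProfile
    initial_agreement: float
    final_agreement: float
    per_roi_agreement: list
    stage1_history: list
    stage2_history: list
    initial_weighted_kappa: float | None = None
    final_weighted_kappa: float | None = None

    def to_dict(self) -> dict:
        return {
            "profile": self.profile.to_dict(),
            "initial_agreement": self.initial_agreement,
            "final_agreement": self.final_agreement,
            "per_roi_agreement": self.per_roi_agreement,
            "stage1_history": self.stage1_history,
            "stage2_history": [
                {"cutpoints": list(c), "weighted_kappa": k} for c, k in self.stage2_history
            ],
            "initial_weighted_kappa": self.initial_weighted_kappa,
            "final_weighted_kappa": self.final_weighted_kappa,
        }


def calibrate(rois, search_space, seed: int = 0, profile: StainProfile | None = None,
              max_dist: float | None = None) -> CalibrationReport:
    """Two-stage calibration of a detection profile on annotated regions.

    Stage 1: coordinate descent over the detection-parameter grid in
    ``search_space`` maximizing mean one-to-one detection agreement across
    regions.  Stage 2: grid search over intensity cutpoints
    (``search_space['cutpoints']`` with lists for t1, t2, t3) maximizing
    quadratic weighted kappa of Total Scores against the pathologist's.
    Deterministic given the input order; ``seed`` is accepted for interface
    uniformity (the search itself is exhaustive, not stochastic).
    """
    rois = [roi if isinstance(roi, CalibrationROI) else CalibrationROI(*roi) for roi in rois]
    if not rois:
        raise ValueError("need at least one calibration region")
    if not search_space:
        raise ValueError("empty search space")
    base = profile if profile is not None else StainProfile.default()
    if max_dist is None:
        max_dist = _median_radius(rois)
    pre = [_precompute(roi.image, base) for roi in rois]
    init_obj, _ = _mean_agreement(rois, base, pre, max_dist)

    stage1 = {k: v for k, v in search_space.items() if k != "cutpoints"}
    if stage1:
        fitted, history = _stage1_search(rois, base, stage1, max_dist)
    else:
        fitted, history = base, [init_obj]
    final_obj, per_roi = _mean_agreement(rois, fitted, pre, max_dist)

    init_kw = final_kw = None
    stage2_history = []
    cut_space = search_space.get("cutpoints")
    scored = [roi for roi in rois if roi.ts is not None]
    if cut_space and scored:
        init_kw = _ts_weighted_kappa(rois, fitted, pre)
        fitted, stage2_history = _stage2_search(rois, fitted, cut_space, pre)
        final_kw = _ts_weighted_kappa(rois, fitted, pre)
    logger.info(
        "calibration: agreement %.3f -> %.3f; weighted kappa %s -> %s",
        init_obj, final_obj, init_kw, final_kw,
    )
    return CalibrationReport(
        profile=fitted,
        initial_agreement=init_obj,
        final_agreement=final_obj,
        per_roi_agreement=per_roi,
        stage1_history=history,
        stage2_history=stage2_history,
        initial_weighted_kappa=init_kw,
        final_weighted_kappa=final_kw,
    )


def _ts_weighted_kappa(rois, profile, pre=None):
    if pre is None:
        pre = [_precompute(roi.image, profile) for roi in rois]
    ref, alg = [], []
    for roi, cached in zip(rois, pre):
        if roi.ts is None:
            continue
        objs = detect_nuclei(roi.image, profile, precomputed=cached)
        cls = classify_intensity(np.array([o.mean_dab for o in objs]), profile.cutpoints) \
            if objs else np.array([], dtype=int)
        ref.append(roi.ts)
        alg.append(score_roi(cls).ts)
    if len(ref) < 2:
        return None
    kw, _ = quadratic_weighted_kappa(ref, alg, list(range(9)))
    return kw


@dataclass
class EquivalenceResult:
    """Agreement of algorithmic vs reference Allred scores over regions."""

    report: AgreementReport
    binary_report: AgreementReport | None
    ts_pairs: list
    excluded: list


def evaluate_equivalence(rois, profile: StainProfile) -> EquivalenceResult:
    """Score every suitable region with a fixed profile and quantify
    agreement of Total Scores (0..8) and of positive/negative calls
    against the reference scores.

    Regions with background DAB above the profile threshold are excluded as
    unsuitable for quantification; an empty remainder is an error.
    """
    rois = [roi if isinstance(roi, CalibrationROI) else CalibrationROI(*roi) for roi in rois]
    pairs, excluded = [], []
    for idx, roi in enumerate(rois):
        if not is_suitable(roi.image, profile):
            excluded.append(roi.name or f"roi_{idx}")
            continue
        objs = detect_nuclei(roi.image, profile)
        cls = classify_intensity(np.array([o.mean_dab for o in objs]), profile.cutpoints) \
            if objs else np.array([], dtype=int)
        pairs.append((roi.ts, score_roi(cls).ts))
    if not pairs:
        raise ValueError(
            "no region suitable for quantification remains after exclusion"
        )
    ref = [a for a, _ in pairs]
    alg = [b for _, b in pairs]
    report = agreement_report(ref, alg, categories=list(range(9)))
    binary = None
    try:
        binary = agreement_report(
            [int(t >= 3) for t in ref], [int(t >= 3) for t in alg], categories=[0, 1]
        )
    except Exception:
        pass
    return EquivalenceResult(report=report, binary_report=binary, ts_pairs=pairs, excluded=excluded)


class NuclearQuantifier(BaseEstimator):
    """End-to-end estimator: calibrate on annotated regions, then score tiles.

    ``fit(X)`` takes a list of :class:`CalibrationROI` (image, per-cell
    annotations, pathologist Total Score) and runs the two-stage calibration;
    ``predict(X)`` maps RGB tiles to Allred :class:`~ihcquant.allred.ROIResult`
    summaries with the fitted profile; ``score(X)`` returns the mean
    detection agreement against annotations.
    """

    def __init__(self, profile: StainProfile | None = None, search_space: dict | None = None,
                 seed: int = 0):
        self.profile = profile
        self.search_space = search_space
        self.seed = seed

    def fit(self, X, y=None):
        base = self.profile if self.profile is not None else StainProfile.default()
        if self.search_space:
            report = calibrate(X, self.search_space, seed=self.seed, profile=base)
            self.report_ = report
            self.profile_ = report.profile
        else:
            self.profile_ = base
        return self

    def predict(self, X):
        """Allred ROIResult for each RGB tile in X."""
        if not hasattr(self, "profile_"):
            self.profile_ = self.profile if self.profile is not None else StainProfile.default()
        single = isinstance(X, np.ndarray) and X.ndim == 3
        tiles = [X] if single else list(X)
        results = []
        for img in tiles:
            objs = detect_nuclei(img, self.profile_)
            cls = classify_intensity(
                np.array([o.mean_dab for o in objs]), self.profile_.cutpoints
            ) if objs else np.array([], dtype=int)
            results.append(score_roi(cls))
        return results[0] if single else results

    def score(self, X, y=None) -> float:
        """Mean one-to-one detection agreement over annotated regions."""
        rois = [roi if isinstance(roi, CalibrationROI) else CalibrationROI(*roi) for roi in X]
        max_dist = _median_radius(rois)
        agr = []
        for roi in rois:
            objs = detect_nuclei(roi.image, self.profile_)
            agr.append(match_objects(roi.annotations, objs, max_dist).detection_agreement)
        return float(np.mean(agr))
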