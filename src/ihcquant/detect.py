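"""Nucleus detection on the normalized stain-intensity image.

Detection runs on a grayscale "detection intensity" image — the sum of the
hematoxylin and DAB concentration maps rescaled to [0, 1] and Wallis
normalized — so counterstained-only (receptor-negative) and DAB-stained
nuclei are detected alike.  Candidate objects come from a fixed global
threshold; touching nuclei are separated by a distance-transform watershed;
candidates are then filtered on morphometrics: area, roundness (4*pi*A/P^2),
average density, and boundary contrast (interior minus a 2-px outer ring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import perimeter as _skimage_perimeter
from skimage.morphology import disk
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator

from .stains import deconvolve, rgb_to_od
from .wallis import wallis_filter

__all__ = [
    "DetectionParams",
    "NucleusObject",
    "roundness",
    "detection_intensity_image",
    "split_joint_objects",
    "detect_nuclei",
    "NucleusDetector",
]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds and morphometric bounds of the nucleus detector.

    All intensity-like bounds refer to the normalized detection image in
    [0, 1]; areas are in pixels^2, distances in pixels.  The threshold is a
    fixed profile parameter (calibrated once, applied to every slide) rather
    than recomputed per image.
    """

    threshold: float = 0.35
    min_area: int = 40
    max_area: int = 5000
    min_roundness: float = 0.30
    min_avg_density: float = 0.30
    min_boundary_contrast: float = 0.02
    split_enabled: bool = True
    split_min_distance: int = 7
    smoothing_sigma: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if not 0 < self.min_area < self.max_area:
            raise ValueError("require 0 < min_area < max_area")
        if not 0.0 <= self.min_roundness <= 1.0:
            raise ValueError("min_roundness must be in [0, 1]")
        if not 0.0 <= self.min_avg_density <= 1.0:
            raise ValueError("min_avg_density must be in [0, 1]")
        if not -1.0 <= self.min_boundary_contrast <= 1.0:
            raise ValueError("min_boundary_contrast must be in [-1, 1]")
        if self.split_min_distance < 1:
            raise ValueError("split_min_distance must be >= 1")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


@dataclass
class NucleusObject:
    """One detected nucleus: a connected pixel set with its morphometrics.

    ``mask`` is a boolean patch positioned at ``bbox`` = (r0, c0, r1, c1) in
    image coordinates (0-based, row-major, origin top-left); the centroid is
    sub-pixel, in absolute image coordinates.
    """

    label: int
    mask: np.ndarray
    bbox: tuple
    centroid: tuple
    area: int
    perimeter: float
    roundness: float
    avg_density: float
    boundary_contrast: float
    mean_dab: float
    intensity_class: int | None = None

    def full_mask(self, shape) -> np.ndarray:
        """Boolean mask in full-image coordinates."""
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


def roundness(area: float, perimeter: float) -> float:
    """Isoperimetric roundness 4*pi*A/P^2: 1 for an ideal circle."""
    if perimeter <= 0:
        raise ValueError("perimeter must be > 0")
    return 4.0 * math.pi * float(area) / float(perimeter) ** 2


def detection_intensity_image(img: np.ndarray, profile) -> np.ndarray:
    """Normalized grayscale image that drives detection.

    (c_H + c_DAB) / K clipped to [0, 1] (K = ``profile.intensity_scale``),
    then Wallis-filtered with the profile's parameters.
    """
    maps = deconvolve(rgb_to_od(img), profile.basis)
    g = _pre_wallis_intensity(maps, profile)
    return wallis_filter(g, profile.wallis)


def _pre_wallis_intensity(maps, profile) -> np.ndarray:
    h = maps.maps[profile.basis.index("hematoxylin")]
    d = maps.maps[profile.basis.index("DAB")]
    return np.clip((h + d) / float(profile.intensity_scale), 0.0, 1.0)


def split_joint_objects(
    mask: np.ndarray,
    intensity: np.ndarray | None = None,
    split_min_distance: int = 7,
) -> list:
    """Separate a connected component into touching nuclei.

    Watershed on the (lightly smoothed) Euclidean distance transform, seeded
    at local maxima at least ``split_min_distance`` apart.  The children
    exactly partition the parent; with a single seed the parent is returned
    unchanged.  ``intensity`` is accepted for interface compatibility but the
    split is driven by shape (the distance transform) alone.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot split an empty mask")
    dist = ndi.distance_transform_edt(mask)
    dist = gaussian(dist, sigma=1.0, preserve_range=True)
    peaks = peak_local_max(
        dist,
        min_distance=int(split_min_distance),
        labels=mask.astype(np.int32),
        exclude_border=False,
    )
    if len(peaks) <= 1:
        return [mask]
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers=markers, mask=mask, connectivity=2)
    children = [labels == k for k in range(1, len(peaks) + 1)]
    return [c for c in children if c.any()]


_RING = disk(2)


def _boundary_ring_means(g, mask, bbox, shape):
    """Mean interior intensity and mean intensity of the 2-px outer ring."""
    r0, c0, r1, c1 = bbox
    pr0, pc0 = max(r0 - 2, 0), max(c0 - 2, 0)
    pr1, pc1 = min(r1 + 2, shape[0]), min(c1 + 2, shape[1])
    padded = np.zeros((pr1 - pr0, pc1 - pc0), dtype=bool)
    padded[r0 - pr0 : r1 - pr0, c0 - pc0 : c1 - pc0] = mask
    ring = ndi.binary_dilation(padded, structure=_RING) & ~padded
    patch = g[pr0:pr1, pc0:pc1]
    interior = float(patch[padded].mean())
    ring_mean = float(patch[ring].mean()) if ring.any() else interior
    return interior, ring_mean


def _measure(mask, bbox, g, dab, shape, label=0):
    area = int(mask.sum())
    perim = float(_skimage_perimeter(mask, neighborhood=4))
    rnd = roundness(area, perim) if perim > 0 else 0.0
    rows, cols = np.nonzero(mask)
    centroid = (float(rows.mean()) + bbox[0], float(cols.mean()) + bbox[1])
    r0, c0, r1, c1 = bbox
    avg_density = float(g[r0:r1, c0:c1][mask].mean())
    interior, ring = _boundary_ring_means(g, mask, bbox, shape)
    mean_dab = float(dab[r0:r1, c0:c1][mask].mean())
    return NucleusObject(
        label=label,
        mask=mask,
        bbox=bbox,
        centroid=centroid,
        area=area,
        perimeter=perim,
        roundness=rnd,
        avg_density=avg_density,
        boundary_contrast=interior - ring,
        mean_dab=mean_dab,
        intensity_class=None,
    )


def detect_nuclei(img: np.ndarray, profile, *, precomputed=None) -> list:
    """Detect nuclei in an RGB tile with a detection profile.

    Pipeline: normalized detection image -> Gaussian smoothing -> global
    threshold -> 8-connected components -> optional watershed splitting ->
    morphometric filtering.  Deterministic; objects are sorted by centroid
    (row, then column) and labelled 1..n.

    ``precomputed`` may carry ``(normalized_image, dab_map)`` to reuse the
    stain separation and Wallis steps across repeated detections (as the
    calibration search does).
    """
    p: DetectionParams = profile.detection
    if precomputed is not None:
        g, dab = precomputed
    else:
        maps = deconvolve(rgb_to_od(img), profile.basis)
        g = wallis_filter(_pre_wallis_intensity(maps, profile), profile.wallis)
        dab = maps.maps[profile.basis.index("DAB")]

    gs = gaussian(g, sigma=p.smoothing_sigma, preserve_range=True) if p.smoothing_sigma > 0 else g
    binary = gs >= p.threshold
    labels, n_comp = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        return []

    objects = []
    slices = ndi.find_objects(labels)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labels[sl] == idx
        if comp.sum() < p.min_area:  # cheap pre-filter before splitting
            continue
        bbox0 = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
        if p.split_enabled:
            children = split_joint_objects(comp, split_min_distance=p.split_min_distance)
        else:
            children = [comp]
        for child in children:
            rows, cols = np.nonzero(child)
            r0, c0 = rows.min(), cols.min()
            r1, c1 = rows.max() + 1, cols.max() + 1
            sub = child[r0:r1, c0:c1]
            bbox = (bbox0[0] + r0, bbox0[1] + c0, bbox0[0] + r1, bbox0[1] + c1)
            obj = _measure(sub, bbox, g, dab, g.shape)
            if (
                p.min_area <= obj.area <= p.max_area
                and obj.roundness >= p.min_roundness
                and obj.avg_density >= p.min_avg_density
                and obj.boundary_contrast >= p.min_boundary_contrast
            ):
                objects.append(obj)

    objects.sort(key=lambda o: o.centroid)
    for i, obj in enumerate(objects, start=1):
        obj.label = i
    return objects


class NucleusDetector(BaseEstimator):
    """Estimator detecting nuclei in RGB tiles with fixed profile parameters.

    ``predict`` maps an image (or list of images) to lists of
    :class:`NucleusObject`.  ``fit`` accepts annotated regions and performs
    the stage-1 detection calibration (see :mod:`ihcquant.calibrate`); with
    no search space it simply freezes the current parameters.
    """

    def __init__(self, profile=None, search_space=None):
        self.profile = profile
        self.search_space = search_space

    def fit(self, X=None, y=None):
        """Freeze (or calibrate) the detection profile.

        X : list of (image, annotations) pairs, optional; used only when a
        ``search_space`` over detection parameters is given.
        """
        from .profiles import StainProfile

        profile = self.profile if self.profile is not None else StainProfile.default()
        if self.search_space and X:
            from .calibrate import _stage1_search

            rois = [(img, ann) for img, ann in X]
            profile, history = _stage1_search(rois, profile, self.search_space)
            self.history_ = history
        self.profile_ = profile
        return self

    def predict(self, X):
        if not hasattr(self, "profile_"):
            self.fit()
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return detect_nuclei(X, self.profile_)
        return [detect_nuclei(img, self.profile_) for img in X]

    def set_detection(self, **kwargs) -> "NucleusDetector":
        """Return a copy of the fitted profile with updated detection params."""
        if not hasattr(self, "profile_"):
            self.fit()
        self.profile_ = self.profile_.with_detection(replace(self.profile_.detection, **kwargs))
        return self
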