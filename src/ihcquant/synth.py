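"""Synthetic H-DAB tiles with exact per-nucleus ground truth.

Slides are rendered with the same Beer-Lambert model the deconvolution
inverts: per-pixel transmitted light I = 255 * 10^-(c_H*v_H + c_DAB*v_DAB)
plus additive Gaussian sensor noise and an optional diffuse cytoplasmic DAB
background.  Nuclei are hard-edged ellipses placed by rejection sampling; a
configurable fraction is deliberately placed at sub-diameter spacing to
exercise the watershed splitting of touching nuclei.  Every generated tile
carries full ground truth (centers, radii, intensity classes, Allred
scores), so the whole pipeline is testable without real slides.

Two presets emulate a typical validation-study layout of a calibration set (38 regions,
lognormal cell counts with mean 195 clamped to [73, 489]) and an equivalence
set (53 regions spanning the attainable Total Scores, 7 negative and 46
positive reference calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as _draw_ellipse

from .allred import score_roi
from .calibrate import CalibrationROI, ManualAnnotation
from .stains import StainBasis

__all__ = [
    "SlideSpec",
    "GroundTruthNucleus",
    "GroundTruth",
    "generate_slide",
    "generate_calibration_set",
    "generate_equivalence_set",
]

#: Default DAB concentration range per intensity class (disjoint, mid-bin
#: relative to the default cutpoints 0.15/0.40/0.70 so slight edge dilution
#: in measured means does not flip classes).
DEFAULT_DAB_BY_CLASS = {1: (0.20, 0.32), 2: (0.48, 0.62), 3: (0.78, 0.92)}


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic tile.

    noise_sd is additive Gaussian noise in 8-bit intensity units;
    cytoplasmic_dab is a diffuse background DAB concentration (OD units)
    emulating cytoplasmic staining; concentrations per class must stay in
    disjoint, increasing ranges.  Image scale is an implied ~0.23 um/px
    (metadata only).
    """

    width: int = 576
    height: int = 576
    n_cells: int = 200
    positive_fraction: float = 0.3
    class_mix: tuple = (1 / 3, 1 / 3, 1 / 3)
    radius_mean: float = 7.0
    radius_sd: float = 1.0
    touching_fraction: float = 0.15
    noise_sd: float = 2.0
    cytoplasmic_dab: float = 0.02
    hematoxylin_conc: float = 0.60
    dab_conc_by_class: dict = field(default_factory=lambda: dict(DEFAULT_DAB_BY_CLASS))
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValueError("tile dimensions must be >= 64")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not np.isclose(sum(self.class_mix), 1.0):
            raise ValueError("class_mix probabilities must sum to 1")
        if not 0.0 <= self.touching_fraction <= 1.0:
            raise ValueError("touching_fraction must be in [0, 1]")
        lo_prev = 0.0
        for k in (1, 2, 3):
            lo, hi = self.dab_conc_by_class[k]
            if not lo_prev < lo < hi:
                raise ValueError("class concentration ranges must be ordered and disjoint")
            lo_prev = hi
        if self.cytoplasmic_dab < 0:
            raise ValueError("cytoplasmic_dab must be >= 0")


@dataclass
class GroundTruthNucleus:
    center: tuple  # (row, col)
    radius: float
    intensity_class: int


@dataclass
class GroundTruth:
    """Exact per-nucleus and region-level truth of one synthetic tile."""

    nuclei: list
    positive_fraction: float
    ps: int
    is_: int
    ts: int

    @property
    def n_cells(self) -> int:
        return len(self.nuclei)


def _place_centers(rng, spec: SlideSpec, radii):
    """Rejection-sampled centers: singles keep >= 2.6 * radius_mean spacing,
    touching pairs sit at 0.75 * (r_i + r_j) (overlapping ellipses)."""
    n = spec.n_cells
    n_pairs = int(round(spec.touching_fraction * n / 2.0))
    margin = 2.0 * spec.radius_mean
    min_dist = 2.6 * spec.radius_mean
    lo_r, hi_r = margin, spec.height - margin
    lo_c, hi_c = margin, spec.width - margin
    centers = np.empty((0, 2))

    def ok(pt, exempt=None):
        if centers.shape[0] == 0:
            return True
        d2 = ((centers - pt) ** 2).sum(axis=1)
        if exempt is not None:
            d2 = np.delete(d2, exempt)
        return d2.size == 0 or d2.min() >= min_dist**2

    max_attempts = 400 * max(n, 1)
    attempts = 0
    placed = 0
    pair_partner_of = {}
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"infeasible packing: placed {placed}/{n} cells in a "
                f"{spec.width}x{spec.height} tile after {max_attempts} attempts"
            )
        pt = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
        if not ok(pt):
            continue
        if placed < 2 * n_pairs and placed + 1 < n:
            # place an anchor and its touching partner together
            theta = rng.uniform(0, 2 * np.pi)
            gap = 0.75 * (radii[placed] + radii[placed + 1])
            partner = pt + gap * np.array([np.sin(theta), np.cos(theta)])
            if not (lo_r <= partner[0] <= hi_r and lo_c <= partner[1] <= hi_c):
                continue
            if centers.shape[0] and ((centers - partner) ** 2).sum(axis=1).min() < min_dist**2:
                continue
            centers = np.vstack([centers, pt, partner])
            pair_partner_of[placed] = placed + 1
            placed += 2
        else:
            centers = np.vstack([centers, pt])
            placed += 1
    return centers


def _assign_classes(rng, spec: SlideSpec):
    n = spec.n_cells
    n_pos = int(round(spec.positive_fraction * n))
    classes = np.zeros(n, dtype=int)
    if n_pos:
        classes[:n_pos] = rng.choice([1, 2, 3], size=n_pos, p=np.asarray(spec.class_mix))
    rng.shuffle(classes)
    return classes


def generate_slide(spec: SlideSpec):
    """Render one tile; identical spec (incl. seed) gives identical pixels.

    Returns (image uint8 HxWx3, :class:`GroundTruth`).
    """
    rng = np.random.default_rng(spec.seed)
    basis = StainBasis.h_dab()
    v_h = basis.vectors[basis.index("hematoxylin")]
    v_d = basis.vectors[basis.index("DAB")]

    n = spec.n_cells
    radii = np.clip(
        rng.normal(spec.radius_mean, spec.radius_sd, size=n),
        0.6 * spec.radius_mean,
        1.6 * spec.radius_mean,
    ) if n else np.empty(0)
    centers = _place_centers(rng, spec, radii) if n else np.empty((0, 2))
    classes = _assign_classes(rng, spec)

    c_h = np.zeros((spec.height, spec.width))
    c_d = np.full((spec.height, spec.width), spec.cytoplasmic_dab)
    nuclei = []
    for i in range(n):
        r = radii[i]
        ecc = rng.uniform(0.0, 0.15)
        a, b = r * (1 + ecc), r * (1 - ecc)
        rot = rng.uniform(0, np.pi)
        rr, cc = _draw_ellipse(
            centers[i, 0], centers[i, 1], a, b,
            shape=(spec.height, spec.width), rotation=rot,
        )
        h_conc = spec.hematoxylin_conc * rng.uniform(0.9, 1.1)
        c_h[rr, cc] = np.maximum(c_h[rr, cc], h_conc)
        k = int(classes[i])
        if k >= 1:
            lo, hi = spec.dab_conc_by_class[k]
            d_conc = rng.uniform(lo, hi)
            c_d[rr, cc] = np.maximum(c_d[rr, cc], d_conc)
        nuclei.append(GroundTruthNucleus(center=(centers[i, 0], centers[i, 1]),
                                         radius=float(r), intensity_class=k))

    od = c_h[..., None] * v_h + c_d[..., None] * v_d
    img = 255.0 * np.power(10.0, -od)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    roi = score_roi(classes)
    truth = GroundTruth(
        nuclei=nuclei,
        positive_fraction=roi.positive_fraction,
        ps=roi.ps,
        is_=roi.is_,
        ts=roi.ts,
    )
    return img, truth


def annotations_from_truth(truth: GroundTruth):
    """Manual-annotation analogues derived from ground truth (circles at the
    true centers/radii, labelled with the true intensity class)."""
    return [
        ManualAnnotation(center=nuc.center, radius=nuc.radius, label=nuc.intensity_class)
        for nuc in truth.nuclei
    ]


def _stratified_lognormal_counts(rng, n, mean, sigma, lo, hi):
    """Lognormal counts with the stated mean, sampled by equal-probability
    strata so the sample mean is a faithful estimate at small n, then
    clamped to [lo, hi]."""
    mu = np.log(mean) - sigma**2 / 2.0
    u = (np.arange(n) + rng.uniform(0, 1, size=n)) / n
    rng.shuffle(u)
    from scipy.stats import norm

    draws = np.exp(mu + sigma * norm.ppf(u))
    return np.clip(np.round(draws), lo, hi).astype(int)


#: Positivity fractions and class mixes cycled across the calibration set so
#: it covers the full positivity range (as such samples are selected to in practice).
_CAL_FRACTIONS = (0.0, 0.005, 0.03, 0.08, 0.2, 0.35, 0.5, 0.65, 0.8, 0.95, 1.0)
_CAL_MIXES = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0), (0.3, 0.4, 0.3))


def generate_calibration_set(seed: int = 0, n_rois: int = 38, **overrides):
    """38 annotated, scored regions emulating the calibration sample
    (lognormal cell counts, mean 195, clamped to [73, 489], all positivity
    ranges represented).

    Returns a list of :class:`~ihcquant.calibrate.CalibrationROI` whose
    annotations and Total Scores come from the generator's ground truth.
    """
    rng = np.random.default_rng(seed)
    counts = _stratified_lognormal_counts(rng, n_rois, mean=195, sigma=0.35, lo=73, hi=489)
    rois = []
    for i in range(n_rois):
        spec = SlideSpec(
            n_cells=int(counts[i]),
            positive_fraction=_CAL_FRACTIONS[i % len(_CAL_FRACTIONS)],
            class_mix=_CAL_MIXES[i % len(_CAL_MIXES)],
            seed=int(rng.integers(0, 2**31 - 1)),
            **overrides,
        )
        img, truth = generate_slide(spec)
        rois.append(
            CalibrationROI(
                image=img,
                annotations=annotations_from_truth(truth),
                ts=truth.ts,
                name=f"cal_{i:03d}",
            )
        )
    return rois


def _equivalence_targets():
    """(positive_fraction, class_mix) recipes: 7 negative regions (TS 0 or 2)
    and 46 positive ones jointly covering the attainable Total Scores 2..8."""
    negative = [
        (0.0, (1.0, 0.0, 0.0)),  # TS 0
        (0.0, (1.0, 0.0, 0.0)),
        (0.0, (1.0, 0.0, 0.0)),
        (0.0, (1.0, 0.0, 0.0)),
        (0.008, (1.0, 0.0, 0.0)),  # PS1 + IS1 = TS 2
        (0.008, (1.0, 0.0, 0.0)),
        (0.008, (1.0, 0.0, 0.0)),
    ]
    positive_cycle = [
        (0.05, (1.0, 0.0, 0.0)),   # PS2 IS1 = 3
        (0.05, (0.0, 1.0, 0.0)),   # PS2 IS2 = 4
        (0.2, (1.0, 0.0, 0.0)),    # PS3 IS1 = 4
        (0.2, (0.0, 1.0, 0.0)),    # PS3 IS2 = 5
        (0.5, (1.0, 0.0, 0.0)),    # PS4 IS1 = 5
        (0.5, (0.0, 1.0, 0.0)),    # PS4 IS2 = 6
        (0.2, (0.0, 0.0, 1.0)),    # PS3 IS3 = 6
        (0.5, (0.0, 0.0, 1.0)),    # PS4 IS3 = 7
        (0.85, (0.0, 1.0, 0.0)),   # PS5 IS2 = 7
        (0.85, (0.0, 0.0, 1.0)),   # PS5 IS3 = 8
        (0.95, (0.25, 0.5, 0.25)), # PS5, mixed IS2 = 7
        (0.65, (0.2, 0.6, 0.2)),   # PS4, mixed IS2 = 6
    ]
    positive = [positive_cycle[i % len(positive_cycle)] for i in range(46)]
    return negative + positive


def generate_equivalence_set(seed: int = 0, n_rois: int = 53, full_scale: bool = False,
                             **overrides):
    """53 scored regions for the equivalence experiment.

    Ground-truth Total Scores cover the attainable values (0, 2..8) with at
    least 7 negative and 46 positive reference calls in the default draw.
    Cell counts default to ~500 per region for desk runtime; ``full_scale``
    switches to full-slide-scale counts (lognormal mean ~5069, clamped to
    [2780, 19740]) with correspondingly larger tiles.
    """
    rng = np.random.default_rng(seed)
    targets = _equivalence_targets()
    if n_rois != len(targets):
        idx = [i % len(targets) for i in range(n_rois)]
        targets = [targets[i] for i in idx]
    if full_scale:
        counts = _stratified_lognormal_counts(rng, n_rois, mean=5069, sigma=0.5,
                                              lo=2780, hi=19740)
        size = {"width": 2048, "height": 2048}
    else:
        counts = _stratified_lognormal_counts(rng, n_rois, mean=500, sigma=0.15,
                                              lo=300, hi=700)
        size = {"width": 640, "height": 640}
    order = rng.permutation(n_rois)
    rois = []
    for i in range(n_rois):
        frac, mix = targets[order[i]]
        spec = SlideSpec(
            n_cells=int(counts[i]),
            positive_fraction=frac,
            class_mix=mix,
            seed=int(rng.integers(0, 2**31 - 1)),
            **size,
            **overrides,
        )
        img, truth = generate_slide(spec)
        rois.append(
            CalibrationROI(
                image=img,
                annotations=annotations_from_truth(truth),
                ts=truth.ts,
                name=f"eq_{i:03d}",
            )
        )
    return rois
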