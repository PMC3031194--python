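# Methods note

This note records the image model, the algorithmic choices and their
parameter defaults, how the synthetic data emulate the intended use, and
what the test suite does and does not demonstrate.

## Image model

Brightfield H-DAB tiles are modelled by Beer–Lambert absorption: a pixel
with stain concentrations `c` transmits `I = 255 · 10^(−Σ_s c_s v_s)` where
`v_s` are unit-norm RGB absorption vectors. The package uses the standard
Ruifrok–Johnston vectors, hematoxylin ≈ (0.650, 0.704, 0.286) and DAB ≈
(0.269, 0.568, 0.778), with the residual channel completed as their
normalized cross product. Deconvolution inverts this linear system in
optical-density space (`OD = −log10(max(I,1)/255)`; intensities are floored
at 1 to keep OD finite) and clips negative concentrations to zero. The
"concentration" unit is therefore OD along the stain vector, not molarity;
all cutpoints below are in these units.

## Pipeline parameters

Detection operates on `(c_H + c_DAB) / intensity_scale` (scale 2.0, clipped
to [0, 1]): both stains mark nuclei, so positive and negative nuclei are
detected by one pathway. That image is Wallis-normalized:

`out = (g − m_w) · c·s_t / (c·max(s_w, s_min) + (1−c)·s_t) + b·m_t + (1−b)·m_w`

with window 65, target mean 0.5, target SD 0.2, brightness factor b = 0.5,
contrast factor c = 0.8, clipped to [0, 1]. The window (~4–5 nucleus
diameters at the implied ~0.23 µm/px scale) is large enough to estimate
local background, small enough to track staining gradients. After Gaussian
smoothing (σ = 1 px) a fixed threshold 0.35 binarizes; the Wallis step is
what makes a fixed threshold defensible across tiles.

Touching nuclei are split by watershed on the smoothed Euclidean distance
transform with `peak_local_max` minimum peak distance 7 px (≈ one nucleus
radius). Candidate objects must pass:

| filter | default | rationale |
| --- | --- | --- |
| `min_area` | 40 px² | rejects debris below ~3.5 px radius |
| `max_area` | 5000 px² | rejects confluent clumps the watershed failed on |
| `min_roundness` | 0.30 | `4πA/P²` bound; rejects scratches and fibres |
| `min_avg_density` | 0.30 | mean normalized intensity; rejects faint texture |
| `min_boundary_contrast` | 0.02 | object mean minus 2-px ring mean; rejects flat regions |

Allred scoring: the proportion score bins the positive fraction at
(0, 1/100, 1/10, 1/3, 2/3, 1] (upper-inclusive); the intensity score is the
mean class of positive nuclei rounded half-up and clamped to 1..3; TS = PS +
IS, positive ⇔ TS ≥ 3. TS = 1 is unattainable by construction (any positive
cell forces PS ≥ 1 and IS ≥ 1). Intensity classes come from mean nuclear DAB
via cutpoints t1 = 0.15, t2 = 0.40, t3 = 0.70 (lower-inclusive), roughly
weak/moderate/strong staining in OD units; these are the parameters stage-2
calibration tunes per laboratory.

## Calibration

Stage 1 maximizes mean per-region detection agreement — the Dice-style
one-to-one match fraction `2|M| / (|A| + |D|)` under greedy nearest-centroid
matching (eligible within the annotation shape or the median annotation
radius) — by coordinate descent over the supplied detection grid (at most 3
sweeps; the objective is monotone by construction). Stage 2 exhaustively
grids the three cutpoints and maximizes quadratic weighted kappa of
algorithmic vs reference TS on categories 0..8. Both stages share
precomputed deconvolution and Wallis images, which the searched parameters
do not touch. The two stages optimize the shared objective jointly across
all regions rather than aggregating per-region optima; a single parameter
set must serve every region, and the joint objective is what the
equivalence evaluation later measures.

## Synthetic data as surrogate

`ihcquant.synth` renders nuclei as hard-edged ellipses (radius 7 ± 1 px,
eccentricity ≤ 0.15) with hematoxylin 0.6 ± 10%, per-class DAB drawn from
disjoint ranges (class 1: 0.20–0.32, class 2: 0.48–0.62, class 3:
0.78–0.92), diffuse cytoplasmic DAB 0.02, additive Gaussian sensor noise
(SD 2 of 255), and a configurable fraction of deliberately touching pairs
(centre distance 0.75 of the summed radii). Reference annotations and Total
Scores are the generator's ground truth.

Two presets emulate a validation-study layout: a calibration set of 38
annotated regions with lognormal cell counts (mean 195, clamped to
[73, 489], sampled by equal-probability strata so the sample mean is stable
at n = 38) cycling through positivity fractions 0–1; and an equivalence set
of 53 scored regions (7 negative, 46 positive) covering every attainable TS.
The equivalence preset defaults to ~500 cells per 640² region for desk
runtime; `full_scale=True` switches to ~5000-cell 2048² regions.

Passing the acceptance experiments on these sets demonstrates that the
implemented pipeline is self-consistent: it recovers, from rendered pixels
alone, the detections and scores the generator embedded, through realistic
nuisances (noise, touching nuclei, background DAB, count variation). It does
not demonstrate clinical performance — the generator shares the pipeline's
forward model, real chromatin texture, stain variation, and tissue
architecture are absent, and the reference scores are exact rather than a
human rater's.

## Numerical and statistical choices

- Measured mean DAB of a detected mask is slightly *diluted* relative to the
  generated nuclear concentration (masks overhang the hard edge by ~1 px at
  the default threshold). The class ranges sit mid-bin so dilution does not
  flip classes, and stage-2 calibration absorbs any residual shift.
- Cohen's kappa uses the large-sample SE `sqrt(p_o(1−p_o) / (n(1−p_e)²))`
  and a Wald 95% CI; the radicand is clamped at 0 against floating-point
  underflow at perfect agreement. Weighted kappa uses agreement weights
  `w_ij = 1 − (i−j)²/(k−1)²` and the Fleiss–Cohen–Everitt variance; the test
  suite verifies both against statsmodels, Spearman (average ranks,
  t-approximation p, Fisher-z CI) against scipy, and unweighted kappa
  against scikit-learn, to ~1e-12.
- Landis–Koch verbal bands use midpoint cutoffs (0.205, 0.405, 0.605, 0.805)
  so every kappa maps to exactly one label despite the gaps in the published
  band edges.
- Degenerate cases raise `DegenerateAgreementError` (chance agreement 1 with
  disagreement; zero-variance rater for Spearman) instead of returning NaN.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical tiles. Searches are exhaustive/deterministic;
  ties keep the first candidate in grid order.

## Limitations

- Single fixed stain basis; no per-slide basis estimation (adaptation is
  confined to the Wallis step and calibrated thresholds).
- Mean-DAB intensity classes ignore subnuclear staining texture.
- Greedy matching is not globally optimal (Hungarian) matching; with the
  one-to-one constraint and well-separated annotations the difference is
  negligible, but it is a bias in principle.
- The watershed split is tuned for roughly circular nuclei of similar size;
  elongated or highly variable nuclei would need per-profile retuning.
- Synthetic validation only, as discussed above; conclusions transfer to
  real slides only insofar as the forward model does.
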