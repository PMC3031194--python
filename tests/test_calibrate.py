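import numpy as np
import pytest

from ihcquant import SlideSpec, StainProfile, generate_slide
from ihcquant.calibrate import (
    CalibrationROI,
    NuclearQuantifier,
    background_dab_level,
    calibrate,
    evaluate_equivalence,
    is_suitable,
)
from ihcquant.synth import annotations_from_truth


def small_roi_set(n_rois=4, n_cells=80, seed0=100, **spec_kwargs):
    rois = []
    fracs = [0.0, 0.2, 0.5, 0.9]
    for i in range(n_rois):
        kwargs = dict(
            n_cells=n_cells, width=320, height=320,
            positive_fraction=fracs[i % len(fracs)],
            class_mix=(0.3, 0.4, 0.3),
            touching_fraction=0.1, seed=seed0 + i,
        )
        kwargs.update(spec_kwargs)
        spec = SlideSpec(**kwargs)
        img, truth = generate_slide(spec)
        rois.append(CalibrationROI(image=img, annotations=annotations_from_truth(truth),
                                   ts=truth.ts, name=f"roi_{i}"))
    return rois


#: Regions designed so that, on a coarse cutpoint grid, only the
#: generator-true cutpoints (0.15, 0.40, 0.70) reproduce every reference
#: Total Score: each recipe places one class's concentrations between the
#: true cutpoint and one wrong grid value, so that wrong value flips that
#: region's TS.
_RECOVERY_RECIPES = [
    # (positive_fraction, dab ranges by class, mix over classes 1..3)
    (0.5, {1: (0.28, 0.38), 2: (0.48, 0.54), 3: (0.78, 0.84)}, (1, 0, 0)),  # vs t2=0.25
    (0.5, {1: (0.20, 0.24), 2: (0.44, 0.52), 3: (0.78, 0.84)}, (0, 1, 0)),  # vs t2=0.55
    (0.5, {1: (0.20, 0.24), 2: (0.63, 0.68), 3: (0.78, 0.84)}, (0, 1, 0)),  # vs t3=0.60
    (0.5, {1: (0.20, 0.24), 2: (0.44, 0.52), 3: (0.74, 0.80)}, (0, 0, 1)),  # vs t3=0.85
    (0.05, {1: (0.17, 0.22), 2: (0.44, 0.52), 3: (0.78, 0.84)}, (1, 0, 0)),  # vs t1=0.25
    (0.0, {1: (0.20, 0.24), 2: (0.44, 0.52), 3: (0.78, 0.84)}, (1, 0, 0)),  # vs t1=0.05
]

RECOVERY_GRID = {
    "t1": [0.05, 0.15, 0.25],
    "t2": [0.25, 0.40, 0.55],
    "t3": [0.60, 0.70, 0.85],
}


def cutpoint_recovery_set():
    """(profile, rois) for the cutpoint-recovery experiment.  The profile
    uses a higher detection threshold so measured mean DAB stays close to
    the generated concentration (masks stay interior to the nuclei)."""
    from dataclasses import replace

    base = StainProfile.default()
    prof = base.with_detection(replace(base.detection, threshold=0.45))
    rois = []
    for i, (frac, ranges, mix) in enumerate(_RECOVERY_RECIPES):
        spec = SlideSpec(
            n_cells=100, width=320, height=320, positive_fraction=frac,
            class_mix=mix, touching_fraction=0.0, noise_sd=0.5,
            cytoplasmic_dab=0.08, dab_conc_by_class=ranges, seed=700 + i,
        )
        img, truth = generate_slide(spec)
        rois.append(CalibrationROI(image=img, annotations=annotations_from_truth(truth),
                                   ts=truth.ts, name=f"rec_{i}"))
    return prof, rois


@pytest.fixture(scope="module")
def rois():
    return small_roi_set()


class TestCalibrate:
    def test_singleton_search_space_returns_profile_unchanged(self, rois, profile):
        space = {"threshold": [profile.detection.threshold]}
        report = calibrate(rois, space, profile=profile)
        assert report.profile.detection == profile.detection

    def test_objective_never_decreases(self, rois, profile):
        space = {"threshold": [0.2, 0.35, 0.5], "min_roundness": [0.2, 0.3]}
        report = calibrate(rois, space, profile=profile)
        assert report.final_agreement >= report.initial_agreement - 1e-12
        assert all(b >= a - 1e-12 for a, b in zip(report.stage1_history,
                                                  report.stage1_history[1:]))

    def test_empty_search_space_rejected(self, rois):
        with pytest.raises(ValueError):
            calibrate(rois, {})

    def test_empty_roi_list_rejected(self):
        with pytest.raises(ValueError):
            calibrate([], {"threshold": [0.3]})

    def test_unknown_parameter_rejected(self, rois):
        with pytest.raises(ValueError, match="unknown detection parameter"):
            calibrate(rois, {"not_a_param": [1]})

    def test_cutpoint_recovery_from_grid_containing_truth(self):
        """On regions whose class concentrations straddle the wrong grid
        values, the cutpoints that generated the data uniquely maximize TS
        agreement over the grid."""
        prof, rois = cutpoint_recovery_set()
        report = calibrate(rois, {"cutpoints": RECOVERY_GRID}, profile=prof)
        cut = report.profile.cutpoints
        assert (cut.t1, cut.t2, cut.t3) == (0.15, 0.40, 0.70)
        assert report.final_weighted_kappa >= report.initial_weighted_kappa - 1e-12


class TestSuitability:
    def test_clean_tile_suitable(self, profile):
        img, _ = generate_slide(SlideSpec(n_cells=40, width=256, height=256, seed=5))
        assert is_suitable(img, profile)

    def test_diffuse_cytoplasmic_dab_flagged_unsuitable(self, profile):
        img, _ = generate_slide(
            SlideSpec(n_cells=40, width=256, height=256, seed=5, cytoplasmic_dab=0.25)
        )
        assert background_dab_level(img, profile) > profile.max_background_dab
        assert not is_suitable(img, profile)


class TestEvaluateEquivalence:
    def test_perfect_agreement_when_scores_match(self, rois, profile):
        # set the reference scores to the algorithm's own output: kappa must be 1
        quant = NuclearQuantifier(profile=profile).fit([])
        for roi in rois:
            roi.ts = quant.predict(roi.image).ts
        result = evaluate_equivalence(rois, profile)
        assert result.report.kappa == pytest.approx(1.0)
        assert result.report.weighted_kappa == pytest.approx(1.0)

    def test_unsuitable_rois_excluded(self, profile):
        good = small_roi_set(n_rois=3, n_cells=40, seed0=400)
        bad = small_roi_set(n_rois=1, n_cells=40, seed0=500, cytoplasmic_dab=0.3)
        result = evaluate_equivalence(good + bad, profile)
        assert len(result.excluded) == 1
        assert len(result.ts_pairs) == 3

    def test_all_excluded_is_error(self, profile):
        bad = small_roi_set(n_rois=2, n_cells=40, seed0=600, cytoplasmic_dab=0.3)
        with pytest.raises(ValueError, match="suitable"):
            evaluate_equivalence(bad, profile)


class TestNuclearQuantifier:
    def test_fit_predict_cycle(self, rois, profile):
        quant = NuclearQuantifier(profile=profile,
                                  search_space={"threshold": [0.3, 0.4]})
        quant.fit(rois)
        assert hasattr(quant, "profile_")
        results = quant.predict([r.image for r in rois[:2]])
        assert len(results) == 2
        assert all(0 <= r.ts <= 8 for r in results)
        agreement = quant.score(rois)
        assert 0.8 <= agreement <= 1.0

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        quant = NuclearQuantifier(seed=7)
        assert clone(quant).get_params()["seed"] == 7
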