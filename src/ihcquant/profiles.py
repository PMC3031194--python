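"""Detection profiles: the serialized parameter set applied uniformly to slides.

A profile bundles everything the pipeline needs — stain basis, Wallis
normalization, detection thresholds and intensity cutpoints — into a single
versioned JSON document, so one calibrated profile can be applied to any
ER/PR slide.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .allred import IntensityCutpoints
from .detect import DetectionParams
from .stains import StainBasis
from .wallis import WallisParams

__all__ = ["StainProfile", "load_profile", "save_profile"]

FORMAT_VERSION = "1.0"


@dataclass(frozen=True)
class StainProfile:
    """Full parameter profile for detection and scoring.

    intensity_scale : K dividing (c_H + c_DAB) before clipping to [0, 1];
        fixed per profile so detection thresholds stay comparable.
    max_background_dab : median background DAB concentration above which a
        region is flagged unsuitable for quantification (diffuse cytoplasmic
        staining).
    """

    basis: StainBasis = field(default_factory=StainBasis.h_dab)
    wallis: WallisParams = field(default_factory=WallisParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    cutpoints: IntensityCutpoints = field(default_factory=IntensityCutpoints)
    intensity_scale: float = 2.0
    max_background_dab: float = 0.10
    name: str = "default"
    version: str = FORMAT_VERSION

    @classmethod
    def default(cls) -> "StainProfile":
        return cls()

    def with_detection(self, detection: DetectionParams) -> "StainProfile":
        return replace(self, detection=detection)

    def with_cutpoints(self, cutpoints: IntensityCutpoints) -> "StainProfile":
        return replace(self, cutpoints=cutpoints)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "name": self.name,
            "intensity_scale": self.intensity_scale,
            "max_background_dab": self.max_background_dab,
            "stain_basis": {
                "names": list(self.basis.names),
                "vectors": np.asarray(self.basis.vectors).tolist(),
            },
            "wallis": asdict(self.wallis),
            "detection": asdict(self.detection),
            "cutpoints": asdict(self.cutpoints),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StainProfile":
        version = data.get("version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported profile version {version!r} (expected {FORMAT_VERSION})"
            )
        known = {
            "version",
            "name",
            "intensity_scale",
            "max_background_dab",
            "stain_basis",
            "wallis",
            "detection",
            "cutpoints",
        }
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown profile fields {sorted(unknown)} "
                f"(profile format version {FORMAT_VERSION})"
            )
        basis = StainBasis(
            vectors=np.asarray(data["stain_basis"]["vectors"], dtype=float),
            names=tuple(data["stain_basis"]["names"]),
        )
        return cls(
            basis=basis,
            wallis=WallisParams(**data["wallis"]),
            detection=DetectionParams(**data["detection"]),
            cutpoints=IntensityCutpoints(**data["cutpoints"]),
            intensity_scale=float(data["intensity_scale"]),
            max_background_dab=float(data["max_background_dab"]),
            name=data.get("name", "default"),
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "StainProfile":
        """Load a profile from a JSON string or a file path."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            with open(text, encoding="utf-8") as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    def sha256(self) -> str:
        """Content hash of the canonical JSON form, for run logging."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def save_profile(profile: StainProfile, path) -> None:
    profile.to_json(path)


def load_profile(path) -> StainProfile:
    return StainProfile.from_json(path)
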