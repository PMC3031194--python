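"""Optical-density conversion and colour deconvolution for H-DAB brightfield images.

Brightfield IHC images mix stains multiplicatively in transmitted light but
linearly in optical density (Beer-Lambert).  Converting RGB intensities to OD
and inverting the 3x3 stain-vector matrix yields one concentration map per
stain; nuclear scoring then reads the DAB (brown chromogen) map only, while
detection uses hematoxylin + DAB together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "StainBasis",
    "ConcentrationMaps",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "dab_density_map",
    "StainDeconvolver",
]

#: Ruifrok-Johnston hematoxylin and DAB optical-density vectors (R, G, B).
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DAB_OD = (0.269, 0.568, 0.778)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainBasis:
    """Unit-norm OD vectors of the stains, one row per stain.

    The third (residual) vector completes the basis so the 3x3 system is
    invertible even for two-stain protocols.
    """

    vectors: np.ndarray
    names: tuple = ("hematoxylin", "DAB", "residual")

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"stain basis must be 3x3, got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError(f"stain vectors must be unit norm, norms={norms}")
        if len(self.names) != 3:
            raise ValueError("need exactly three stain names")
        cond = np.linalg.cond(v)
        if not np.isfinite(cond) or cond > 1e12:
            raise ValueError(
                "stain basis is singular or ill-conditioned; "
                f"vectors={v.tolist()} (condition number {cond:.3g})"
            )
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "names", tuple(self.names))

    @classmethod
    def h_dab(cls) -> "StainBasis":
        """Standard H-DAB basis; residual = normalized cross product."""
        h = _unit(HEMATOXYLIN_OD)
        d = _unit(DAB_OD)
        r = _unit(np.cross(h, d))
        return cls(vectors=np.stack([h, d, r]), names=("hematoxylin", "DAB", "residual"))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 mixing matrix M with stain vectors as columns (od = M @ c)."""
        return self.vectors.T

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(
                f"no stain named {name!r} in basis (have {self.names})"
            ) from None


@dataclass
class ConcentrationMaps:
    """Per-stain concentration maps, shape (n_stains, H, W), clipped >= 0."""

    maps: np.ndarray
    names: tuple

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[self.names.index(name)]


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must be at least 1x1")
    return img


def rgb_to_od(img: np.ndarray, i0: float | None = None) -> np.ndarray:
    """Convert an 8-bit RGB image to optical density.

    od = -log10(max(I, 1) / i0) per channel; intensities are floored at 1 so
    saturated-black pixels stay finite.  ``i0`` defaults to 255 for 8-bit
    input; non-8-bit input requires an explicit reference white.
    """
    img = _validate_rgb(img)
    if i0 is None:
        if not np.issubdtype(img.dtype, np.integer) or img.max(initial=0) > 255 or img.min(initial=0) < 0:
            raise ValueError(
                "input is not 8-bit [0,255]; pass an explicit reference white i0"
            )
        i0 = 255.0
    if i0 <= 0:
        raise ValueError(f"reference white i0 must be > 0, got {i0}")
    intensity = np.maximum(img.astype(float), 1.0)
    return -np.log10(intensity / float(i0))


def od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (render OD back to 8-bit transmitted light)."""
    rgb = np.power(10.0, -np.asarray(od, dtype=float)) * i0
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, basis: StainBasis) -> ConcentrationMaps:
    """Invert the linear stain mixing model per pixel.

    Solves od = M @ c for each pixel, M being the basis matrix; negative
    components (noise outside the stain simplex) are clipped to 0.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError(f"expected HxWx3 OD array, got shape {od.shape}")
    inv = np.linalg.inv(basis.matrix)  # basis validated invertible on construction
    conc = od @ inv.T  # (H, W, 3) in basis order
    conc = np.clip(conc, 0.0, None)
    return ConcentrationMaps(maps=np.moveaxis(conc, -1, 0), names=basis.names)


def dab_density_map(img: np.ndarray, profile) -> np.ndarray:
    """DAB concentration map of an RGB image: rgb_to_od then deconvolve.

    ``profile`` may be a :class:`StainBasis` or any object with a ``basis``
    attribute (a detection profile).
    """
    basis = profile if isinstance(profile, StainBasis) else profile.basis
    idx = basis.index("DAB")
    maps = deconvolve(rgb_to_od(img), basis)
    return maps.maps[idx]


class StainDeconvolver(TransformerMixin, BaseEstimator):
    """Transformer from RGB images to per-stain concentration maps.

    Parameters
    ----------
    basis : StainBasis or None
        Stain vectors; defaults to the Ruifrok-Johnston H-DAB basis.
    i0 : float or None
        Reference white; None means 255 for 8-bit input.
    """

    def __init__(self, basis: StainBasis | None = None, i0: float | None = None):
        self.basis = basis
        self.i0 = i0

    def fit(self, X=None, y=None):
        self.basis_ = self.basis if self.basis is not None else StainBasis.h_dab()
        return self

    def transform(self, X):
        """Deconvolve one image (HxWx3) or a list of images."""
        if not hasattr(self, "basis_"):
            self.fit()
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return deconvolve(rgb_to_od(X, self.i0), self.basis_)
        return [deconvolve(rgb_to_od(img, self.i0), self.basis_) for img in X]
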