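"""Wallis local mean/variance normalization.

The Wallis filter pushes every local neighbourhood of a grayscale image toward
target first and second moments, compensating slowly varying illumination and
contrast deviations before nucleus detection.  The blended form used here is

    out = (g - m_w) * (c * s_t) / (c * max(s_w, s_min) + (1 - c) * s_t)
          + b * m_t + (1 - b) * m_w

with local window mean m_w and std s_w, target mean m_t and std s_t,
brightness blend b and contrast gain limit c, finally clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["WallisParams", "wallis_filter", "WallisNormalizer"]


@dataclass(frozen=True)
class WallisParams:
    """Wallis filter parameters.

    window : odd pixel span of the local neighbourhood
    target_mean : m_t in [0, 1]
    target_std : s_t > 0
    brightness_blend : b in [0, 1]; 1 forces local mean fully to m_t
    contrast_gain_limit : c in (0, 1]; < 1 damps the gain in flat regions
    std_floor : s_min > 0, guards division where the window is constant
    """

    window: int = 65
    target_mean: float = 0.5
    target_std: float = 0.2
    brightness_blend: float = 0.5
    contrast_gain_limit: float = 0.8
    std_floor: float = 1e-3

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if not 0.0 <= self.target_mean <= 1.0:
            raise ValueError("target_mean must be in [0, 1]")
        if self.target_std <= 0:
            raise ValueError("target_std must be > 0")
        if not 0.0 <= self.brightness_blend <= 1.0:
            raise ValueError("brightness_blend must be in [0, 1]")
        if not 0.0 < self.contrast_gain_limit <= 1.0:
            raise ValueError("contrast_gain_limit must be in (0, 1]")
        if self.std_floor <= 0:
            raise ValueError("std_floor must be > 0")


def wallis_filter(img: np.ndarray, params: WallisParams | None = None) -> np.ndarray:
    """Apply the Wallis filter to a grayscale image in [0, 1].

    Local statistics use uniform box windows with edge-replication padding,
    so the filter is separable and deterministic.  Output is clipped to [0, 1].
    """
    if params is None:
        params = WallisParams()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if min(img.shape) < params.window:
        raise ValueError(
            f"image {img.shape} is smaller than the Wallis window "
            f"({params.window}); use a smaller window"
        )
    w = params.window
    m_w = uniform_filter(img, size=w, mode="nearest")
    m2 = uniform_filter(img * img, size=w, mode="nearest")
    s_w = np.sqrt(np.clip(m2 - m_w * m_w, 0.0, None))

    c = params.contrast_gain_limit
    s_t = params.target_std
    b = params.brightness_blend
    gain = (c * s_t) / (c * np.maximum(s_w, params.std_floor) + (1.0 - c) * s_t)
    out = (img - m_w) * gain + b * params.target_mean + (1.0 - b) * m_w
    return np.clip(out, 0.0, 1.0)


class WallisNormalizer(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`wallis_filter`."""

    def __init__(
        self,
        window: int = 65,
        target_mean: float = 0.5,
        target_std: float = 0.2,
        brightness_blend: float = 0.5,
        contrast_gain_limit: float = 0.8,
        std_floor: float = 1e-3,
    ):
        self.window = window
        self.target_mean = target_mean
        self.target_std = target_std
        self.brightness_blend = brightness_blend
        self.contrast_gain_limit = contrast_gain_limit
        self.std_floor = std_floor

    def _params(self) -> WallisParams:
        return WallisParams(
            window=self.window,
            target_mean=self.target_mean,
            target_std=self.target_std,
            brightness_blend=self.brightness_blend,
            contrast_gain_limit=self.contrast_gain_limit,
            std_floor=self.std_floor,
        )

    def fit(self, X=None, y=None):
        self.params_ = self._params()
        return self

    def transform(self, X):
        if not hasattr(self, "params_"):
            self.fit()
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return wallis_filter(X, self.params_)
        return [wallis_filter(img, self.params_) for img in X]
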