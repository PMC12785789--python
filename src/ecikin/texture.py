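"""Gray-level co-occurrence texture metrics for toasted stave surfaces.

Toasting chars the stave surface unevenly: cracks, char speckle and
colour variation grow with treatment intensity.  This module quantifies
that heterogeneity with the standard GLCM protocol: images quantized to
256 gray levels, co-occurrence matrices at four angles (0°, 45°, 90°,
135°) with a 1-pixel offset, symmetrized and normalized, and five scalar
metrics — entropy (bits, base-2 log), homogeneity Σ P/(1+|i−j|), energy
Σ P², correlation Σ (i−μi)(j−μj)P/(σiσj) and contrast Σ (i−j)²P —
reported as the average over the four directions.  A local-standard-
deviation heterogeneity map complements the global metrics.

Angle → displacement convention (row, col), 0° horizontal:
0° → (0, +1), 45° → (−1, +1), 90° → (−1, 0), 135° → (−1, −1).
Correlation is undefined (NaN, with a warning) for constant images where
σi·σj = 0; undefined values propagate through direction averaging rather
than silently biasing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.feature import graycomatrix

__all__ = [
    "GLCMatrix",
    "TextureMetrics",
    "ANGLES",
    "quantize",
    "compute_glcm",
    "texture_metrics",
    "direction_average",
    "texture_profile",
    "heterogeneity_map",
]

ANGLES: tuple[int, ...] = (0, 45, 90, 135)

# skimage's angle parameter uses the opposite row sense for the diagonal
# and vertical offsets; with symmetric matrices the displacement sets
# coincide after swapping the 45°/135° labels.
_SKIMAGE_ANGLE = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}
# whether skimage's raw (unsymmetrized) counts are the transpose of ours
_NEEDS_TRANSPOSE = {0: False, 45: True, 90: True, 135: True}


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized 256×256 co-occurrence probability matrix."""

    probabilities: np.ndarray
    angle: int
    offset: int = 1
    symmetrized: bool = True

    def __post_init__(self) -> None:
        P = self.probabilities
        if P.shape != (256, 256):
            raise ValueError("GLCM must be 256×256")
        if (P < 0).any() or abs(P.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM entries must be non-negative and sum to 1")


@dataclass(frozen=True)
class TextureMetrics:
    """Scalar texture descriptors of one GLCM (or a direction average)."""

    contrast: float
    entropy: float       # bits
    homogeneity: float
    energy: float
    correlation: float   # NaN when undefined (constant image)


def quantize(image: np.ndarray) -> np.ndarray:
    """Map a single-channel image onto 256 integer gray levels.

    8-bit input passes through unchanged.  Higher-depth unsigned-integer
    input is linearly mapped from [0, dtype max] to [0, 255]; float input
    is interpreted on [0, 1].  Rounding is round-half-even.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(
            "expected a single-channel (2-D) image; convert to grayscale first"
        )
    if image.dtype == np.uint8:
        return image
    if np.issubdtype(image.dtype, np.unsignedinteger):
        top = np.iinfo(image.dtype).max
        return np.rint(image.astype(float) * 255.0 / top).astype(np.uint8)
    if np.issubdtype(image.dtype, np.floating):
        if image.min() < 0 or image.max() > 1:
            raise ValueError("float images must lie in [0, 1]")
        return np.rint(image * 255.0).astype(np.uint8)
    raise ValueError(f"unsupported image dtype {image.dtype}")


def compute_glcm(
    image: np.ndarray,
    angle: int,
    offset: int = 1,
    symmetric: bool = True,
) -> GLCMatrix:
    """Co-occurrence probabilities of a quantized image at one angle.

    Counts co-occurring gray-level pairs at the 1-pixel displacement for
    the given angle, optionally symmetrizes by adding the transpose, and
    normalizes to probabilities summing to 1.
    """
    if angle not in ANGLES:
        raise ValueError(f"angle must be one of {ANGLES}")
    image = np.asarray(image)
    if image.ndim != 2 or image.size < 2:
        raise ValueError("image must be 2-D with at least 2 pixels")
    if image.dtype != np.uint8:
        raise ValueError("image must be quantized to uint8 first (see quantize)")
    if offset >= max(image.shape):
        raise ValueError("offset exceeds image extent")
    counts = graycomatrix(
        image, distances=[offset], angles=[_SKIMAGE_ANGLE[angle]],
        levels=256, symmetric=symmetric, normed=False,
    )[:, :, 0, 0].astype(float)
    if not symmetric and _NEEDS_TRANSPOSE[angle]:
        counts = counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("image too small for the requested offset/angle")
    return GLCMatrix(
        probabilities=counts / total, angle=angle, offset=offset,
        symmetrized=symmetric,
    )


_IDX = np.arange(256, dtype=float)


def texture_metrics(g: GLCMatrix) -> TextureMetrics:
    """Evaluate the five scalar metrics on one normalized GLCM.

    Entropy uses the base-2 logarithm with the 0·log 0 ≡ 0 convention.
    Correlation is NaN (with a warning) when either marginal standard
    deviation vanishes.
    """
    P = g.probabilities
    i = _IDX[:, None]
    j = _IDX[None, :]

    nz = P > 0
    entropy = float(-np.sum(P[nz] * np.log2(P[nz])))
    homogeneity = float(np.sum(P / (1.0 + np.abs(i - j))))
    energy = float(np.sum(P * P))
    contrast = float(np.sum((i - j) ** 2 * P))

    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(pi @ _IDX)
    mu_j = float(pj @ _IDX)
    var_i = float(pi @ (_IDX - mu_i) ** 2)
    var_j = float(pj @ (_IDX - mu_j) ** 2)
    if var_i <= 0 or var_j <= 0:
        warnings.warn(
            "correlation undefined for constant image (zero marginal variance)",
            RuntimeWarning, stacklevel=2,
        )
        correlation = float("nan")
    else:
        correlation = float(
            np.sum((i - mu_i) * (j - mu_j) * P) / np.sqrt(var_i * var_j)
        )
    return TextureMetrics(contrast, entropy, homogeneity, energy, correlation)


def direction_average(metrics: Sequence[TextureMetrics]) -> TextureMetrics:
    """Arithmetic mean of the metrics over the four directions.

    An undefined (NaN) correlation in any direction leaves the averaged
    correlation undefined.
    """
    if len(metrics) != 4:
        raise ValueError(f"expected metrics for all 4 directions, got {len(metrics)}")
    vals = {
        f.name: float(np.mean([getattr(m, f.name) for m in metrics]))
        for f in fields(TextureMetrics)
    }
    return TextureMetrics(**vals)


def texture_profile(image: np.ndarray, offset: int = 1) -> TextureMetrics:
    """Quantize, compute all four directional GLCMs and return their metric average."""
    q = quantize(image)
    return direction_average(
        [texture_metrics(compute_glcm(q, a, offset=offset)) for a in ANGLES]
    )


def heterogeneity_map(image: np.ndarray, window: int = 15) -> np.ndarray:
    """Per-pixel local standard deviation over a square window (reflect padding).

    Highlights char speckle, cracks and grain boundaries; the window must
    be odd so it is centred on each pixel.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel (2-D) image")
    if window > min(image.shape):
        raise ValueError("window exceeds image size")
    m = uniform_filter(image, size=window, mode="reflect")
    m2 = uniform_filter(image * image, size=window, mode="reflect")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))
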