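"""Core deterministic image operators.

The pipeline depends on four primitives: Gaussian blur, full-range
rescaling, maximum-intensity projection, and two automatic threshold
selectors operating on 256-bin gray-level histograms — Huang's
minimum-fuzziness criterion (used for islet-region masks) and the
Li–Lee minimum cross-entropy criterion (used to bound the cell-growth
region during seeded propagation).

Conventions used throughout the package:

* intensities live on ``[0, 1]`` internally; 8-bit data is the native
  scale of the threshold selectors, and float images are linearly
  binned to 256 levels over their observed range first;
* foreground means *strictly greater than* the threshold;
* ties between equally good thresholds are broken toward the smallest
  candidate (selectors scan ascending);
* natural logarithms in both criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has fewer than two occupied gray levels."""


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of an automatic threshold selection.

    ``threshold`` is a gray level in ``[g_min, g_max)`` of the occupied
    range; foreground is every pixel strictly above it.
    ``criterion_curve`` holds the criterion value at every candidate
    threshold (index = gray level), NaN where no candidate exists; it is
    retained so the selection can be audited against an exhaustive scan.
    """

    threshold: int
    criterion_value: float
    criterion_curve: np.ndarray = field(repr=False, default=None)


def histogram256(img: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram of an image.

    Integer images must already fit in [0, 255]. Float images are
    linearly binned over their observed [min, max] range (the constant
    image maps to a single occupied bin).
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(img.dtype, np.integer):
        if img.min() < 0 or img.max() > 255:
            raise ValueError("integer image values outside [0, 255]")
        levels = img.astype(np.intp)
    else:
        lo, hi = float(img.min()), float(img.max())
        if hi > lo:
            levels = np.clip(
                np.floor((img - lo) / (hi - lo) * 256).astype(np.intp), 0, 255
            )
        else:
            levels = np.zeros(img.shape, dtype=np.intp)
    return np.bincount(levels.ravel(), minlength=256)


def _occupied_range(counts: np.ndarray) -> tuple[int, int]:
    counts = np.asarray(counts)
    if counts.shape != (256,) or (counts < 0).any() or counts.sum() == 0:
        raise ValueError("histogram must be 256 non-negative counts with total > 0")
    occ = np.nonzero(counts)[0]
    if occ.size < 2:
        raise DegenerateHistogramError(
            "histogram has a single occupied gray level; no threshold separates it"
        )
    return int(occ[0]), int(occ[-1])


def huang_threshold(counts: np.ndarray) -> ThresholdResult:
    """Huang–Wang minimum-fuzziness threshold of a 256-bin histogram.

    For each candidate threshold ``t`` (``g_min ≤ t < g_max``), pixels are
    split into the classes ``≤ t`` and ``> t`` with mean gray levels
    ``m0, m1``.  Membership of gray level ``g`` in its class is
    ``mu = 1 / (1 + |g - m_class| / C)`` with ``C = g_max - g_min``, and the
    fuzziness is the Shannon entropy ``S(mu) = -mu ln mu - (1-mu) ln(1-mu)``
    summed over the histogram.  The threshold minimising total fuzziness is
    returned; ties go to the smallest ``t``.
    """
    counts = np.asarray(counts, dtype=np.float64)
    g_min, g_max = _occupied_range(counts)
    g = np.arange(256, dtype=np.float64)
    c = float(g_max - g_min)

    csum = np.cumsum(counts)
    cmoment = np.cumsum(counts * g)
    total, moment = csum[-1], cmoment[-1]

    curve = np.full(256, np.nan)
    for t in range(g_min, g_max):
        n0 = csum[t]
        n1 = total - n0
        if n0 == 0 or n1 == 0:  # only possible at unoccupied edges
            continue
        m0 = cmoment[t] / n0
        m1 = (moment - cmoment[t]) / n1
        mu = np.empty(256)
        mu[: t + 1] = 1.0 / (1.0 + np.abs(g[: t + 1] - m0) / c)
        mu[t + 1 :] = 1.0 / (1.0 + np.abs(g[t + 1 :] - m1) / c)
        curve[t] = float(np.sum(counts * _entropy(mu)))

    return _argmin_result(curve)


def min_cross_entropy_threshold(counts: np.ndarray) -> ThresholdResult:
    """Li–Lee minimum cross-entropy threshold of a 256-bin histogram.

    Gray levels are shifted by +1 so level 0 contributes nothing ill-defined
    (``g log g → 0``).  For candidate ``t`` the criterion is
    ``-M0(t) ln mu0(t) - M1(t) ln mu1(t)`` where ``M0, M1`` are the
    class gray-level masses and ``mu0, mu1`` the class means (shifted
    scale); the additive ``sum g h(g) ln g`` term is constant in ``t`` and
    omitted.  Ties go to the smallest ``t``.
    """
    counts = np.asarray(counts, dtype=np.float64)
    g_min, g_max = _occupied_range(counts)
    g = np.arange(1, 257, dtype=np.float64)  # shift +1: log of 0 never taken

    csum = np.cumsum(counts)
    cmass = np.cumsum(counts * g)
    total, mass = csum[-1], cmass[-1]

    curve = np.full(256, np.nan)
    for t in range(g_min, g_max):
        n0 = csum[t]
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        m0 = cmass[t]
        m1 = mass - m0
        mu0 = m0 / n0
        mu1 = m1 / n1
        curve[t] = float(-m0 * np.log(mu0) - m1 * np.log(mu1))

    return _argmin_result(curve)


def _entropy(mu: np.ndarray) -> np.ndarray:
    """Binary Shannon entropy with the S(0)=S(1)=0 convention."""
    mu = np.clip(mu, 0.0, 1.0)
    out = np.zeros_like(mu)
    inner = (mu > 0) & (mu < 1)
    m = mu[inner]
    out[inner] = -m * np.log(m) - (1 - m) * np.log(1 - m)
    return out


def _argmin_result(curve: np.ndarray) -> ThresholdResult:
    valid = ~np.isnan(curve)
    if not valid.any():
        raise DegenerateHistogramError("no candidate thresholds")
    t = int(np.nanargmin(curve))  # nanargmin returns the first minimum: smallest t
    return ThresholdResult(threshold=t, criterion_value=float(curve[t]), criterion_curve=curve)


def threshold_image(img: np.ndarray, method: str = "huang") -> float:
    """Select a threshold for an image, returned on the image's own scale.

    8-bit images get an integer gray-level threshold. Float images are
    binned to 256 levels over their observed range; the returned value is
    the upper edge of the selected bin, so ``img > threshold`` reproduces
    the binned foreground.
    """
    counts = histogram256(img)
    selector = {"huang": huang_threshold, "li": min_cross_entropy_threshold}[method]
    t = selector(counts).threshold
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        return float(t)
    lo, hi = float(img.min()), float(img.max())
    return lo + (t + 1) / 256.0 * (hi - lo)


def gaussian_blur(img: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian blur with reflecting boundary; sigma 0 is the identity."""
    if sigma_px < 0:
        raise ValueError("sigma must be non-negative")
    img = np.asarray(img, dtype=np.float64)
    if sigma_px == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma=sigma_px, mode="reflect")


def rescale_full_range(img: np.ndarray) -> np.ndarray:
    """Affine rescale sending observed min→0 and max→1.

    A constant image carries no contrast to stretch; it maps to all
    zeros with a warning.
    """
    img = np.asarray(img, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn("constant image rescaled to all zeros", stacklevel=2)
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def max_projection(planes: list[np.ndarray]) -> np.ndarray:
    """Pixelwise maximum over same-shaped planes."""
    if len(planes) == 0:
        raise ValueError("need at least one plane")
    stack = np.stack([np.asarray(p, dtype=np.float64) for p in planes])
    return stack.max(axis=0)


def to_8bit(img: np.ndarray) -> np.ndarray:
    """Export a [0,1] float plane as 8-bit: ×255, round half-up, clip."""
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    return np.floor(img * 255.0 + 0.5).astype(np.uint8)
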