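"""Three-stage segmentation: islet region, nuclei, cell boundaries.

1. **Islet region** — the 8-bit islet-probability map has a fixed offset
   subtracted (default 40), is Gaussian-blurred (default sigma 20 px) and
   thresholded with Huang's minimum-fuzziness criterion; foreground is the
   islet mask.
2. **Nuclei** — the nuclear channel, masked to the islet, is converted to
   the 8-bit scale, blurred (default sigma 9 px) and searched for local
   maxima above a normalized peak threshold (default 0.7); greedy
   non-maximum suppression removes detections whose disk overlap (IoU)
   with a better-scoring one exceeds the overlap threshold (default 0.8).
   Detected nuclei are painted as non-overlapping disks onto a blank label
   image, which seeds the next stage.
3. **Cell boundaries** — the three hormone channels are rescaled to full
   range and max-projected into a guide image; seeds grow over the guide
   by minimum-cost-path propagation, where a step between neighboring
   pixels costs sqrt((I(p)-I(q))^2 + lambda*|p-q|^2), so boundaries settle
   along intensity ridges while the regularisation term lambda (default
   0.25) keeps territories compact.  Growth is confined to pixels above a
   minimum-cross-entropy threshold of the smoothed guide.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max

from .imops import (
    DegenerateHistogramError,
    gaussian_blur,
    histogram256,
    huang_threshold,
    max_projection,
    min_cross_entropy_threshold,
    rescale_full_range,
)


@dataclass(frozen=True)
class IsletParams:
    """Islet-region segmentation: offset subtraction and blur before Huang."""

    offset: int = 40
    blur_sigma_px: float = 20.0

    def __post_init__(self):
        if not (0 <= self.offset <= 255):
            raise ValueError("offset must be in [0, 255]")
        if self.blur_sigma_px < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class NucleiParams:
    """Nucleus detection: blur, peak threshold, NMS overlap, radius bounds."""

    blur_sigma_px: float = 9.0
    peak_threshold: float = 0.7
    overlap_threshold: float = 0.8
    min_radius_px: float = 4.0
    max_radius_px: float = 14.0

    def __post_init__(self):
        if not (0 < self.peak_threshold < 1) or not (0 < self.overlap_threshold < 1):
            raise ValueError("peak and overlap thresholds must be in (0, 1)")
        if not (0 < self.min_radius_px < self.max_radius_px):
            raise ValueError("need 0 < min_radius_px < max_radius_px")


@dataclass(frozen=True)
class NucleusSet:
    """Detections after suppression: (row, col, radius, score) per nucleus."""

    centroids: np.ndarray  # (n, 2) float
    radii: np.ndarray  # (n,)
    scores: np.ndarray  # (n,) in (0, 1]
    frame_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class PropagationParams:
    """Seeded propagation parameters.

    ``regularization_lambda`` weights squared spatial distance against
    squared intensity difference in the step cost; ``smoothing_sigma_px``
    blurs the guide before thresholding and cost evaluation;
    ``threshold_correction`` scales the automatic growth-region threshold.
    """

    regularization_lambda: float = 0.25
    smoothing_sigma_px: float = 1.0
    threshold_correction: float = 1.0
    connectivity: int = 8

    def __post_init__(self):
        if self.regularization_lambda < 0:
            raise ValueError("lambda must be >= 0")
        if self.threshold_correction <= 0:
            raise ValueError("threshold correction must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def segment_islet(prob_map: np.ndarray, params: IsletParams = IsletParams()) -> np.ndarray:
    """Binary islet mask from an 8-bit probability map.

    clamp(map − offset, ≥0) → Gaussian blur → Huang threshold → foreground.
    Fields without islets are legitimate, so a degenerate (single-level)
    post-blur histogram yields an empty mask with a warning, not an error.
    """
    prob_map = np.asarray(prob_map)
    if not np.issubdtype(prob_map.dtype, np.integer) or prob_map.min() < 0 or prob_map.max() > 255:
        raise ValueError("probability map must be 8-bit (integer values in [0, 255])")
    work = np.clip(prob_map.astype(np.float64) - params.offset, 0.0, None)
    blurred = gaussian_blur(work, params.blur_sigma_px)
    blurred8 = np.floor(blurred + 0.5).astype(np.int32)
    try:
        t = huang_threshold(histogram256(blurred8)).threshold
    except DegenerateHistogramError:
        # constant map: all islet if above the offset floor, else no islet
        if blurred8.flat[0] > 0:
            return np.ones(prob_map.shape, dtype=bool)
        warnings.warn("degenerate probability map; returning empty islet mask", stacklevel=2)
        return np.zeros(prob_map.shape, dtype=bool)
    return blurred8 > t


def mask_channel(img: np.ndarray, islet_mask: np.ndarray) -> np.ndarray:
    """Zero every pixel outside the islet mask, keep values inside."""
    img = np.asarray(img, dtype=np.float64)
    if img.shape != islet_mask.shape:
        raise ValueError("image and mask shapes differ")
    return np.where(islet_mask, img, 0.0)


def _disk_iou(c1, r1, c2, r2) -> float:
    """Intersection-over-union of two disks (analytic lens area)."""
    d = float(np.hypot(c1[0] - c2[0], c1[1] - c2[1]))
    a1, a2 = np.pi * r1**2, np.pi * r2**2
    if d >= r1 + r2:
        inter = 0.0
    elif d <= abs(r1 - r2):
        inter = min(a1, a2)
    else:
        alpha = np.arccos(np.clip((d**2 + r1**2 - r2**2) / (2 * d * r1), -1, 1))
        beta = np.arccos(np.clip((d**2 + r2**2 - r1**2) / (2 * d * r2), -1, 1))
        inter = r1**2 * (alpha - np.sin(2 * alpha) / 2) + r2**2 * (beta - np.sin(2 * beta) / 2)
    union = a1 + a2 - inter
    return inter / union if union > 0 else 1.0


def detect_nuclei(nuclear_img: np.ndarray, params: NucleiParams = NucleiParams()) -> NucleusSet:
    """Detect nuclei as suppressed local maxima of the blurred nuclear channel.

    The image is brought to the 8-bit scale, blurred, and local maxima with
    normalized height >= ``peak_threshold`` become candidates.  Each gets a
    radius from the distance to half-maximum along the four axis directions
    (clipped to the configured bounds) and a score equal to its normalized
    height.  Greedy NMS in descending score (ties toward smaller (row, col))
    drops any candidate whose disk IoU with a kept one exceeds
    ``overlap_threshold``.
    """
    img = np.asarray(nuclear_img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("nuclear image must be 2D")
    shape = img.shape
    if img.max() == img.min():
        return NucleusSet(np.empty((0, 2)), np.empty(0), np.empty(0), shape)

    scaled = rescale_full_range(img) * 255.0
    blurred = gaussian_blur(scaled, params.blur_sigma_px)
    peak_max = float(blurred.max())
    if peak_max <= 0:
        return NucleusSet(np.empty((0, 2)), np.empty(0), np.empty(0), shape)

    coords = peak_local_max(
        blurred,
        min_distance=max(1, int(round(params.min_radius_px))),
        threshold_abs=params.peak_threshold * peak_max,
        exclude_border=False,
    )
    if len(coords) == 0:
        return NucleusSet(np.empty((0, 2)), np.empty(0), np.empty(0), shape)

    cands = []
    for r, c in coords:
        height = blurred[r, c]
        score = height / peak_max
        radius = _half_max_radius(blurred, (r, c), params)
        cands.append((float(score), int(r), int(c), float(radius)))
    # descending score; ties toward smaller (row, col)
    cands.sort(key=lambda x: (-x[0], x[1], x[2]))

    kept = []
    for score, r, c, rad in cands:
        if all(_disk_iou((r, c), rad, (kr, kc), krad) <= params.overlap_threshold
               for _, kr, kc, krad in kept):
            kept.append((score, r, c, rad))

    return NucleusSet(
        centroids=np.array([(r, c) for _, r, c, _ in kept], dtype=float),
        radii=np.array([rad for _, _, _, rad in kept]),
        scores=np.array([s for s, _, _, _ in kept]),
        frame_shape=shape,
    )


def _half_max_radius(blurred: np.ndarray, peak: tuple[int, int], params: NucleiParams) -> float:
    """Mean distance from the peak to half its height along the 4 axes."""
    r0, c0 = peak
    half = blurred[r0, c0] / 2.0
    limit = int(np.ceil(params.max_radius_px)) + 2
    dists = []
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        d = limit
        for step in range(1, limit + 1):
            r, c = r0 + dr * step, c0 + dc * step
            if not (0 <= r < blurred.shape[0] and 0 <= c < blurred.shape[1]):
                d = step
                break
            if blurred[r, c] < half:
                d = step
                break
        dists.append(d)
    return float(np.clip(np.mean(dists), params.min_radius_px, params.max_radius_px))


def paint_labels(nuclei: NucleusSet, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterize detections as disks onto a blank label image.

    Disks are painted in descending score order and never overwrite an
    already-labeled pixel, so labeled regions are disjoint even when the
    underlying disks overlap.  Label ids run 1..n in painting order.
    """
    shape = shape or nuclei.frame_shape
    labels = np.zeros(shape, dtype=np.int32)
    order = np.lexsort((nuclei.centroids[:, 1] if len(nuclei) else np.empty(0),
                        nuclei.centroids[:, 0] if len(nuclei) else np.empty(0),
                        -nuclei.scores))
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for lab, i in enumerate(order, start=1):
        r, c = nuclei.centroids[i]
        disk = (rr - r) ** 2 + (cc - c) ** 2 <= nuclei.radii[i] ** 2
        labels[disk & (labels == 0)] = lab
    return labels


def make_guide(channels: dict) -> np.ndarray:
    """Guide image: rescaled hormone channels combined by max projection."""
    planes = []
    for ch in ("insulin", "glucagon", "igfbp7"):
        if ch not in channels:
            raise ValueError(f"missing channel {ch!r}")
        planes.append(rescale_full_range(channels[ch]))
    return max_projection(planes)


def propagate_cells(
    seeds: np.ndarray, guide: np.ndarray, params: PropagationParams = PropagationParams()
) -> np.ndarray:
    """Grow seed labels over the guide by minimum-cost-path propagation.

    The guide is smoothed, and the growth region is the set of pixels whose
    smoothed value exceeds ``threshold_correction`` times the minimum
    cross-entropy threshold of the smoothed guide (a constant guide carries
    no separating information, so the whole frame grows), united with the
    seed pixels.  Each growth pixel takes the label of the seed reachable at
    minimum accumulated step cost sqrt((I(p)-I(q))^2 + lambda*d(p,q)^2);
    cost ties go to the smaller label id.  Seed pixels keep their labels.
    """
    seeds = np.asarray(seeds)
    guide = np.asarray(guide, dtype=np.float64)
    if seeds.shape != guide.shape:
        raise ValueError("seeds and guide shapes differ")
    if not (seeds > 0).any():
        raise ValueError("propagation needs at least one seed")

    smoothed = gaussian_blur(guide, params.smoothing_sigma_px)
    growth = _growth_region(smoothed, params.threshold_correction) | (seeds > 0)

    return _dijkstra_assign(seeds, smoothed, growth, params)


def _growth_region(smoothed: np.ndarray, correction: float) -> np.ndarray:
    from .imops import threshold_image

    try:
        thr = correction * threshold_image(smoothed, method="li")
    except DegenerateHistogramError:
        return np.ones(smoothed.shape, dtype=bool)
    return smoothed > thr


_STEPS8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_STEPS4 = ((-1, 0), (0, -1), (0, 1), (1, 0))


# Accumulated path costs are snapped to this grid so that mathematically
# tied paths (same multiset of step costs, different summation order)
# compare exactly equal and the smaller-label tie rule applies
# deterministically. Real cost differences in images are orders of
# magnitude larger.
_COST_QUANTUM = 1e-7


def _dijkstra_assign(
    seeds: np.ndarray, intensity: np.ndarray, growth: np.ndarray, params: PropagationParams
) -> np.ndarray:
    """Multi-source Dijkstra on the step-cost graph, flat-array hot loop.

    Heap entries are (cost, label, index); among equal costs the smaller
    label pops — and therefore settles — first, which implements the
    smaller-label tie rule, including along chains of zero-cost steps.
    """
    n_rows, n_cols = seeds.shape
    n = n_rows * n_cols
    lam = params.regularization_lambda
    steps = _STEPS8 if params.connectivity == 8 else _STEPS4

    offsets = [dr * n_cols + dc for dr, dc in steps]
    d2s = [float(dr * dr + dc * dc) for dr, dc in steps]

    inten = intensity.ravel().tolist()
    in_growth = growth.ravel().tolist()
    seed_flat = seeds.ravel()

    INF = float("inf")
    cost = [INF] * n
    label = [0] * n
    settled = bytearray(n)

    heap: list[tuple[float, int, int]] = []
    for i in np.nonzero(seed_flat > 0)[0]:
        i = int(i)
        cost[i] = 0.0
        heap.append((0.0, int(seed_flat[i]), i))
    heapq.heapify(heap)

    push = heapq.heappush
    pop = heapq.heappop
    msqrt = math.sqrt
    q = _COST_QUANTUM
    nk = len(offsets)
    while heap:
        c0, lab, i = pop(heap)
        if settled[i]:
            continue
        settled[i] = 1
        cost[i] = c0
        label[i] = lab
        vi = inten[i]
        r = i // n_cols
        ccol = i - r * n_cols
        for k in range(nk):
            dr, dc = steps[k]
            r2 = r + dr
            c2 = ccol + dc
            if r2 < 0 or r2 >= n_rows or c2 < 0 or c2 >= n_cols:
                continue
            j = i + offsets[k]
            if settled[j] or not in_growth[j]:
                continue
            di = vi - inten[j]
            c_new = c0 + msqrt(di * di + lam * d2s[k])
            c_new = q * round(c_new / q)
            if c_new < cost[j]:
                cost[j] = c_new
                push(heap, (c_new, lab, j))
            elif c_new == cost[j]:
                # equal-cost tie: push too; heap order by (cost, label)
                # lets the smaller label settle first
                push(heap, (c_new, lab, j))

    out = np.array(label, dtype=np.int32).reshape(seeds.shape)
    # seeds keep their own labels even where a cheaper foreign path exists
    out[seeds > 0] = seeds[seeds > 0]
    return out
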