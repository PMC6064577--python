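"""Measurement operators for canopy photographs.

Greyness histograms, gap-fraction curves, grey-pixel bounds and fraction,
binarisation, misclassification maps, Sobel-based mixed-pixel-zone (MPZ)
length and the 10-90% edge-response sharpness metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import sobel
from scipy.signal import find_peaks

from canopyhp.camera import Photograph
from canopyhp.model_canopy import LABEL_CANOPY, LABEL_GREY, LABEL_SKY

__all__ = [
    "GreynessHistogram",
    "GreyPixelSummary",
    "BinaryMap",
    "MisclassificationMap",
    "MPZResult",
    "SharpnessEstimate",
    "greyness_histogram",
    "gap_fraction_at_threshold",
    "grey_pixel_bounds",
    "binarize",
    "misclassification_map",
    "mpz_sobel",
    "edge_response_distance",
]


@dataclass
class GreynessHistogram:
    """Pixel counts per digital number within the analysis mask."""

    counts: np.ndarray  # int64, length 256

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError("counts must have length 256")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("histogram is empty")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def gap_fraction_curve(self) -> np.ndarray:
        """Gap fraction for every threshold 0..255 (fraction of DN >= i)."""
        tail = np.cumsum(self.counts[::-1])[::-1]
        return tail / self.total


def greyness_histogram(photo: Photograph) -> GreynessHistogram:
    """Exact DN frequency distribution of the masked pixels."""
    if photo.n_masked == 0:
        raise ValueError("photograph has an empty analysis mask")
    return GreynessHistogram(np.bincount(photo.masked_dn, minlength=256))


def gap_fraction_at_threshold(hist: GreynessHistogram, threshold: int) -> float:
    """Fraction of masked pixels with DN >= threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    return float(hist.counts[int(threshold) :].sum() / hist.total)


@dataclass
class GreyPixelSummary:
    """Grey-pixel band of a greyness histogram.

    ``t_low`` separates canopy from grey pixels and ``t_high`` separates
    sky from grey pixels; the band is open at both ends, so the bounds
    themselves belong to canopy and sky.  ``grey_fraction`` is the mass
    strictly between the bounds.
    """

    t_low: int
    t_high: int
    grey_fraction: float
    canopy_hump: int | None = None
    sky_hump: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.t_low <= self.t_high <= 255:
            raise ValueError("bounds must satisfy 0 <= t_low <= t_high <= 255")
        if not 0.0 <= self.grey_fraction <= 1.0:
            raise ValueError("grey_fraction must lie in [0, 1]")


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    """Moving average normalised by the in-range window length at the edges."""
    if window <= 1:
        return counts.astype(float)
    kernel = np.ones(window)
    total = np.convolve(counts.astype(float), kernel, mode="same")
    coverage = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return total / coverage


def _find_humps(smoothed: np.ndarray, alpha: float) -> list[int]:
    """DN positions of up to two well-separated histogram humps.

    Local maxima (including the edge bins, which hold clipped canopy or
    saturated sky spikes) are ranked by height; a secondary hump is
    accepted only if the smoothed histogram drops below ``alpha`` times
    the smaller hump between the two, i.e. the humps are genuinely
    separated by a valley.
    """
    padded = np.concatenate(([-1.0], smoothed, [-1.0]))
    peaks, props = find_peaks(padded, height=0.0)
    peaks -= 1
    if len(peaks) == 0:
        return []
    heights = props["peak_heights"]
    order = np.argsort(heights)[::-1]
    primary = int(peaks[order[0]])
    for idx in order[1:]:
        candidate = int(peaks[idx])
        lo, hi = sorted((primary, candidate))
        if hi - lo < 2:
            continue
        valley = smoothed[lo + 1 : hi].min()
        if valley < alpha * min(smoothed[primary], smoothed[candidate]):
            return sorted((primary, candidate))
    return [primary]


def grey_pixel_bounds(
    hist: GreynessHistogram,
    alpha: float = 0.05,
    window: int = 5,
    method: str = "amplitude",
    bounds: tuple[int, int] | None = None,
) -> GreyPixelSummary:
    """Locate the grey-pixel band between the canopy and sky humps.

    The histogram is smoothed with a moving average of ``window`` bins
    and its canopy (low-DN) and sky (high-DN) humps are located.  Two
    algorithmic stand-ins for the sharp turn that manual analysis
    identifies by eye are available:

    ``"amplitude"`` (default)
        the bounds sit at a fixed relative greyness: ``t_low`` is the
        canopy hump DN plus ``alpha`` times the hump-to-hump amplitude
        and ``t_high`` the sky hump minus the same offset.  The band
        width is then a property of the edge-spread alone, so the grey
        fraction scales linearly with the border length regardless of
        how much border a canopy has.
    ``"peak"``
        moving from each hump towards the other, the bound is the first
        DN at which the smoothed count falls below ``alpha`` times that
        hump's peak count.  Closer to what a reader of a linear-scale
        histogram does, but the detected band narrows as the border
        density grows relative to the hump.

    If only one hump is present (heavily over- or under-exposed
    photographs, or gap fractions near 0 or 1) the missing bound
    collapses to the corresponding histogram edge.  Pass ``bounds`` to
    bypass detection and use explicit values.
    """
    if bounds is not None:
        t_low, t_high = int(bounds[0]), int(bounds[1])
        grey = float(hist.counts[t_low + 1 : t_high].sum() / hist.total)
        return GreyPixelSummary(t_low=t_low, t_high=t_high, grey_fraction=grey)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if method not in ("amplitude", "peak"):
        raise ValueError("method must be 'amplitude' or 'peak'")
    smoothed = _smooth(hist.counts, window)
    humps = _find_humps(smoothed, alpha)
    if len(humps) == 0:
        return GreyPixelSummary(t_low=0, t_high=0, grey_fraction=0.0)
    if len(humps) == 1:
        hump = humps[0]
        if hump >= 128:  # sky-only histogram
            t_high = _descend(smoothed, hump, alpha, step=-1, stop=0)
            return GreyPixelSummary(
                t_low=0,
                t_high=t_high,
                grey_fraction=float(hist.counts[1:t_high].sum() / hist.total),
                sky_hump=hump,
            )
        t_low = _descend(smoothed, hump, alpha, step=+1, stop=255)
        return GreyPixelSummary(
            t_low=t_low,
            t_high=255,
            grey_fraction=float(hist.counts[t_low + 1 : 255].sum() / hist.total),
            canopy_hump=hump,
        )
    canopy_hump, sky_hump = humps
    if method == "amplitude":
        offset = alpha * (sky_hump - canopy_hump)
        t_low = int(np.floor(canopy_hump + offset))
        t_high = int(np.ceil(sky_hump - offset))
    else:
        t_low = _descend(smoothed, canopy_hump, alpha, step=+1, stop=sky_hump)
        t_high = _descend(smoothed, sky_hump, alpha, step=-1, stop=canopy_hump)
    if t_low > t_high:  # humps too close to carry a grey band
        t_low = t_high = (t_low + t_high) // 2
    grey = float(hist.counts[t_low + 1 : t_high].sum() / hist.total)
    return GreyPixelSummary(
        t_low=t_low,
        t_high=t_high,
        grey_fraction=grey,
        canopy_hump=canopy_hump,
        sky_hump=sky_hump,
    )


def _descend(smoothed: np.ndarray, hump: int, alpha: float, step: int, stop: int) -> int:
    """First DN from ``hump`` towards ``stop`` with count below alpha*peak."""
    level = alpha * smoothed[hump]
    dn = hump
    while dn != stop:
        dn += step
        if smoothed[dn] < level:
            return dn
    return stop


@dataclass
class BinaryMap:
    """Sky/canopy classification of a photograph at a threshold."""

    sky: np.ndarray  # bool: classified as sky (DN >= threshold)
    mask: np.ndarray  # bool: analysis region
    threshold: int

    def __post_init__(self) -> None:
        if self.sky.shape != self.mask.shape:
            raise ValueError("sky and mask geometry differ")
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold must lie in [0, 255]")

    @property
    def gap_fraction(self) -> float:
        n = int(self.mask.sum())
        if n == 0:
            raise ValueError("empty analysis mask")
        return float((self.sky & self.mask).sum() / n)


def binarize(photo: Photograph, threshold: int) -> BinaryMap:
    """Classify pixels as sky iff DN >= threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold}")
    return BinaryMap(
        sky=photo.dn >= threshold, mask=photo.mask.copy(), threshold=int(threshold)
    )


# Fig-6-style colour code for misclassification maps
CATEGORY_CORRECT_SKY = 0  # white
CATEGORY_CORRECT_CANOPY = 1  # black
CATEGORY_FALSE_SKY = 2  # red
CATEGORY_FALSE_CANOPY = 3  # blue

_CATEGORY_RGB = np.array(
    [[255, 255, 255], [0, 0, 0], [255, 0, 0], [0, 0, 255]], dtype=np.uint8
)


@dataclass
class MisclassificationMap:
    """Per-pixel classification audit of a binary map.

    Pure sky and canopy pixels are judged against their ground-truth
    labels; grey (mixed) pixels have no intrinsic class, so they are
    judged against the correctly-matched reference classification.
    """

    categories: np.ndarray  # uint8 within the mask
    mask: np.ndarray
    counts: dict = field(init=False)

    def __post_init__(self) -> None:
        inside = self.categories[self.mask]
        self.counts = {
            "correct_sky": int((inside == CATEGORY_CORRECT_SKY).sum()),
            "correct_canopy": int((inside == CATEGORY_CORRECT_CANOPY).sum()),
            "false_sky": int((inside == CATEGORY_FALSE_SKY).sum()),
            "false_canopy": int((inside == CATEGORY_FALSE_CANOPY).sum()),
        }

    @property
    def n_misclassified(self) -> int:
        return self.counts["false_sky"] + self.counts["false_canopy"]

    @property
    def misclassified_fraction(self) -> float:
        return self.n_misclassified / int(self.mask.sum())

    def to_rgb(self) -> np.ndarray:
        """RGB image (white/black/red/blue; grey outside the mask)."""
        rgb = np.full(self.categories.shape + (3,), 128, dtype=np.uint8)
        rgb[self.mask] = _CATEGORY_RGB[self.categories[self.mask]]
        return rgb


def misclassification_map(
    binary: BinaryMap, labels: np.ndarray, reference: BinaryMap
) -> MisclassificationMap:
    """Audit a binary map against ground truth and a matched reference."""
    if labels.shape != binary.sky.shape or reference.sky.shape != binary.sky.shape:
        raise ValueError("labels, binary map and reference geometry differ")
    should_be_sky = np.where(
        labels == LABEL_GREY, reference.sky, labels == LABEL_SKY
    )
    categories = np.empty(binary.sky.shape, dtype=np.uint8)
    categories[binary.sky & should_be_sky] = CATEGORY_CORRECT_SKY
    categories[~binary.sky & ~should_be_sky] = CATEGORY_CORRECT_CANOPY
    categories[binary.sky & ~should_be_sky] = CATEGORY_FALSE_SKY
    categories[~binary.sky & should_be_sky] = CATEGORY_FALSE_CANOPY
    return MisclassificationMap(categories=categories, mask=binary.mask.copy())


@dataclass
class MPZResult:
    """Mixed-pixel-zone detection on a binary map."""

    edge_mask: np.ndarray  # bool
    mpz_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mpz_fraction <= 1.0:
            raise ValueError("mpz_fraction must lie in [0, 1]")


def mpz_sobel(binary: BinaryMap) -> MPZResult:
    """Mixed-pixel zone via the 3x3 Sobel edge detector.

    A pixel belongs to the MPZ iff the Sobel gradient magnitude
    ``sqrt(Gx^2 + Gy^2)`` of the 0/1 map is non-zero; on a hard edge both
    flanking pixels respond, giving a two-pixel-wide zone whose pixel
    fraction approximates the border length per unit area.  Image borders
    are edge-replicated so the frame itself raises no response.
    """
    img = binary.sky.astype(float)
    gx = sobel(img, axis=1, mode="nearest")
    gy = sobel(img, axis=0, mode="nearest")
    magnitude = np.hypot(gx, gy)
    edge = magnitude > 1e-9
    n = int(binary.mask.sum())
    if n == 0:
        raise ValueError("empty analysis mask")
    return MPZResult(
        edge_mask=edge, mpz_fraction=float((edge & binary.mask).sum() / n)
    )


@dataclass
class SharpnessEstimate:
    """10-90% edge-response distance and the derived sharpness."""

    rise_distance: float  # px
    profile: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rise_distance <= 0.0:
            raise ValueError("rise_distance must be positive")

    @property
    def sharpness(self) -> float:
        """Image sharpness S = 1 / rise distance (per px)."""
        return 1.0 / self.rise_distance


def edge_response_distance(
    photo: Photograph | np.ndarray, orientation: str = "vertical"
) -> SharpnessEstimate:
    """Sharpness from a straight edge of known orientation.

    The DN profile is averaged along the edge direction and the distance
    between the linearly-interpolated 10% and 90% crossings of the
    low-to-high amplitude is returned.  For an unblurred step this
    distance is below one pixel; for a Gaussian point-spread function of
    scale ``sigma`` acting on a linear tone scale it equals
    ``2 * 1.28155 * sigma ~= 2.5631 * sigma`` (the distance between the
    10% and 90% quantiles of the normal distribution).
    """
    dn = photo.dn if isinstance(photo, Photograph) else np.asarray(photo)
    if orientation == "vertical":
        profile = dn.mean(axis=0).astype(float)
    elif orientation == "horizontal":
        profile = dn.mean(axis=1).astype(float)
    else:
        raise ValueError("orientation must be 'vertical' or 'horizontal'")
    if profile[0] > profile[-1]:
        profile = profile[::-1]
    low, high = profile.min(), profile.max()
    amplitude = high - low
    if amplitude <= 0.0:
        raise ValueError("edge profile has zero amplitude")
    return SharpnessEstimate(
        rise_distance=_crossing(profile, low + 0.9 * amplitude)
        - _crossing(profile, low + 0.1 * amplitude),
        profile=profile,
    )


def _crossing(profile: np.ndarray, level: float) -> float:
    """Position of the first upward crossing of ``level`` (linear interp)."""
    above = profile >= level
    if not above.any() or above[0]:
        raise ValueError("no monotone crossing found in the edge profile")
    i = int(np.argmax(above))
    frac = (level - profile[i - 1]) / (profile[i] - profile[i - 1])
    return (i - 1) + float(frac)
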