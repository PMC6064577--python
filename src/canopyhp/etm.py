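"""Exposure-thresholding mismatch (ETM) framework.

Exposure manipulation ``X`` is the deviation of a photograph's exposure
from the reference (metered on unobscured sky), in stops.  Thresholding
manipulation ``S_t`` is the stop value whose optimal threshold equals the
DN threshold actually applied.  Their difference

    M = X - S_t

is the ETM extent: zero means the photograph is analysed with its optimal
threshold, positive M overestimates gap fraction (overexposure or too low
a threshold) and negative M underestimates it.

Two stop-to-DN calibrations coexist here:

* the logistic optimal-threshold model
  ``Y = a / (1 + exp((-X + x0) / s))`` with the published constants
  a = 260.542, x0 = 1.422, s = 1.160 - calibration data belonging to the
  source camera that produced them, used for stop/DN bookkeeping;
* for synthetic photographs, a threshold ladder anchored at the matched
  threshold (the DN that best recovers the scene's true gap fraction
  from the histogram) and shifted by ``2**(dS / gamma)`` per stop, the
  exposure response of the simulated camera itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np

from canopyhp.camera import Photograph
from canopyhp.image_analysis import (
    GreynessHistogram,
    GreyPixelSummary,
    gap_fraction_at_threshold,
    grey_pixel_bounds,
    greyness_histogram,
    binarize,
    mpz_sobel,
)

__all__ = [
    "ETMParams",
    "DEFAULT_ETM_PARAMS",
    "AnalysisRecord",
    "optimal_threshold",
    "thresholding_manipulation",
    "etm_extent",
    "inaccuracy",
    "matched_threshold",
    "threshold_for_stop",
    "analyze_with_etm",
]


@dataclass(frozen=True)
class ETMParams:
    """Constants of the logistic exposure/optimal-threshold model."""

    asymptote: float = 260.542  # a, DN
    midpoint: float = 1.422  # x0, stop
    scale: float = 1.160  # s, stop

    def __post_init__(self) -> None:
        if self.asymptote <= 0.0 or self.scale <= 0.0:
            raise ValueError("asymptote and scale must be positive")


DEFAULT_ETM_PARAMS = ETMParams()


def optimal_threshold(stops: float, params: ETMParams = DEFAULT_ETM_PARAMS) -> int:
    """Integer optimal threshold for an exposure manipulation in stops.

    The real-valued logistic response is floored to an integer DN and
    clamped to [0, 255] (the asymptote 260.542 exceeds the 8-bit range).
    """
    if not math.isfinite(stops):
        raise ValueError("stops must be finite")
    y = params.asymptote / (1.0 + math.exp((-stops + params.midpoint) / params.scale))
    return int(min(max(math.floor(y), 0), 255))


def thresholding_manipulation(
    threshold: float, params: ETMParams = DEFAULT_ETM_PARAMS
) -> float:
    """Stop value whose optimal threshold equals ``threshold`` (logistic inverse)."""
    if not 0.0 < threshold < params.asymptote:
        raise ValueError(
            f"threshold must lie in (0, {params.asymptote:g}), got {threshold}"
        )
    return params.midpoint - params.scale * math.log(params.asymptote / threshold - 1.0)


def etm_extent(exposure: float, threshold_stops: float) -> float:
    """ETM extent M: thresholding manipulation subtracted from exposure."""
    if not (math.isfinite(exposure) and math.isfinite(threshold_stops)):
        raise ValueError("stop values must be finite")
    return exposure - threshold_stops


def inaccuracy(gap_fraction_photo: float, gap_fraction_ref: float) -> float:
    """Estimation inaccuracy I = GF_photo - GF_reference."""
    for value in (gap_fraction_photo, gap_fraction_ref):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"gap fractions must lie in [0, 1], got {value}")
    return gap_fraction_photo - gap_fraction_ref


def matched_threshold(
    photo: Photograph, hist: GreynessHistogram | None = None
) -> int:
    """DN threshold that best recovers the scene's true gap fraction.

    Scans the histogram's gap-fraction curve for the threshold whose gap
    fraction is closest to the ground truth.  Because the curve is a
    staircase, several thresholds may tie; the middle of the tying run is
    returned so the cut sits centrally in the empty greyness interval.
    """
    if hist is None:
        hist = greyness_histogram(photo)
    truth = photo.reference_gap_fraction()
    deviation = np.abs(hist.gap_fraction_curve() - truth)
    ties = np.flatnonzero(deviation == deviation.min())
    return int(ties[(len(ties) - 1) // 2])


def threshold_for_stop(
    photo: Photograph,
    threshold_stops: float,
    hist: GreynessHistogram | None = None,
    anchor: int | None = None,
) -> int:
    """Simulator-consistent DN threshold for a thresholding manipulation.

    The matched threshold of the photograph anchors the ladder at
    ``S_t = X``; other stops scale the anchor by ``2**(dS / gamma)``, the
    factor by which the simulated camera's DN response moves per stop.
    The result is floored and clamped to [0, 255].
    """
    if anchor is None:
        anchor = matched_threshold(photo, hist)
    delta = threshold_stops - photo.exposure
    value = anchor * 2.0 ** (delta / photo.config.gamma)
    return int(min(max(math.floor(value), 0), 255))


def _ladder_raw(photo: Photograph, threshold_stops: float, anchor: int) -> float:
    return anchor * 2.0 ** ((threshold_stops - photo.exposure) / photo.config.gamma)


@dataclass
class AnalysisRecord:
    """Result of analysing one photograph at one thresholding manipulation."""

    exposure: float  # X, stop
    threshold_stops: float  # S_t, stop
    etm: float  # M = X - S_t, stop
    threshold_dn: int
    gap_fraction_photo: float  # GF_p
    gap_fraction_ref: float  # GF_s (scene truth) or matched estimate
    inaccuracy: float  # I = GF_p - GF_ref
    grey_fraction: float  # F
    t_low: int
    t_high: int
    mpz_fraction: float
    gf_designed: float | None = None
    side_length_mm: float | None = None
    scb_per_area: float | None = None  # designed B, mm/mm^2
    scb_per_area_measured: float | None = None  # border contained in the mask
    threshold_clipped: bool = False  # requested stop not representable in 8 bits

    def to_dict(self) -> dict:
        return asdict(self)


def analyze_with_etm(
    photo: Photograph,
    threshold_stops: float,
    reference_gap_fraction: float | None = None,
    threshold_model: Callable[[float], int] | None = None,
    hist: GreynessHistogram | None = None,
    bounds_kwargs: dict | None = None,
    grey: GreyPixelSummary | None = None,
    mpz_fraction: float | None = None,
    measured_border: float | None = None,
) -> AnalysisRecord:
    """Analyse a photograph at a thresholding manipulation of ``S_t`` stops.

    The DN threshold comes from ``threshold_model(S_t)`` if given, else
    from the simulator-consistent ladder (synthetic photographs with
    scene truth attached).  The reference gap fraction defaults to the
    scene ground truth; for photographs without provenance it must be
    supplied (e.g. the matched-analysis estimate).  ``grey`` and
    ``mpz_fraction`` are per-photograph quantities independent of the
    thresholding manipulation and may be passed in to avoid recomputation
    when one photograph is analysed at many stops.
    """
    if hist is None:
        hist = greyness_histogram(photo)
    if reference_gap_fraction is None:
        if photo.scene is None:
            raise ValueError(
                "no reference gap fraction: pass reference_gap_fraction for "
                "photographs without scene ground truth"
            )
        reference_gap_fraction = photo.reference_gap_fraction()
    if threshold_model is None:
        anchor = matched_threshold(photo, hist)
        raw = _ladder_raw(photo, threshold_stops, anchor)
        threshold_dn = int(min(max(math.floor(raw), 0), 255))
        clipped = raw > 255.0 or raw < 1.0
        matched_dn = anchor
    else:
        threshold_dn = int(threshold_model(threshold_stops))
        clipped = threshold_dn in (0, 255)
        matched_dn = int(threshold_model(photo.exposure))
    gf_photo = gap_fraction_at_threshold(hist, threshold_dn)
    if grey is None:
        grey = grey_pixel_bounds(hist, **(bounds_kwargs or {}))
    if mpz_fraction is None:
        mpz_fraction = mpz_sobel(binarize(photo, matched_dn)).mpz_fraction
    spec = photo.scene.spec if photo.scene is not None else None
    if measured_border is None and photo.scene is not None:
        measured_border = photo.scene.border_length_within(photo.mask)
    return AnalysisRecord(
        exposure=photo.exposure,
        threshold_stops=threshold_stops,
        etm=etm_extent(photo.exposure, threshold_stops),
        threshold_dn=threshold_dn,
        gap_fraction_photo=gf_photo,
        gap_fraction_ref=reference_gap_fraction,
        inaccuracy=inaccuracy(gf_photo, reference_gap_fraction),
        grey_fraction=grey.grey_fraction,
        t_low=grey.t_low,
        t_high=grey.t_high,
        mpz_fraction=mpz_fraction,
        gf_designed=None if spec is None else spec.gap_fraction,
        side_length_mm=None if spec is None else spec.side_length,
        scb_per_area=None if spec is None else spec.border_per_area,
        scb_per_area_measured=measured_border,
        threshold_clipped=clipped,
    )
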