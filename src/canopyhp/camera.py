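"""Photograph acquisition model: exposure stops, blur, tone curve, mask.

The simulator maps per-pixel sky occupancy to 8-bit digital numbers (DN):

1. linear radiance ``p = c + (1 - c) * occupancy`` with ``c`` the canopy
   radiance ratio (opaque black canopy elements reflect a little light);
2. exposure scaling by ``2**X`` for an exposure manipulation of ``X``
   stops relative to the reference metered on unobscured sky;
3. a power-law tone response ``v = ref_dn * (p * 2**X) ** (1 / gamma)``
   so that unobscured sky at the reference exposure lands on
   ``sky_dn_at_reference``;
4. Gaussian blur of scale ``blur_sigma`` applied to the tone-mapped
   signal (the effective system point-spread function, dominated by
   in-camera processing that acts downstream of the sensor response);
5. rounding and clipping to the integer range [0, 255].  Clipping after
   the blur reproduces blooming: once the sky saturates, overexposure
   spreads saturation across the sky-canopy border and gaps appear to
   grow.

Every step is monotone in exposure, so DN never decreases when a
photograph is re-taken one stop brighter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from canopyhp.model_canopy import SceneRaster

__all__ = [
    "CameraConfig",
    "Photograph",
    "simulate_photograph",
    "apply_circular_mask",
    "circular_mask",
    "tone_response",
    "sky_level",
    "canopy_level",
    "midtone_level",
]


@dataclass(frozen=True)
class CameraConfig:
    """Radiometric and geometric parameters of the simulated camera.

    Parameters
    ----------
    sky_dn_at_reference : float
        DN of unobscured sky at exposure manipulation 0 (before
        rounding).  Default 128, the middle of the 8-bit range.
    canopy_radiance_ratio : float
        Radiance of canopy elements as a fraction of sky radiance.
        Default 0.01 (opaque black sheet).
    gamma : float
        Tone-curve exponent; DN grows as the ``1/gamma`` power of linear
        exposure.  Default 2.2 (the standard display-referred encoding).
    blur_sigma : float
        Gaussian scale of the effective point-spread function in pixels.
    mask_diameter : int or None
        Diameter of the circular analysis region in pixels; ``None``
        selects the largest circle inscribed in the frame.
    noise_sigma : float
        Optional additive Gaussian DN noise (0 disables it).
    """

    sky_dn_at_reference: float = 128.0
    canopy_radiance_ratio: float = 0.01
    gamma: float = 2.2
    blur_sigma: float = 1.0
    mask_diameter: Optional[int] = None
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.sky_dn_at_reference <= 255.0:
            raise ValueError("sky_dn_at_reference must lie in (0, 255]")
        if not 0.0 <= self.canopy_radiance_ratio < 1.0:
            raise ValueError("canopy_radiance_ratio must lie in [0, 1)")
        if self.gamma <= 0.0:
            raise ValueError("gamma must be positive")
        if self.blur_sigma < 0.0:
            raise ValueError("blur_sigma must be non-negative")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be non-negative")


def tone_response(linear: np.ndarray | float, config: CameraConfig) -> np.ndarray | float:
    """Unclipped tone value of a linear exposure (sky at X=0 maps to ref DN)."""
    return config.sky_dn_at_reference * np.asarray(linear, dtype=float) ** (
        1.0 / config.gamma
    )


def sky_level(config: CameraConfig, stops: float) -> float:
    """Unclipped tone value of unobscured sky at exposure ``stops``."""
    return float(tone_response(2.0**stops, config))


def canopy_level(config: CameraConfig, stops: float) -> float:
    """Unclipped tone value of pure canopy at exposure ``stops``."""
    return float(tone_response(config.canopy_radiance_ratio * 2.0**stops, config))


def midtone_level(config: CameraConfig, stops: float) -> float:
    """Tone value midway between canopy and sky at exposure ``stops``.

    With the blur acting on the tone-mapped signal the border profile is
    symmetric in tone, so this midpoint is the cut that recovers the true
    gap fraction of a scene photographed at ``stops``.
    """
    return 0.5 * (sky_level(config, stops) + canopy_level(config, stops))


def circular_mask(shape: tuple[int, int], diameter: float) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within the centred circle."""
    if diameter <= 0:
        raise ValueError("mask diameter must be positive")
    rows, cols = shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    y = np.arange(rows)[:, None] - cy
    x = np.arange(cols)[None, :] - cx
    return y * y + x * x <= (diameter / 2.0) ** 2


@dataclass
class Photograph:
    """8-bit greyscale photograph with its acquisition metadata."""

    dn: np.ndarray  # uint8, 2-D
    mask: np.ndarray  # bool, same shape
    exposure: float  # exposure manipulation X, stops
    blur_sigma: float
    config: CameraConfig
    scene: SceneRaster | None = None  # ground-truth provenance if synthetic

    def __post_init__(self) -> None:
        dn = np.asarray(self.dn)
        if dn.dtype != np.uint8:
            if dn.min() < 0 or dn.max() > 255:
                raise ValueError("dn values must lie in [0, 255]")
            dn = dn.astype(np.uint8)
        if dn.ndim != 2:
            raise ValueError("dn must be 2-D")
        if self.mask.shape != dn.shape:
            raise ValueError("mask geometry does not match dn")
        self.dn = dn

    @property
    def shape(self) -> tuple[int, int]:
        return self.dn.shape

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def masked_dn(self) -> np.ndarray:
        return self.dn[self.mask]

    def reference_gap_fraction(self) -> float:
        """True gap fraction of the underlying scene within the mask."""
        if self.scene is None:
            raise ValueError("photograph has no scene ground truth attached")
        return self.scene.gap_fraction_within(self.mask)


def simulate_photograph(
    scene: SceneRaster,
    exposure: float,
    config: CameraConfig = CameraConfig(),
    rng: np.random.Generator | None = None,
) -> Photograph:
    """Photograph a rendered scene at an exposure manipulation in stops."""
    if not np.isfinite(exposure):
        raise ValueError("exposure must be finite")
    c = config.canopy_radiance_ratio
    radiance = c + (1.0 - c) * scene.occupancy
    tone = tone_response(radiance * 2.0**exposure, config)
    if config.blur_sigma > 0.0:
        tone = gaussian_filter(tone, sigma=config.blur_sigma, mode="nearest")
    if config.noise_sigma > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        tone = tone + rng.normal(0.0, config.noise_sigma, size=tone.shape)
    dn = np.clip(np.rint(tone), 0, 255).astype(np.uint8)
    diameter = config.mask_diameter
    if diameter is None:
        diameter = min(dn.shape)
    mask = circular_mask(dn.shape, min(diameter, min(dn.shape)))
    return Photograph(
        dn=dn,
        mask=mask,
        exposure=exposure,
        blur_sigma=config.blur_sigma,
        config=config,
        scene=scene,
    )


def blurred_occupancy(photo: Photograph) -> np.ndarray:
    """Scene occupancy convolved with the photograph's point-spread function."""
    if photo.scene is None:
        raise ValueError("photograph has no scene ground truth attached")
    occ = photo.scene.occupancy
    if photo.blur_sigma > 0.0:
        occ = gaussian_filter(occ, sigma=photo.blur_sigma, mode="nearest")
    return occ


def mixed_pixel_labels(photo: Photograph, epsilon: float | None = None) -> np.ndarray:
    """Photographic ground-truth labels {canopy, grey, sky} of a photograph.

    A pixel belongs to the mixed-pixel zone (label grey) if the blur
    spreads a detectable trace of the border into it, i.e. if its blurred
    occupancy differs from 0 or 1 by more than ``epsilon``.  The default
    ``epsilon`` corresponds to half a DN quantum at the photograph's
    canopy-to-sky amplitude, the smallest difference the 8-bit image can
    record.
    """
    from canopyhp.model_canopy import LABEL_CANOPY, LABEL_GREY, LABEL_SKY

    occ = blurred_occupancy(photo)
    if epsilon is None:
        amplitude = sky_level(photo.config, photo.exposure) - canopy_level(
            photo.config, photo.exposure
        )
        epsilon = min(0.5, 0.5 / max(amplitude, 1e-9))
    labels = np.full(occ.shape, LABEL_GREY, dtype=np.uint8)
    labels[occ <= epsilon] = LABEL_CANOPY
    labels[occ >= 1.0 - epsilon] = LABEL_SKY
    return labels


def apply_circular_mask(photo: Photograph, diameter: float) -> Photograph:
    """Replace the analysis mask by a centred circle of the given diameter.

    A pixel is inside the region if its centre lies within ``diameter/2``
    of the image centre; diameters larger than the frame are capped.
    """
    if diameter <= 0:
        raise ValueError("mask diameter must be positive")
    capped = min(diameter, min(photo.shape))
    return replace(photo, mask=circular_mask(photo.shape, capped))
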