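"""Grid model canopies: geometry and rasterisation.

A model canopy is an opaque sheet perforated by a square lattice of square
openings: side length ``L`` (mm), separated by opaque strips of width ``W``
(mm).  The design is fully characterised by two quantities,

* designed gap fraction  ``GF_d = L^2 / (L + W)^2``
* sky-canopy border (SCB) length per unit area  ``B = 4 L / (L + W)^2``

which can be varied independently of one another: canopies with equal
``B`` but different ``GF_d`` (and vice versa) exist on the design grid.
The standard suite is a 5 x 4 grid of gap fractions
{0.05, 0.10, 0.25, 0.50, 0.75} and side lengths {2.5, 5, 10, 20} mm with
three infeasible corner cells removed, 17 canopies in total.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

__all__ = [
    "CanopySpec",
    "SceneRaster",
    "LABEL_CANOPY",
    "LABEL_GREY",
    "LABEL_SKY",
    "separation_width",
    "designed_gap_fraction",
    "scb_length_per_area",
    "scale_canopy",
    "render_canopy",
    "generate_canopy_suite",
    "round_half_up",
]

#: per-pixel ground-truth categories of a rendered scene
LABEL_CANOPY = 0
LABEL_GREY = 1
LABEL_SKY = 2

#: default sheet extent, mm (opaque vinyl sheet of the physical rig)
SHEET_WIDTH_MM = 200.0
SHEET_HEIGHT_MM = 210.0

#: the standard 17-canopy design grid: gap-fraction rows, side-length
#: columns, and the three infeasible cells (either W below fabrication
#: width or opening larger than the sheet) that are left empty
SUITE_GAP_FRACTIONS = (0.05, 0.10, 0.25, 0.50, 0.75)
SUITE_SIDE_LENGTHS = (2.50, 5.00, 10.00, 20.00)
SUITE_EXCLUDED = ((0.05, 20.00), (0.10, 20.00), (0.75, 2.50))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed design tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def separation_width(gap_fraction: float, side_length: float) -> float:
    """Opaque strip width ``W = L / sqrt(GF_d) - L`` for a desired design.

    Parameters
    ----------
    gap_fraction : float
        Designed gap fraction, strictly between 0 and 1.
    side_length : float
        Side length ``L`` of the square openings, mm, positive.
    """
    if not 0.0 < gap_fraction < 1.0:
        raise ValueError(f"gap_fraction must lie in (0, 1), got {gap_fraction}")
    if side_length <= 0.0:
        raise ValueError(f"side_length must be positive, got {side_length}")
    return side_length / math.sqrt(gap_fraction) - side_length


def designed_gap_fraction(side_length: float, separation: float) -> float:
    """Designed gap fraction ``GF_d = L^2 / (L + W)^2``."""
    if side_length <= 0.0:
        raise ValueError(f"side_length must be positive, got {side_length}")
    if separation < 0.0:
        raise ValueError(f"separation must be non-negative, got {separation}")
    return side_length**2 / (side_length + separation) ** 2


def scb_length_per_area(side_length: float, separation: float) -> float:
    """SCB length per unit area ``B = 4 L / (L + W)^2`` (mm / mm^2).

    Each opening contributes a perimeter of ``4 L`` within one lattice
    cell of area ``(L + W)^2``; equivalently ``B = 4 GF_d / L``.
    """
    if side_length <= 0.0:
        raise ValueError(f"side_length must be positive, got {side_length}")
    if separation < 0.0:
        raise ValueError(f"separation must be non-negative, got {separation}")
    return 4.0 * side_length / (side_length + separation) ** 2


@dataclass(frozen=True)
class CanopySpec:
    """Geometry of one grid model canopy.

    ``gap_fraction`` and ``border_per_area`` are derived from ``(L, W)``,
    so the defining identities hold exactly by construction.
    """

    side_length: float  # L, mm
    separation: float  # W, mm
    sheet_width: float = SHEET_WIDTH_MM
    sheet_height: float = SHEET_HEIGHT_MM

    def __post_init__(self) -> None:
        if self.side_length <= 0.0:
            raise ValueError("side_length must be positive")
        if self.separation < 0.0:
            raise ValueError("separation must be non-negative")
        if self.sheet_width <= 0.0 or self.sheet_height <= 0.0:
            raise ValueError("sheet extent must be positive")

    @classmethod
    def from_gap_fraction(
        cls, gap_fraction: float, side_length: float, **kwargs
    ) -> "CanopySpec":
        return cls(
            side_length=side_length,
            separation=separation_width(gap_fraction, side_length),
            **kwargs,
        )

    @property
    def gap_fraction(self) -> float:
        """Designed gap fraction GF_d."""
        return designed_gap_fraction(self.side_length, self.separation)

    @property
    def border_per_area(self) -> float:
        """SCB length per unit area B, mm/mm^2."""
        return scb_length_per_area(self.side_length, self.separation)

    @property
    def period(self) -> float:
        """Lattice period L + W, mm."""
        return self.side_length + self.separation

    @property
    def label(self) -> str:
        return f"gf{self.gap_fraction:.2f}_L{self.side_length:g}"


def scale_canopy(spec: CanopySpec, factor: float) -> CanopySpec:
    """Scale the canopy geometry by ``factor`` (both L and W).

    The gap fraction is scale-invariant while the border length per unit
    area transforms as ``B -> B / factor``; halving the geometry (or
    doubling the camera-to-canopy distance, which halves the image of the
    pattern) therefore doubles the SCB length recorded per unit image
    area.
    """
    if factor <= 0.0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    return replace(
        spec,
        side_length=spec.side_length * factor,
        separation=spec.separation * factor,
    )


def generate_canopy_suite(
    gap_fractions: Sequence[float] = SUITE_GAP_FRACTIONS,
    side_lengths: Sequence[float] = SUITE_SIDE_LENGTHS,
    excluded: Sequence[tuple[float, float]] = SUITE_EXCLUDED,
    **kwargs,
) -> list[CanopySpec]:
    """The standard suite of model canopies (17 with default arguments).

    The full ``gap_fractions x side_lengths`` grid is generated row by
    row, skipping the ``(gap_fraction, side_length)`` pairs listed in
    ``excluded``.
    """
    excluded_set = {(round(g, 6), round(length, 6)) for g, length in excluded}
    suite = []
    for gf in gap_fractions:
        for length in side_lengths:
            if (round(gf, 6), round(length, 6)) in excluded_set:
                continue
            suite.append(CanopySpec.from_gap_fraction(gf, length, **kwargs))
    return suite


@dataclass
class SceneRaster:
    """Continuous-tone rasterisation of a model canopy with ground truth.

    ``occupancy`` holds the sky (opening) area fraction of every pixel in
    [0, 1]; ``labels`` classifies pixels as pure sky (occupancy 1), pure
    canopy (occupancy 0) or grey (partially covered border pixels).
    """

    occupancy: np.ndarray  # float64, 2-D
    pixel_scale: float  # mm per pixel
    spec: CanopySpec | None = None
    labels: np.ndarray = field(init=False)
    true_gap_fraction: float = field(init=False)
    true_border_length: float | None = None  # mm per mm^2, exact geometry

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.size == 0:
            raise ValueError("occupancy must be a non-empty 2-D array")
        if occ.min() < 0.0 or occ.max() > 1.0:
            raise ValueError("occupancy values must lie in [0, 1]")
        self.occupancy = occ
        labels = np.full(occ.shape, LABEL_GREY, dtype=np.uint8)
        labels[occ == 0.0] = LABEL_CANOPY
        labels[occ == 1.0] = LABEL_SKY
        self.labels = labels
        self.true_gap_fraction = float(occ.mean())
        if self.true_border_length is None and self.spec is not None:
            self.true_border_length = self.spec.border_per_area

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    def gap_fraction_within(self, mask: np.ndarray) -> float:
        """Mean sky occupancy over an arbitrary boolean region."""
        if mask.shape != self.occupancy.shape:
            raise ValueError("mask geometry does not match the scene")
        if not mask.any():
            raise ValueError("empty mask")
        return float(self.occupancy[mask].mean())

    def border_length_within(self, mask: np.ndarray) -> float:
        """SCB length per unit area within a region, mm per mm^2.

        Measured as the total variation of the occupancy field between
        region-interior neighbours: each crossing of an axis-aligned
        border contributes exactly one pixel of length, so the sum over
        both axes is the border length in pixels.  This is the border
        actually contained in an analysis mask, which for masks covering
        few lattice periods can deviate from the design value ``B``.
        """
        if mask.shape != self.occupancy.shape:
            raise ValueError("mask geometry does not match the scene")
        n = int(mask.sum())
        if n == 0:
            raise ValueError("empty mask")
        occ = self.occupancy
        horiz = np.abs(np.diff(occ, axis=1))[mask[:, 1:] & mask[:, :-1]].sum()
        vert = np.abs(np.diff(occ, axis=0))[mask[1:, :] & mask[:-1, :]].sum()
        return float((horiz + vert) / (n * self.pixel_scale))


def _axis_coverage(
    n_pixels: int, pixel_scale: float, period: float, opening: float, supersample: int
) -> np.ndarray:
    """1-D in-opening fraction per pixel by midpoint supersampling."""
    n_sub = n_pixels * supersample
    centres = (np.arange(n_sub) + 0.5) * (pixel_scale / supersample)
    inside = np.mod(centres, period) < opening
    return inside.reshape(n_pixels, supersample).mean(axis=1)


def render_canopy(
    spec: CanopySpec,
    pixel_scale: float,
    supersample: int = 8,
    max_extent: float | None = None,
) -> SceneRaster:
    """Rasterise a model canopy to a square scene with exact ground truth.

    The rendered region spans a whole number of lattice periods (the
    largest number that fits the sheet, optionally capped by
    ``max_extent`` in mm) so that the designed gap fraction is not biased
    by partial cells.  Per-pixel occupancy is obtained by area-averaging a
    ``supersample x supersample`` midpoint sampling of the binary opening
    pattern; the pattern origin coincides with an opening corner.

    Because the opening indicator factorises over the two axes, the
    occupancy grid is the outer product of two identical 1-D coverage
    profiles.
    """
    if pixel_scale <= 0.0:
        raise ValueError("pixel_scale must be positive")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    period = spec.period
    extent = min(spec.sheet_width, spec.sheet_height)
    if max_extent is not None:
        extent = min(extent, max_extent)
    n_periods = int(extent // period)
    if n_periods < 1:
        warnings.warn(
            f"extent {extent:g} mm is smaller than one pattern period "
            f"({period:g} mm); rendering a single period",
            stacklevel=2,
        )
        n_periods = 1
    n_pixels = int(round(n_periods * period / pixel_scale))
    if n_pixels < 1:
        raise ValueError("raster has zero size; decrease pixel_scale")
    coverage = _axis_coverage(n_pixels, pixel_scale, period, spec.side_length, supersample)
    occupancy = np.outer(coverage, coverage)
    return SceneRaster(
        occupancy=occupancy,
        pixel_scale=pixel_scale,
        spec=spec,
        true_border_length=spec.border_per_area,
    )


def suite_table(suite: Sequence[CanopySpec]) -> "pandas.DataFrame":  # noqa: F821
    """Design table of a canopy suite (one row per canopy)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "canopy": [s.label for s in suite],
            "gf_designed": [s.gap_fraction for s in suite],
            "side_length_mm": [s.side_length for s in suite],
            "separation_mm": [s.separation for s in suite],
            "scb_per_area": [s.border_per_area for s in suite],
        }
    )
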