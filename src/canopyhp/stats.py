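"""Regression statistics: zero-intercept slopes, the slope-homogeneity
F-test, and the grey-fraction / inaccuracy models.

The central quantities are

* ``F = B / S + G`` - the grey-pixel fraction as a linear function of the
  sky-canopy border length per unit area ``B``, with slope the inverse
  image sharpness ``1/S`` (the effective mixed-pixel-zone width) and
  intercept ``G`` the grey fraction from sources other than borders;
* ``I = M * F`` - inaccuracy proportional to the ETM extent ``M`` times
  the grey-pixel fraction, fitted as per-``M`` zero-intercept lines of
  ``I`` on ``F``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "SlopeTestResult",
    "SharpnessModelFit",
    "InaccuracyModelFit",
    "zero_intercept_slope",
    "slope_homogeneity_ftest",
    "fit_grey_fraction_model",
    "fit_inaccuracy_model",
]


def zero_intercept_slope(x: Sequence[float], y: Sequence[float]) -> float:
    """Least-squares slope of a line through the origin: sum(xy)/sum(x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length non-empty 1-D sequences")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all x are zero; the through-origin slope is undefined")
    return float(np.dot(x, y) / sxx)


def origin_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination of the through-origin fit.

    Computed against the centred total sum of squares, as regression
    figures conventionally report it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope = zero_intercept_slope(x, y)
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


@dataclass
class SlopeTestResult:
    """F-test for homogeneity of zero-intercept regression slopes.

    The grand through-origin line fitted to the pooled data gives the
    total residual sum of squares SST; group-specific lines give the
    within-group sum SSW; their difference SSB (clipped at zero against
    floating-point cancellation) measures slope heterogeneity with
    ``DFB = k - 1`` degrees of freedom against ``DFW = n - k``.
    """

    n: int
    k: int
    sst: float
    ssw: float
    ssb: float
    dfw: int
    dfb: int
    f_value: float
    p_value: float
    grand_slope: float
    group_slopes: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Slope-homogeneity F-test (zero-intercept regressions)",
            f"  groups k = {self.k}, observations n = {self.n}",
            f"  grand slope = {self.grand_slope:.6g}",
            "  group slopes = "
            + ", ".join(f"{s:.6g}" for s in self.group_slopes),
            f"  SST = {self.sst:.6g}  SSW = {self.ssw:.6g}  SSB = {self.ssb:.6g}",
            f"  F({self.dfb}, {self.dfw}) = {self.f_value:.6g}   p = {self.p_value:.4g}",
        ]
        return "\n".join(lines)


def slope_homogeneity_ftest(
    groups: Sequence[tuple[Sequence[float], Sequence[float]]],
) -> SlopeTestResult:
    """Test whether several through-origin regressions share one slope.

    ``groups`` is a sequence of ``(x, y)`` pairs, one per group.  The
    statistic is ``F = (SSB / DFB) / (SSW / DFW)`` with the p-value from
    the upper tail of the F(DFB, DFW) distribution.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("at least two groups are required")
    xs, ys, slopes = [], [], []
    for gx, gy in groups:
        gx = np.asarray(gx, dtype=float)
        gy = np.asarray(gy, dtype=float)
        if gx.size == 0:
            raise ValueError("groups must be non-empty")
        xs.append(gx)
        ys.append(gy)
        slopes.append(zero_intercept_slope(gx, gy))
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    n = x_all.size
    dfw, dfb = n - k, k - 1
    if dfw < 1:
        raise ValueError("not enough observations: n - k must be >= 1")
    grand = zero_intercept_slope(x_all, y_all)
    sst = float(np.sum((y_all - grand * x_all) ** 2))
    ssw = float(
        sum(np.sum((gy - b * gx) ** 2) for gx, gy, b in zip(xs, ys, slopes))
    )
    ssb = max(sst - ssw, 0.0)
    if ssw == 0.0:
        # identical perfect fits carry no evidence against homogeneity;
        # unequal perfect fits give an infinite statistic
        f_value = 0.0 if ssb == 0.0 else float("inf")
        p_value = 1.0 if ssb == 0.0 else 0.0
    else:
        f_value = (ssb / dfb) / (ssw / dfw)
        p_value = float(sp_stats.f.sf(f_value, dfb, dfw))
    return SlopeTestResult(
        n=n,
        k=k,
        sst=sst,
        ssw=ssw,
        ssb=ssb,
        dfw=dfw,
        dfb=dfb,
        f_value=f_value,
        p_value=p_value,
        grand_slope=grand,
        group_slopes=slopes,
    )


@dataclass
class SharpnessModelFit:
    """Ordinary least squares fit of F = B / S + G.

    ``inverse_sharpness`` (the coefficient of B, units mm: the effective
    mixed-pixel-zone width) and ``stray_grey`` (the intercept G, grey
    pixels from sources other than borders) with the centred r^2.
    """

    inverse_sharpness: float
    stray_grey: float
    r2: float
    n: int

    def summary(self) -> str:
        return (
            "Grey-fraction model F = B/S + G\n"
            f"  1/S = {self.inverse_sharpness:.6g} mm   "
            f"G = {self.stray_grey:.6g}   r^2 = {self.r2:.4f}   n = {self.n}"
        )


def fit_grey_fraction_model(
    border_per_area: Sequence[float], grey_fraction: Sequence[float]
) -> SharpnessModelFit:
    """Fit the grey-pixel fraction as a linear function of border length."""
    b = np.asarray(border_per_area, dtype=float)
    f = np.asarray(grey_fraction, dtype=float)
    if b.shape != f.shape or b.size < 3:
        raise ValueError("need at least three (B, F) records")
    if np.ptp(b) == 0.0:
        raise ValueError("degenerate design: all border lengths equal")
    design = np.column_stack([b, np.ones_like(b)])
    coef, _, _, _ = np.linalg.lstsq(design, f, rcond=None)
    resid = f - design @ coef
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return SharpnessModelFit(
        inverse_sharpness=float(coef[0]), stray_grey=float(coef[1]), r2=r2, n=b.size
    )


@dataclass
class InaccuracyModelFit:
    """Per-ETM-extent zero-intercept regressions of inaccuracy on grey fraction.

    ``slopes`` maps each ETM extent M to the fitted slope of I on F;
    ``slope_ratios`` holds the ratios of consecutive slopes (ordered by
    M); ``pooled_slope`` is the through-origin slope of I on M*F over all
    records.
    """

    slopes: dict
    slope_ratios: list
    pooled_slope: float
    n: int

    def summary(self) -> str:
        per_m = ", ".join(f"M={m:+g}: {s:.4g}" for m, s in sorted(self.slopes.items()))
        return (
            "Inaccuracy model I = M * F (per-M through-origin slopes)\n"
            f"  {per_m}\n"
            f"  consecutive slope ratios = "
            + ", ".join(f"{r:.3g}" for r in self.slope_ratios)
            + f"\n  pooled slope of I on M*F = {self.pooled_slope:.4g}   n = {self.n}"
        )


def fit_inaccuracy_model(
    etm: Sequence[float],
    grey_fraction: Sequence[float],
    inaccuracy: Sequence[float],
) -> InaccuracyModelFit:
    """Fit the inaccuracy model over records at several ETM extents."""
    m = np.asarray(etm, dtype=float)
    f = np.asarray(grey_fraction, dtype=float)
    i = np.asarray(inaccuracy, dtype=float)
    if not (m.shape == f.shape == i.shape) or m.size == 0:
        raise ValueError("etm, grey_fraction and inaccuracy must align")
    levels = np.unique(m)
    if levels.size < 2:
        raise ValueError("records at >= 2 distinct ETM extents are required")
    slopes = {}
    for level in levels:
        sel = m == level
        slopes[float(level)] = zero_intercept_slope(f[sel], i[sel])
    ordered = [slopes[level] for level in sorted(slopes)]
    ratios = [
        ordered[j + 1] / ordered[j] if ordered[j] != 0 else float("inf")
        for j in range(len(ordered) - 1)
    ]
    pooled = zero_intercept_slope(m * f, i)
    return InaccuracyModelFit(
        slopes=slopes, slope_ratios=ratios, pooled_slope=pooled, n=m.size
    )
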