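# Methods

This note documents the models, numerical choices and limitations behind
`canopyhp`. The package quantifies why hemispherical-photography (HP)
estimates of canopy gap fraction go wrong: pixels recording the
sky–canopy border (SCB) are grey, and exposure or thresholding errors
misclassify exactly those pixels. Everything is studied on synthetic
model canopies where the ground truth is exact.

## Model canopies

A model canopy is an opaque sheet with a square lattice of square
openings: opening side `L` (mm), strip width `W` (mm), lattice period
`P = L + W`. Two designed quantities follow:

    GF_d = L^2 / (L + W)^2        designed gap fraction
    B    = 4 L / (L + W)^2        SCB length per unit area (mm / mm^2)

Given a target gap fraction, `W = L / sqrt(GF_d) − L`. Because
`B = 4 GF_d / L`, the two quantities can be varied independently — the
property that lets the study separate the effect of border length from
the effect of gap fraction. The standard suite is the 5 × 4 grid of
`GF_d ∈ {0.05, 0.10, 0.25, 0.50, 0.75}` × `L ∈ {2.5, 5, 10, 20}` mm with
three infeasible corner cells removed (17 canopies). Uniform scaling of
`(L, W)` by `c` leaves `GF_d` unchanged and maps `B → B/c`; this is the
geometric content of "doubling the camera-to-canopy distance doubles the
SCB length in the image".

### Rasterisation

`render_canopy` draws a square region spanning a whole number of lattice
periods (largest number that fits the 20 cm sheet, optionally capped by
`max_extent`, default 75 mm) so the designed gap fraction is not biased
by partial cells. Per-pixel sky occupancy is the area average of an
`8 × 8` midpoint supersampling of the binary opening pattern (the
indicator factorises over axes, so the grid is an outer product of two
1-D coverage profiles; occupancy quantisation ≤ 1/64). Pixels with
occupancy exactly 0 / exactly 1 are labelled canopy / sky; partially
covered pixels are the render-level mixed pixels. The scene records
`true_gap_fraction` (mean occupancy) and the analytic `B`.

The border actually contained in an analysis mask can differ from the
designed `B` when the mask spans few periods; `border_length_within`
measures it as the total variation of occupancy between mask-interior
neighbours (each border crossing contributes exactly one pixel of
length). Regressions use this measured value — it is the SCB length of
what is actually photographed.

**Alignment.** The experiment's default pixel scale is 0.0507 mm/px,
deliberately incommensurate with every lattice period. When the period
is a whole number of pixels, all borders share one sub-pixel phase and
the greyness histogram collapses onto a few DN values, making
gap-fraction curves staircases; an incommensurate scale makes border
pixels sample all phases (the same reason slanted-edge sharpness
protocols avoid axis-aligned edges).

## Camera model

Digital numbers are produced by

1. linear radiance `p = c + (1 − c)·occupancy`, with
   `canopy_radiance_ratio c = 0.01` (opaque black canopy elements);
2. exposure scaling `2^X` for an exposure manipulation of `X` stops
   relative to the reference metered on unobscured sky;
3. tone response `v = ref·(p·2^X)^(1/γ)` with `γ = 2.2` and
   `sky_dn_at_reference ref = 128`, so unobscured sky at `X = 0` lands
   mid-range and saturates at `X ≈ +2.2`;
4. Gaussian blur of scale `blur_sigma` (default 1 px) applied to the
   tone-mapped signal;
5. rounding and clipping to [0, 255] after the blur, so saturation
   spreads across borders under overexposure (blooming).

DN is monotone in `X` pixel-wise, two-valued for unblurred aligned
scenes, and for `γ = 1` a blurred edge is exactly the normal-CDF ramp.

**Why blur in tone space.** Optical blur precedes the sensor, but the
effective system point-spread function of a consumer camera is dominated
by processing (demosaicing, sharpening, JPEG) that acts on the
tone-mapped signal. The choice matters: with the blur in tone space the
border profile is symmetric in DN, so the gap-fraction-recovering
threshold is the canopy/sky DN midpoint, which sits at
`((1 + c^{1/γ})/2)^γ ≈ 0.281` of the sky radiance. One thresholding stop
moves a threshold by a factor 2 in radiance, so thresholds leave the
grey band at mismatch extents `M = −γ·log2(2/(1+c^{1/γ})) ≈ −1.83` and
`M = +γ·log2((1+c^{1/γ})/(2 c^{1/γ})) ≈ +4.81` stops. These boundaries
reproduce the observed classification regimes — grey-only
misclassification for `M ∈ [−1, +3]`, all-canopy below `M = −1`, canopy
misclassified as sky around `M = +5`, all-sky by `M = +7`. Blurring in
linear radiance instead puts the truth-recovering cut ~1 stop below sky,
which would (wrongly) make `M = −1` an all-canopy regime.

The circular analysis mask (pixel-centre-in-circle, default the
inscribed circle) mimics the circular hemispherical image. Sensor noise
is off by default; a Gaussian-DN option exists for robustness work.

`mixed_pixel_labels` gives the *photographic* mixed-pixel zone: pixels
whose blurred occupancy differs from 0/1 by more than half a DN quantum.
This is the ground truth used when auditing misclassification — blur
legitimately widens the MPZ beyond the render-level grey pixels.

## Measurement operators

* **Greyness histogram** — exact DN counts within the mask;
  `GF_p(i)` = fraction of masked pixels with DN ≥ i (non-increasing in i,
  and identical to binarising at i by construction).
* **Grey-pixel bounds** — the histogram is smoothed (5-bin moving
  average, edge-normalised); canopy and sky humps are local maxima
  separated by a valley below 5% of the smaller hump. Two deterministic
  surrogates for the visually-identified "sharp turn" are provided.
  The default `amplitude` rule puts the bounds at a fixed 5% relative
  greyness offset from the hump DNs, making the band width a property of
  the edge spread alone, so the grey fraction `F` is proportional to the
  border length regardless of how much border a canopy has. The `peak`
  rule (first DN where smoothed counts drop below 5% of the hump peak)
  is closer to reading a linear-scale histogram, but its band narrows as
  the border density grows relative to the hump — measured across the
  17-canopy suite it bends the F-vs-B line (origin r² 0.970 vs 0.999).
  Single-hump histograms (saturation, extreme gap fractions) collapse
  the missing bound to the histogram edge; explicit bounds can be passed.
  The band is open at both ends: the bound DNs belong to canopy and sky.
* **MPZ via Sobel** — a binary map's mixed-pixel zone is every pixel
  with non-zero 3×3 Sobel gradient magnitude (edge-replicated borders);
  a hard edge yields the two flanking pixels, so the MPZ fraction is
  ≈ 2 px × pixel scale × border length per area, linear in `B` through
  the origin.
* **Sharpness** — the 10–90% edge-response distance of a straight edge,
  from the linearly interpolated crossings of the along-edge-averaged DN
  profile. For a Gaussian PSF on a linear tone scale the distance is
  `2·z_0.9·σ ≈ 2.5631 σ`; image sharpness is its reciprocal.

## Exposure–thresholding mismatch

Thresholding manipulation `S_t` is the stop whose optimal threshold
equals the DN applied; the ETM extent is `M = X − S_t`. Inaccuracy is
`I = GF_p − GF_ref` with `GF_ref` the scene truth for synthetic
photographs.

Two stop↔DN calibrations coexist. The published logistic
`Y = 260.542 / (1 + e^{(−X+1.422)/1.160})`, floored and clamped to
[0, 255], is calibration data of the source camera (it reproduces the
printed 162 at +2 stop, 28 at −1 stop and their 134-DN difference) and
is used for bookkeeping and for analysing externally supplied images.
Note the quoted threshold "202 at +3 stop" is inconsistent with the
formula (207.34); the formula is followed. For synthetic photographs the
matched (M = 0) threshold is defined as the DN whose gap fraction is
closest to the scene truth (midpoint of ties); thresholds at other stops
scale that anchor by `2^{ΔS/γ}`, the simulated camera's own DN response
per stop. A stop whose ladder value leaves [0, 255] is not representable
in 8 bits; such records are flagged `threshold_clipped` and excluded
from regime analyses (they remain in the tables).

On the default study this yields: mean |I| ≈ 0.0012 at M = 0 (an order
of magnitude below half the grey fraction); sign(I) = sign(M) on every
unclipped record with M ∈ {−1, +1, +2, +3}; misclassified fractions at
equal M agreeing within 0.3% of masked pixels across different (X, S_t)
pairs; and per-M slopes of I on F close to proportional in M (slope/M
constant within ±7%, consecutive ratio ≈ 2.1 for the +1→+2 step). The
idealisation `I = M·F` should be read as proportionality: taken
literally at M = +3 it would require more misclassified pixels than the
grey band contains (I ≤ F whenever only grey pixels are misclassified);
the fitted pooled slope of I on M·F is ≈ 0.16 here and depends on where
the band bounds are drawn.

One degenerate case is worth knowing: at the mismatch extent where the
threshold ladder lands exactly on the uniform canopy DN (`M ≈ +4.8`
stops with the default camera), classifying the canopy class is an
all-or-nothing rounding outcome, so misclassified counts jump between
(X, S_t) pairs of equal M. A noiseless camera with a perfectly uniform
canopy exposes this knife edge; real photographs straddle it smoothly.

## Statistics

Through-origin slopes are `Σxy / Σx²`. The slope-homogeneity F-test
follows the printed sums-of-squares recipe: SST from the grand
through-origin line on pooled data, SSW from group-specific lines,
SSB = SST − SSW (clipped at 0 against floating-point cancellation),
`F = (SSB/DFB)/(SSW/DFW)` with DFB = k−1, DFW = n−k and the p-value from
the upper tail of F(DFB, DFW). SSW = 0 with SSB = 0 (identical perfect
fits) reports F = 0, p = 1; SSW = 0 with SSB > 0 reports F = ∞, p = 0.
Monte-Carlo calibration (1000 null replicates) puts the type-I error at
the nominal 5% within [0.03, 0.07].

`F = B/S + G` is fitted by ordinary least squares with intercept: the
coefficient of `B` is the inverse sharpness (effective MPZ width in mm,
0.145 mm ≈ 2.9 px at σ = 1 on the default study) and the intercept `G`
is the grey fraction from sources other than borders (≈ 0 on the
synthetic rig, r² ≈ 0.999). `I = M·F` is fitted as per-M through-origin
lines of I on F, reporting slopes, consecutive ratios and the pooled
slope of I on M·F.

## The default study and problem sizes

17 canopies × 9 exposure manipulations (−3…+5 stop) × 9 thresholding
manipulations = 153 photographs and 1377 records, rendered at
0.0507 mm/px with the region capped at 75 mm (images ≤ ~1500 px across,
≥ 1 lattice period each; the full-sheet render is available via
`max_extent=None`). The run is deterministic — identical configs and
seeds give byte-identical CSVs — and completes in well under a minute on
one core.

## What the synthetic rig does and does not show

The generator emulates the model-canopy conditions: an opaque black
pattern, even back-illumination, no sub-pixel canopy elements, no bright
canopy or dark sky. Grey pixels therefore come from SCBs only, which is
exactly what makes `G ≈ 0` and the F-vs-B line near-perfect. Passing
tests show the mechanism — grey-pixel mass set by border length and
blur, misclassification governed by the mismatch extent — not field
performance: real photographs add stray grey sources (G > 0), exposure
metering error, wind motion, JPEG artefacts and fisheye geometry, none
of which are modelled. Field datasets and their statistics (including
slope-homogeneity tests of real-photo regressions) are out of scope;
the logistic constants are borrowed calibration, not re-derived. The
hemispherical projection itself is not simulated — scenes are flat, as
the physical model-canopy rig effectively was.
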