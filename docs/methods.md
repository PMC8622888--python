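# Methods

## Shape model

Two equal viscous cylinders coalescing under surface tension evolve through a
one-parameter family of "inverse ellipse" profiles.  `boothsinter` uses two
equivalent descriptions:

- **Polar Booth lemniscate** `r(φ) = a √(cos²φ + B² sin²φ)` with size
  coefficient `a > 0` (the long-axis half-extent, here in pixels) and shape
  parameter `B ∈ (0, 1]`.  `B = 1` is a circle; `B → 0` degenerates into two
  tangent circles.  `B` is clamped to `[10⁻⁶, 1]` throughout to avoid the
  zero-radius rays of the exact limit.
- **Hopper parameterization** with parameter `m ∈ [0, 1)` and final
  equivalent radius `R₀ = √2·Rᵢ` (`Rᵢ` the initial filament radius), linked
  by `B = (1 − m)/(1 + m)`.  Keeping the enclosed area at `π R₀²` fixes
  `a = R₀ √(2/(1 + B²))`, which moves from `√2·R₀` (tangent circles) to `R₀`
  (final circle).

The Cartesian parametric form is implemented as

    x(α) = R₀ (1 − m²)(1 − m) sin α / (√(1+m²) · D(α)),
    y(α) = R₀ (1 − m²)(1 + m) cos α / (√(1+m²) · D(α)),
    D(α) = 1 + 2m cos 2α + m²,

with the filament pair horizontal (long axis along x, bonding-neck plane at
x = 0, `φ = α − π/2`).  Note the factor pairing: `(1 − m)` with `sin α` and
`(1 + m)` with `cos α`.  The pairing is sometimes printed the other way
around in the literature, which produces an unbounded curve as `α → π/2`
(denominator `(1 − m)²`); the form above is bounded, encloses the constant
area, and is algebraically identical to the polar lemniscate with
`B = (1−m)/(1+m)` — the package treats the swapped variant as a typesetting
slip and tests the polar/Cartesian identity to 10⁻⁹.

Neck geometry: the bonding-neck thickness at the symmetry plane is
`x_neck = 2aB = 2R₀(1−m)/√(1+m²)` and the bonding angle is
`θ = arcsin(x_neck/d)` with `d` the filament diameter; once the neck outgrows
`d` (late coalescence) θ is undefined and reported as NaN.

## Image pipeline

Frames are 8-bit grayscale, dark silhouette on bright backlit background by
default (polarity switchable).  Steps per frame:

1. optional ROI crop (grey levels untouched);
2. fixed-threshold segmentation; largest 8-connected component; enclosed
   holes filled before any morphology, so internal bubbles cannot create
   spurious contours;
3. contour = mask minus its erosion by the 3×3 square structuring element
   (pixels outside the image count as background, so border pixels are
   contour); an optional bottom strip of rows (the oven base) is removed
   from the contour but kept in the bookkeeping, which preserves
   |contour| + |interior| + |excluded| = |mask| exactly;
4. centroid of the mask (mean of foreground coordinates);
5. maximum horizontal length `L_max`: per-row extent from leftmost to
   rightmost foreground column inclusive (gaps included, whole pixels, no
   sub-pixel interpolation); ties resolved toward the centroid row, then the
   smaller row index — robust for flat-topped silhouettes;
6. centering at (row of `L_max`, centroid column), y pointing up, and polar
   conversion `r = √(x²+y²)`, `φ = atan2(y, x)`.

Image coordinates are 0-based `(row, col)`, row 0 at the top; all coordinate
conventions live in `image_pipeline`.

### Thresholds and the half-pixel edge convention

For a blurred backlit edge, the mid grey level (128 by default for the
synthetic 30/220 levels) crosses at the geometric boundary.  The erosion
contour, however, marks the *centers* of the outermost foreground pixels,
which sit on average half a pixel inside the physical edge.  Rasterized
contours therefore carry a `pixel_grid` flag and the fitter compares model
radii against `r + 0.5`; exact analytic point sets are fitted as-is.  Without
this convention the fitted `B` is systematically low by ≈0.01–0.03.

## Shape fitting

Per frame, `a` is pinned to `L_max/2` and the single parameter `B` minimizes
the radial least-squares objective `Σ (rᵢ − a√(cos²φᵢ + B² sin²φᵢ))²` by
Nelder–Mead simplex descent (xatol 10⁻⁶, fatol 10⁻⁹, cap 500 iterations),
warm-started across a sequence from the previous frame's optimum (0.5 for
the first frame).  Points with `r < 2 px` are excluded (unstable angle).

Because the silhouette is star-shaped about the centering origin, the polar
boundary at each angle is the **outermost** contour pixel along that ray:
the objective keeps the maximum-radius pixel per angular bin (720 bins).
This matters for near-tangent shapes: below `B ≈ 0.1` the concave notch
between the lobes is narrower than one pixel at ~200 px/mm, and the
rasterized notch walls otherwise alias into spurious inner points that
collapse the fit toward `B = 0`.  Even with ray casting, shapes with
`B ≲ 0.1` are at the resolution limit; the fitting accuracy claims
(median error ≤ 0.01, max ≤ 0.03 on ≥60 px objects) hold for `B ≥ 0.1`.

An optional constant-area mode (`a` from the closed form instead of
`L_max/2`) exists for simulation studies; it is never the default.

## Kinetics and the master curve

Row-wise, `m = (1−B)/(1+B)` and `m²` are tabulated together with
`L_max/L_max_initial` (normalized to the first valid frame).  The
experimental rate `(dm²/dt)` is the ordinary least-squares slope of `m²`
against time over the pure-sintering window, default **20–60 s**: the first
~20 s are the warm-up lag while the filament surface reaches the molten
steady state (frames are kept in the outputs but excluded from the
regression), and after ~60 s viscoelastic swelling and gravity spreading
contaminate the signal.  Plain OLS is used; the standard error comes from
the regression.

The theoretical dimensionless rate `f(m²) = dm²/d(t/t_vs)` is a tabulated
master curve with a degree-3 polynomial fit (degree configurable; the
polynomial must reproduce every knot within 1%, and evaluation outside the
tabulated span raises).  Then

    t_vs = f(m²_ref) / slope,   Δt_vs = t_vs · (Δslope/|slope|),

with `m²_ref = 0.3` by default (mid-range of the window's typical
`m² ≈ 0.4 → 0.2`).  The theoretical coefficient is treated as exact in the
uncertainty propagation.  `t_vs = Rᵢ·μ/Γ` gives the melt's
viscosity-to-surface-tension ratio via `capillary_ratio`.

### Packaged master curve is a synthetic reconstruction

The packaged table `data/hopper_master_curve_synthetic.csv` is **not** a
digitization of Hopper's original abacus, which is not shipped here.  It is
a synthetic stand-in constrained by (i) the published anchor value
`f(0.3) = −0.4727`, (ii) negativity over the whole span (coalescence only
drives m down), and (iii) smoothness — it is quadratic in `m²`,
`f(u) = −0.4727 − 0.3(u − 0.3)(u − 0.75)`, tabulated at 23 knots over
`[0.02, 0.90]`, nearly flat (±4%) across the working band.  Polynomial fits
of degree 2–4 agree identically on it.  Users with their own digitization of
the true abacus should pass it as a CSV (`m_squared,dm2_dtau`); every
kinetics routine takes the curve as a replaceable input.  Consequences:
t_vs estimates computed with the packaged curve inherit the anchor's
accuracy near `m² ≈ 0.3` but are not an independent reproduction of
Hopper's solution away from it.

## Synthetic data generator

`SimulationConfig` defaults emulate the target acquisition:

| parameter | default | meaning |
|---|---|---|
| `t_vs_true` | 80 s | characteristic time driving the dynamics |
| `m_initial` | 0.68 | starting shape (B = 0.19), see below |
| `warmup_s` | 20 s | static shape before the surface melts |
| `frame_interval_s`, `n_frames` | 1 s, 120 | 1 frame/s, 2-minute trial |
| `R0_px` | 283 px | √2 × (1 mm filament radius at 200 px/mm) |
| `image_size` | 960×960 | fits the widest shape with margin |
| `object_grey` / `background_grey` | 30 / 220 | backlit contrast |
| `blur_sigma_px` / `noise_sigma_grey` | 1 px / 3 levels | optics + sensor (engineering choices; the real camera's values are not published) |
| `swell_ratio_final` | 1.12 | final width ratio (None disables swelling) |
| `swell_start_s` / `swell_end_s` | 60 / 90 s | swelling episode |
| `base_strip_rows` | 0 | optional solid oven-base strip |

`m²(t)` is constant during the warm-up, then integrated by fixed-step
classical Runge–Kutta (one step per frame) from `dm²/dt = f(m²)/t_vs_true`
and floored at zero; `B` and the constant-area `a` follow from the closed
forms.  All randomness derives from the single integer seed; frame `k` uses
the child stream `(seed, k)`, so every frame is bit-reproducible.

**Starting shape.** The default `m_initial = 0.68` is the first shape an
analysis at this pixel scale can actually resolve: for `m ≳ 0.9`
(near-tangent lobes) the concave notch is sub-pixel and the silhouette is
indistinguishable from a slightly thicker neck, so simulating from there
would test the renderer's rasterization rather than the method.  It also
matches the observed starting point of real sintering sequences once the
surface melts (B ≈ 0.19).

**Swelling.** Real melts swell viscoelastically and spread under gravity
late in the sequence, which real data show as the width ratio stabilizing
above 1 (≈112%).  The generator emulates this as an isotropic size factor
at fixed `B`: between `swell_start_s` and `swell_end_s` the width ratio
interpolates linearly from its current (area-conserving) value to
`swell_ratio_final`, then stays flat.  This deliberately breaks area
conservation, as the real phenomenon does, and targets the observable
(the final plateau value) rather than any particular swelling mechanism;
before `swell_start_s` the truth conserves area to 10⁻⁹.

What the simulator does **not** emulate: gravity-asymmetric spreading
shapes, bubble nucleation, illumination drift, optical distortion, or any
true Stokes-flow physics beyond the master-curve kinetics.  Passing the
closed-loop tests therefore validates the measurement chain (render →
segment → contour → fit → kinetics), not the fluid mechanics of real
filaments.

## Validation summary

The test suite checks, among others: exact morphology against a brute-force
8-neighborhood oracle on random small masks; the closed-form Booth area
against numeric quadrature (10⁻⁶); the Cartesian/polar shape identity
(10⁻⁹); constant-area identity (10⁻⁹); single-frame `B` recovery within
±0.02 on rendered noisy shapes; and end-to-end `t_vs` recovery within ±10%
for true values of 50, 80 and 120 s on 120-frame sequences.  Test sequences
use `R0_px = 100` (well above the 60 px validity floor) to keep the suite
fast; the resolution enters the accuracy claims only through that floor.

## Known limitations

- Shapes with `B < 0.1` are at the rasterization limit (see above); fitted
  values there are reported but not covered by the accuracy claims.
- `a = L_max/2` is quantized to half-pixels; for a rendered circle of odd
  pixel diameter this leaves `B` at ≈0.99 rather than exactly 1.
- The t_vs uncertainty reflects the slope's standard error only; threshold
  choice, window choice and master-curve digitization errors are not
  propagated.
- The bonding-angle description applies only while `x_neck ≤ d`; later
  frames carry NaN markers rather than extrapolated angles.
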