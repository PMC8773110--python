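# Methods

`delamod` models and measures how a corroding species travels along the
interface between a metal film and a polymer encapsulant, and how the
resulting corrosion detaches the polymer (delamination).  The application
context is lifetime assessment of polymer-encapsulated implant
electronics, studied at the bench with an accelerated copper /
polydimethylsiloxane (PDMS) / potassium-polysulfide system: the exposed
copper blackens within minutes, so the position of the corrosion front
under the polymer can be read off ordinary time-lapse photographs.

## Moving-boundary model of interface diffusion (phase I)

The interface is treated as a one-dimensional medium initially free of
solute.  At the droplet edge (`x = 0`) the bath maintains the boundary
concentration `C0`.  Corroding ions diffuse inward with interface
diffusivity `D` and are immobilized at the visible front `X(t)` by
reaction with the metal, consuming an amount `S` per unit front advance
per unit cross-section.  This is a Stefan problem:

    dC/dt = D d²C/dx²                     0 < x < X(t)
    C(0, t) = C0,   C(X, t) = 0
    S dX/dt = -D dC/dx |_{x=X}

**Heat-balance integral (HBI) solution.**  Following Goodman's method a
quadratic profile `C = a (x - X) + b (x - X)²` is required to satisfy the
boundary conditions and the spatially integrated diffusion equation.
With the similarity ansatz `X = α √t` the Stefan condition gives
`aX = -S α²/(2D)`, the bath condition `bX² = C0 + aX`, and the integral
balance collapses to one scalar equation in `u = α²`:

    C0 u / 6 + S u² / (12 D) + S u = 2 D C0.

The implementation solves this by bracketed root-finding (Brent, relative
tolerance 1e-12, initial bracket `(0, 10 √(2 D C0/S)]` with up to ten
doublings), because that is the robust general mechanism; the equation is
also a quadratic in `u`, and the closed-form root serves as an
independent oracle in the test suite.  The quasi-steady limit
`α → √(2 D C0 / S)` for `C0/S → 0` is recovered by construction, and the
profile is provably nonnegative on `[0, X]` for all parameter values.

**Surface-layer capacity `l`.**  The model admits a surface reservoir
term `l dC/dt = D dC/dx` at `x = 0`.  Under a maintained bath the surface
value is constant in time, so a finite `l` only stores `l·C0` once at
startup and does not change `α`; it is accepted, bookkept, and flagged as
having no dynamic effect.  The default is `l = 0`.

**Finite-volume oracle.**  `fd_solve` discretizes `[0, L]` into `nx`
cells (default 160, minimum 50).  Open cells update explicitly with time
step `cfl · dx²/(2D)` (`cfl ≤ 0.5`, i.e. a fraction of the stability
limit; the bath face uses a half-cell spacing, which remains monotone at
`cfl = 0.5`).  The flux through the front face — evaluated over the true
sub-cell distance from the last open cell center to the front — feeds an
accumulator; each `S·dx` of accumulated mass opens one more cell, and the
front position is `X = j·dx + acc/S`.  Because every update moves mass
between cells, the accumulator and the influx tally, the discrete balance
*influx = stored + S·X* holds to round-off and is reported on every run
(required ≤ 1e-3 relative).  The domain is sized from the HBI prediction
so the front ends about 70% across the grid.  Against the HBI closed
form the FD front agrees within 0.2% over the late half of the horizon
across a decade each of `D` and `C0/S`, comfortably inside the 5%
equivalence requirement, and its log-log slope is 0.500 ± 0.001.

## Delamination and the linear phase (phase II)

Once the metal under the polymer is corroded past the adhesion threshold,
the polymer detaches behind the visible front.  The delamination front is
modelled as trailing at a constant lag: `d(t) = max(0, X(t) - Δ)`.  The
flooded channel behind `d(t)` carries bath concentration, so the
not-yet-delaminated strip of width `Δ` acts as a fixed-width membrane;
its steady-state flux `D C0 / Δ` drives the front at constant velocity

    v2 = D C0 / (S Δ).

`fd_solve(source_lag=Δ)` checks this numerically: cells behind `X - Δ`
are clamped to `C0` each step (injected mass is added to the influx tally
so the balance audit still holds), and the late-time front slope matches
`v2` within ~5% (10% required; residual bias comes from the cell-width
granularity of the flooded region).  `Δ` is not directly observable in
the photographs and is treated as a free parameter.

## Phase segmentation

Measured traces show three segments: `α√t`, a continuous linear segment,
and a terminal jump that is an optical artifact (bulk diffusion darkens
the whole protected disk at once and the fixed threshold stops being
meaningful), not physics.  `segment_phases` therefore:

1. detects the jump on residual first-differences from the fitted
   piecewise model (iterated refit), flagging points after the largest
   difference exceeding 5 local robust (MAD) standard deviations — raw
   first differences would false-trigger on the steep early `√t` samples;
   a small absolute floor (1e-9 of the trace range) prevents truncation
   of numerically flat noise-free traces;
2. grid-searches the phase I→II changepoint `t1` over all observed
   timestamps (each phase keeps ≥ `min_seg` = 5 points).  For each
   candidate the model `s = α √min(t, t1) + v2 max(t - t1, 0)` is linear
   in `(α, v2)` and solved by least squares, so continuity at `t1` is
   built in; exactness is preferred over speed since traces have at most
   a few hundred frames;
3. falls back to the single-phase `α√t` fit when the two-phase model
   improves the SSE by less than 5% (or the single-phase fit is already
   at numerical zero).

Under the reference conditions (α = 1 px/√min, t1 = 420 min, v2 = 0.05
px/min, 5-min cadence, Gaussian pixel noise sd 0.5 px) the changepoint is
recovered within ±3 frames in ≈ 96% of replicates and the median error
is one frame.

## Imaging stage

Frames are converted to grayscale with Rec. 601 luminance
(0.299 R + 0.587 G + 0.114 B, rounded; the convention is configurable
since the original conversion is not standardized), thresholded at a
contrast margin of 90 with the boundary level counted as corroded, and
the corroded pixels inside a circular region of interest are counted and
subtracted from the ROI total; the remainder is the protected area `A`
and `r = √(A/π)`.  No morphological cleanup is applied by default (an
optional small-object removal flag exists).  `s(t) = r(t₀) - r(t)` is
reported raw and may go slightly negative under noise.  The pixel scale
of a real rig must be calibrated externally (`mm_per_px`).

## Bulk diffusivity from the tilted plate

The cuvette geometry maps position `y` on the plate to layer thickness
`h(y) = offset + y tan(tilt)` (defaults: offset 1 mm, tilt 30°).  Each
position blackens after the membrane traversal time, so
`D_i = h(y_i)² / (2 (t_i - lag))` (Einstein–Smoluchowski).  Because `h`
is linear in `y`, onset vs position is intrinsically quadratic; the
estimator restricts itself to the maximal contiguous run where onset vs
`y` is linear at R² ≥ 0.98 under an expanding-window fit — the regime the
optical readout supports — and averages `D_i` arithmetically over it.
The lag is either supplied or fitted as the intercept of the onset vs
`h²` regression over that interval (default: fitted; the mode is always
recorded).  A flat plate (no thickness variation) is rejected as a
degenerate regression, and a lag that leaves non-positive diffusion
times is rejected with the offending rows named.

The spot value 1.676e-6 cm²/s for a 1 mm membrane traversed in 2983 s
pins the estimator's arithmetic in the tests; it is an arithmetic anchor,
not an empirical claim about any particular specimen.

## Failure-route competition

`predict_merge` compares the time for the composite interface front
(phase I until `X = Δ`, then the membrane velocity `v2`) to traverse the
droplet radius `r0` against the lag-free bulk breakthrough time
`cover_thickness²/(2 D_bulk)`; the earlier route labels the failure mode
("interface" or "bulk"; "none" if neither is finite).  The constant-lag
construction requires `Δ` explicitly, so it is an argument alongside the
Stefan parameters.

## Synthetic-data generator

The generator emulates the two experiments with known ground truth: a
shrinking bright disk (protected metal) inside a dark corroded annulus,
rendered at the study conditions by default — droplet radius 15 mm at
0.05 mm/px (300 px), frames every 5 min — with additive i.i.d. Gaussian
pixel noise, an optional linear illumination ramp (the simplest stress on
a global threshold), and colors chosen so the margin-90 rule separates
the classes under Rec. 601 (protected (200, 110, 50) ≈ level 130,
corroded (35, 25, 20) ≈ level 27, background (120, 120, 120)).  Phase III
is rendered as abrupt whole-disk darkening.  It does **not** reproduce
droplet-edge waviness, partial-corrosion color rings, the wax-like
surface film, or spatially correlated illumination drift — so passing
round-trip tests demonstrate the correctness of the pipeline's geometry
and counting, not robustness to every optical artifact of a real rig.
The cuvette generator returns onsets exactly consistent with
`t = lag + h²/(2D)` plus optional multiplicative noise.

## Numerical and scale choices

- Units: minutes and mm/px in all files; seconds and cm internally for
  physics.  Every CLI output echoes its configuration hash, seed and
  package version; identical configs give byte-identical outputs.
- Test and validation problem sizes — 27-point solver grid at `nx` = 160,
  100-frame image series at 672², 100-replicate Monte Carlo runs —
  complete the whole suite in about a minute on one core while leaving
  large margins to every tolerance.
- Degenerate inputs are rejected fail-fast with field-level messages
  (empty windows, single frames, flat plates, fronts beyond the droplet
  radius, CFL violations, non-8-bit images).

## Known limitations

- The model is one-dimensional; front curvature of the circular droplet
  is neglected (radial corrections would matter once `s` is comparable
  to `r0`).
- `D`, `C0`, `S` and `Δ` are not separately identifiable from a front
  trace alone: phase I constrains `α(D, C0/S)` and phase II constrains
  `D C0/(S Δ)` only.
- The `l > 0` surface-reservoir mode is bookkeeping only (see above) and
  is flagged experimental.
- Phase III is excluded, not modelled; traces whose artifact jump is
  smaller than 5 local SDs of the noise will not be truncated.
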