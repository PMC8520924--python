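# Methods

This note documents the models implemented in `lymphchip`, their
assumptions, the default parameters and why they were chosen, the
numerical schemes, and what the synthetic-data generators do and do not
emulate.

## Device model

The chip is described parametrically: an ECM (gel) channel of 2 × 1 mm
and medium channels of 4 × 1.2 mm (width × height), medium reservoirs
punched at 4 mm and ECM reservoirs at 1 mm diameter, two reservoirs per
channel. The channel length is not a fabrication constant of the design
we model; it defaults to 10 mm, is always configurable, and every result
that depends on it (decay timescale, interface area) reports it in its
output metadata.

Configurations are YAML or JSON with a versioned `schema_version` field.
Quantities accept explicit unit suffixes (`2 mm`, `10 um`, `1.04e-13
m^2`) and are stored SI internally; save→load round-trips are
bit-identical because floats are serialized at full precision.

The Stokes–Einstein helper `D = kT/(6πμR_h)` takes either an explicit
hydrodynamic radius or a molecular weight, converted with the dextran
power law `R_h[nm] = 0.0488·MW[Da]^0.437`. At 40 kDa, 310 K and medium
viscosity 0.7 mPa·s this gives 6.5×10⁻¹¹ m²/s, which is adopted as the
default gel diffusivity for the 40-kDa tracer — the value that also
places the Péclet endpoints at ≈3 and ≈15 for the measured velocity
range (see below). The 10-kDa tracer defaults to 1.4×10⁻¹⁰ m²/s by the
same correlation.

## Capillary pinning vs. filling

During gel loading the advancing COL1 precursor meniscus pins at the
step edge between ECM and medium channels. We model the maximum
sustainable pressure with the rectangular-channel Young–Laplace burst
form

    P_meniscus = −2σ (cos θ*_h / h + cos θ*_w / w),

where each wall's apparent contact angle is Gibbs-augmented by the edge
expansion angle, `θ* = min(θ + β, 180°)`, and negative (wicking) values
are clamped to zero. This is a modelling choice: it is the standard
capillary-burst-valve description for rectangular cross-sections.
Defaults: σ = 0.072 N/m, θ = 110° on all walls (hydrophobic,
polydopamine-coated and heat-dried PDMS; the exact post-treatment angle
is not known), β = 90°. With θ* saturated at 180° the 2 × 1 mm channel
holds 216 Pa.

The opposing filling pressure is the aspect-ratio-corrected rectangular
Poiseuille drop `ΔP = 12 μ L Q / (w h³ (1 − 0.63 h/w))`, evaluated in
the worst case at the fully filled channel length. COL1 precursor
viscosity is not a tabulated constant; default 0.01 Pa·s, configurable.
The stability map evaluates both pressures over a fill-rate sweep and
locates the critical rate (margin = 0) by Brent bisection at relative
tolerance 10⁻⁶ when the scanned range brackets a transition. With the
defaults, filling is stable over the whole practical 0.1–100 µl/s
range — the margin is monotone decreasing in rate, so there is at most
one stable→burst transition.

## Interstitial flow

Gel and endothelial monolayer are porous layers in series under Darcy's
law; the superficial velocity under head difference Δh is

    v = ρ g Δh / (μ R),   R = Σᵢ Lᵢ / Kᵢ.

Darcy permeabilities: COL1 gel 1.04×10⁻¹³ m², lymphatic endothelium
2.46×10⁻¹⁶ m². The monolayer thickness is taken as 10 µm (a typical
endothelial monolayer height) and the applied head as 3 mm of water;
this pair reproduces an initial velocity of 0.49 µm/s across the 2-mm
gel path, the operating point of the stimulation protocol.

In a closed two-reservoir device the head relaxes exponentially with
timescale `τ = μR / (ρ g A_int (1/A₁ + 1/A₂))`. We integrate the paired
reservoir levels with classical fixed-step RK4 (default dt = 60 s); the
ODE is linear, so the integrator tracks the closed form to better than
10⁻⁸ relative over 24 h, and the transferred volumes of the two
reservoirs balance to round-off. The geometric τ (≈2.1 h with the
default 10-mm channel) is much shorter than the observed 24-h velocity
window 0.49→0.09 µm/s, which is expected: medium is topped up during
culture and the effective interface area depends on the unprinted
channel length. `head_decay` therefore reports τ in its metadata and
`calibrate_tau` fits τ directly to a measured (v(0), v(t)) pair,
`τ = t / ln(v₀/v_t)`; the end-to-end pipeline uses the calibrated τ by
default so that reported Péclet ranges reflect the device's operating
window. `Pe = vL/D` uses the ECM channel width (2 mm, the solute's
traverse distance) as its default length scale.

## Solute transport

One spatial dimension suffices for the channel–gel–monolayer path; the
solver is cell-centered finite volume with per-layer diffusivities.
The endothelial monolayer is not resolved as cells: it enters as an
interface conductance `P_m` (default 10⁻⁸ m/s for growth-factor-scale
solutes) added in series with the adjoining half-cell resistances.
This avoids a 200:1 cell-size contrast and is exactly equivalent in the
series-resistance sense.

Face fluxes use the exponential-fitting (Scharfetter–Gummel) scheme,
`F = G[B(−Pe_f)c_i − B(Pe_f)c_j]` with `B(x) = x/(eˣ−1)` and
`Pe_f = v/G`. The scheme is monotone (discrete maximum principle holds
for all source-free runs), reduces to central diffusion at v = 0, and is
nodally exact for piecewise-constant coefficients at steady state. We
chose it over plain first-order upwinding as the default because upwind's
numerical diffusion at the device's operating point (Pe ≈ 15) leaves a
~0.7 % profile error at 400 cells, while the exponential scheme meets
the same benchmark at round-off; upwind is retained as an option and is
cross-checked against the closed forms in the tests. Time stepping is
backward Euler on a prefactorized sparse system (unconditionally
stable); an explicit mode is kept for cross-checks and refuses steps
above its stability bound with a message recommending implicit mode.
Snapshots default to every 3 h, the cadence at which tracer
distributions are monitored experimentally.

Boundary conditions: fixed concentration by default (reservoirs
refreshed daily hold the source at c = 1 and the sink at 0), `closed`,
or finite well-mixed reservoirs whose concentration evolves with the
boundary flux (for long unrefreshed runs). The coordinate origin is the
lymphangiogenic-factor-channel/gel interface, positive toward the
stimulated channel, velocity positive in the same sense.

Analytic references used as oracles: the two-layer steady solution
(linear in the gel with a monolayer drop fraction
`(1/P_m)/(L/D + 1/P_m)`; 0.765 with the defaults, hence the steep
concentration decrease over the endothelium) and the uniform-coefficient
advection–diffusion profile `c(x) = (e^{Pe·x/L} − e^{Pe})/(1 − e^{Pe})`
(mid-gel value 0.9994 at Pe = 15 — the convectively flattened
gradient). Secretion against the flow is quantified by solving the
steady problem with a thin interior source and absorbing ends; the
upstream mass fraction is 1/2 at v = 0 by symmetry and decreases
monotonically with Pe, dropping to ≈0.12 at the Pe ≈ 15 operating point.

## Morphometry

Shape metrics per 8-connected component: area (pixel count), perimeter,
circularity `4πA/P²` clamped at 1, aspect ratio and orientation from
the second-central-moment equivalent ellipse (orientation reported in
degrees from the +x image axis, [−90, 90)). The perimeter estimator is
a smoothed subpixel contour length — Gaussian blur at σ = 1.5 px, then
marching-squares contour at the 0.5 level — because pixel-edge step
counting biases circularity low for smooth shapes (disk ≈ 0.91) and
Crofton-style estimators bias squares high (≈ 0.88): the smoothed
contour recovers a rasterized disk at 0.998 and a square at 0.796.
Components under 20 px (configurable) are treated as noise;
border-touching components are flagged.

Orientation statistics treat cell-axis data as axial (180°-periodic):
angles are doubled before computing the circular mean and resultant
length, then halved back. Sprout quantification takes a binary gel mask
and the interface column: structures touching the interface (within
1 px) are sprouts, their distance the maximum perpendicular extent and
their direction the base-centroid→tip angle; structures not connected
to the interface are counted separately as single-cell migration events
and excluded from sprout distances. Both the per-sprout mean and the
image maximum distance are reported, since either convention is found
in practice.

## Assays

Comparative Ct: `ΔCt = Ct_target − Ct_housekeeping` per sample,
`ΔΔCt = mean ΔCt(group) − mean ΔCt(control)`, `fold = 2^(−ΔΔCt)`, with
amplification efficiency fixed at 2 (no efficiency correction).
Replicates are aggregated as the mean ΔCt per group; per-replicate folds
are also emitted for dispersion estimates. Samples lacking a
housekeeping measurement are dropped with a warning. The calculation is
invariant to row order and to any global Ct shift.

The 4PL standard curve `y = d + (a − d)/(1 + (x/c)^b)` is fitted by
least squares in (a, d, log c, b) with multi-start initialisation:
asymptotes from the response extremes, c from the concentration nearest
mid-response, plus seeded jittered restarts (default 8 starts, seed 0).
Inverse prediction `x = c((a−y)/(y−d))^{1/b}` checks its argument
against the open asymptote interval and raises a diagnostic error
outside it; degenerate (constant-response) data raise rather than
returning an unidentifiable fit.

## Synthetic data

All generators are pure functions of (parameters, seed) using numpy's
`default_rng`; every artifact carries a ground-truth manifest consumed
directly by the test suite. Ellipse masks draw non-overlapping rotated
ellipses (largest first, rejection placement) with axial von Mises
orientations; mask noise flips boundary pixels only, mimicking
segmentation jitter without breaking connectivity. Sprout fields draw
interface-connected fingers column by column so the true perpendicular
extent is exact to the pixel, with a von Mises directional bias and
optional disconnected blobs emulating single-cell migration. Intensity
series render a transport solution as a constant-transverse-profile
image stack at the 3-h cadence with additive Gaussian noise. Ct tables
encode fold changes as `Ct = baseline − log₂(fold) + noise`; OD plates
apply the 4PL forward model at a dilution series spanning the
inflection.

What the generators do **not** emulate: optical point-spread functions,
photobleaching, uneven illumination, segmentation errors beyond boundary
jitter, cell–cell contact in masks, pipetting gradients across plates,
or amplification-efficiency drift in qPCR. Passing the recovery tests
therefore demonstrates the correctness of the quantification pipeline on
idealized inputs, not robustness to every real-microscopy artifact.

## Problem sizes and tolerances

Steady-state oracle comparisons use 400 cells (L∞ ≤ 0.5 %); grid
convergence is checked at 50→200 cells against a 1600-cell reference;
transient conservation runs use 40–100 cells over 1–24 h at dt = 60–600 s.
Morphometry recovery uses 200 ellipses across eight 1200² masks and 50
seeded sprout fields; assay recovery uses 50 plates (σ_OD = 0.02) and
200 Ct tables (σ_Ct = 0.3, n = 3). Bisection tolerance for the critical
fill rate is 10⁻⁶ relative; head-decay agreement with the closed form is
required at 10⁻⁸ relative and reservoir volume balance at 10⁻¹⁰.

## Known limitations

- The transport model is strictly 1D series-resistance; no lateral
  gradients, gel remodeling, cellular uptake, or binding kinetics.
- The pinning model is quasi-static; no dynamic contact-line or meniscus
  shape evolution.
- The head-decay geometry assumes two identical reservoir pairs and no
  topping-up; operating-point analyses should use the calibrated τ.
- Wetting parameters after surface treatment are estimates; stability
  conclusions should be re-checked with measured contact angles where
  available.
- Sprout direction angles are defined from base centroid to tip, which
  compresses strongly curved sprouts onto a single angle.
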