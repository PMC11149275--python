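# Methods

## Indentation model

The specimen is modeled as a homogeneous, isotropic, linearly elastic
layer of thickness *h* bonded to a rigid half-space, indented by a rigid
flat-ended cylinder of radius *R* (default 525 μm). The indentation
modulus is E = P(1 − ν²) / (2 R x₀ κ(α, ν)) with α = R/h. Poisson's
ratio defaults to ν = 0.4 (per-specimen override allowed); ν = 0.5 is
excluded because the incompressible bonded layer is singular. The bonded
(adhesive) layer–substrate condition is implemented; the frictionless
variant is out of scope, since cartilage is physically attached to the
subchondral plate.

### The κ(α, ν) correction

In Hankel space the bonded layer's surface compliance relative to a
half-space is, with x = ξh and k = 3 − 4ν,

    W(x) = (2k sinh 2x − 4x) / (2k cosh 2x + 4x² + k² + 1).

This expression was derived independently with a symbolic Love-function
solution of the layer-on-rigid-base boundary-value problem (normal
pressure on the free surface, zero displacement at the bonded face) and
is checked in the test suite against frozen values from that derivation.
The flat-punch mixed boundary-value problem then reduces, via the
Lebedev–Ufliand cosine-transform substitution, to a Fredholm integral
equation of the second kind on the normalized punch radius t ∈ [0, 1]:

    ω(t) − (1/π) ∫₀¹ [K(t + s) + K(t − s)] ω(s) ds = 1,
    K(u) = α ∫₀^∞ (1 − W(y)) cos(α u y) dy,       κ = ∫₀¹ ω(t) dt.

Numerics:

- **Production solver** — Nyström discretization with trapezoidal
  weights at uniform step 0.01 (101 nodes); the kernel argument |t ± s|
  falls on the same grid, so K is evaluated once per solve at 201
  points. The kernel integrand decays like y²e^(−2y); it is integrated
  by 16-point Gauss–Legendre panels to y_max = 40 with panel width
  shrunk as α grows so the cosine is resolved. Doubling y_max changes κ
  by < 1e-6 (tested); halving the step changes κ by < 0.2% on the whole
  test grid.
- **Oracle** — an independent fine-mesh solve at steps 0.002 and 0.001
  with y_max = 80, Richardson-extrapolated (trapezoid error is O(h²)).
  Production vs oracle agrees within 0.5% at spot points spanning
  α ∈ [0.5, 8], ν ∈ [0, 0.45].
- Solves are memoized; `build_kappa_table`/`interpolate_kappa` provide a
  bilinear lookup for cohort work. κ is convex in ν approaching 0.5 and
  in α, so the 0.5% interpolation budget requires grid spacings of about
  0.05 in α and 0.0125 in ν over the physiological range; the table
  refuses to extrapolate outside its hull.

Validation relies on the analytic structure rather than published
tables: κ → 1 as α → 0 (half-space), κ ≥ 1 everywhere, monotone
non-decreasing in α, and non-decreasing in ν for α ≥ 0.5.

## Protocol and phase segmentation

The protocol is 0.1 N preload (≈115 kPa nominal contact pressure), ramp
at 25 μm/s to 50 μm, 13 s hold, unload at 25 μm/s. The detector
estimates the displacement rate from a moving-median (window 5) followed
by a short moving average (~0.09 s, configurable) and central
differences; a plain 5-sample median leaves far too much rate noise at
realistic sampling rates (0.2 μm displacement noise at 100 Hz gives
~8 μm/s rate noise against a 10 μm/s classification band). Samples are
classified as loading (rate within ±40% of +25 μm/s), hold (|rate| <
10%), or unloading (±40% of −25 μm/s), all tunable. Each boundary is
then refined to the sample nearest the intersection of the fitted ramp
line with the adjacent displacement plateau; on noise-free protocol
curves this is exact to the sample, and with 0.2 μm noise it stays
within ±3 samples. Failure to find a ramp signature, a <30% depth rise,
or a hold shorter than half the protocol duration raises a "protocol
mismatch" segmentation error.

**Preload baseline.** Phase extraction re-zeroes displacement *and* load
to the end-of-preload state, so both moduli are incremental above the
0.1 N preload. For a linear material this is exact; keeping the preload
in P would bias E_eq by ≈1.6/κ MPa at x₀ = 50 μm, which is comparable to
the moduli themselves. The behavior is configurable (`rezero_load`).

## Slope fit, QC, equilibrium

- Savitzky-Golay smoothing of the load channel; window defaults to the
  odd number nearest 5% of the phase length (minimum 11), polyorder 3 —
  wide enough to suppress sensor noise, short enough to preserve ramp
  curvature. Endpoints use the filter's one-sided polynomial fit, so the
  series length never changes.
- "Upper 35%" is interpreted on the displacement span: the OLS fit of
  load on displacement keeps samples with x ≥ 0.65·max(x). Displacement
  is the controlled variable in strain-controlled indentation, so this
  is the natural reading; the fraction is a parameter.
- QC: fits with R² < 0.80 (strict inequality) are rejected with a
  recorded reason and excluded from statistics.
- Equilibrium: mean load and displacement over the final 10% of the
  hold. The residual |dP/dt| over the tail is reported so incomplete
  relaxation (long τ vs the 13 s hold) is visible rather than silent.
  For SLS material with τ ≤ 2 s the tail mean is within 1% of the true
  asymptote.

## Synthetic data

The generator simulates a standard linear solid,
G(t) = E_∞ + (E₀ − E_∞)e^(−t/τ), under the exact protocol trajectory.
Load is the hereditary integral of G against the displacement rate,
mapped to force by the same Hayes factor 2Rκ/(1 − ν²) the analysis
inverts; ramp/hold/unload segments use the closed-form integral, so
there is no convolution error. The preload is equilibrated against E_∞
and held for a 2 s dwell. Default cohort structure mirrors the study
design: groups of n = 10, E_∞ means drawn per group (truncated normal),
stiffening ratio E₀/E_∞ = 3, τ = 1 s, all randomness from one seed.

Because the generator shares κ with the analysis, modulus recovery is a
units-and-plumbing check, not an independent validation of the Hayes
solution — that validation is the kernel/oracle battery above. The
surrogate is phenomenological: it reproduces ramp-rate stiffening and
stress relaxation but not biphasic (poroelastic) flow, contact
nonlinearity, tissue heterogeneity, or surface roughness, so passing
recovery tests bounds pipeline error, not model error on real tissue.

## BV/TV

Voxels are binarized by a fixed threshold or Otsu's two-class histogram
method (the value used is always logged; automatic mode errors on
constant volumes). The cylindrical ROI (defaults 5 mm diameter × 5 mm
depth, matching the defect) includes a voxel iff its center lies inside
the cylinder — no partial-volume weighting, which keeps the mask exactly
testable; at 0.05 mm voxels the count is within 2% of the analytic
cylinder volume (measured: 0.08%). BV/TV is a pure voxel-count ratio.

## Statistics

Mean ± SD uses the n−1 denominator. One- and two-way fixed-effects ANOVA
are fitted by OLS (statsmodels); two-way fits include the interaction
and require a balanced design — unbalanced input falls back to one-way
per factor with a logged warning rather than silently choosing a
sum-of-squares type. Tukey's HSD is computed directly from the
studentized-range distribution with Tukey–Kramer standard errors
(significance strict p < 0.05); statsmodels' and scipy's implementations
serve as independent oracles in the tests, and a vectorized
maximum-studentized-range helper (decision-equivalent by construction,
verified against the per-pair route) makes the 2000-replicate null
simulation of the family-wise error rate cheap. MANOVA is not
implemented. Ordinal histology scores can be entered as outcome tables,
but no ordinal-specific methods are provided.

## Problem sizes and determinism

Tests and the acceptance script use 50–100 Hz sampling (ramp-hold
records of ~1000–1900 samples), 27-point parameter sweeps, cohorts of
n = 4–10 per group, 100-fixture property sweeps, 20×20×20–120³ voxel
phantoms, and 2000-replicate null simulations; these sizes give
Monte-Carlo error well below every tolerance asserted. All stochastic
tests are seeded; reports are byte-identical across reruns of the same
configuration and seed.

## Known limitations

- The elastic-layer inversion yields effective moduli; no poroelastic
  material parameters (permeability, aggregate modulus) are estimated
  from the transient.
- κ assumes a flat, uniform-thickness layer normal to the indenter;
  curvature and thickness error propagate directly into α.
- Thickness *h* must be supplied per specimen; there is no default.
- The ROI's axial placement relative to the articular surface is a user
  decision (`depth_start_mm`).
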