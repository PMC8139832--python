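# Methods

## The two-state dispersal model

The model describes a secreted ligand that exists in two interconverting
pools: freely diffusing molecules in the intercellular space and molecules
bound to discrete cell-surface docking sites (heparan-sulfate clusters and
similar scaffolds). In one spatial dimension,

    ∂u/∂t = D ∂²u/∂x² − a(x)·u + b·v + g(x)      (free pool)
    dv/dt =             a(x)·u − b·v − c·v        (bound pool)

on 0 ≤ x ≤ L with no-flux (Neumann) boundaries at both ends. The bound pool
does not diffuse. Parameters, with defaults used throughout:

| symbol | meaning | default | units |
|---|---|---|---|
| D | free-diffusion coefficient | 20 | µm²/s |
| a(x) | binding rate field, nonzero on docking sites | amplitude 10 | 1/s |
| b | release (dissociation) rate from sites | 0.1 | 1/s |
| c | internalization rate of bound ligand | 0.1 | 1/s |
| g(x) | production, confined to [0, R) | g_max = 0.2 | amount/s |
| R | source width | 1 (= L/1000) | µm |
| p1, p2 | docking-site interval and width | 2, 0.2 | µm |
| L | domain length | 1000 | µm |

The defaults are the reference study conditions: D matches the fast
(FCS-measured) diffusing component of a tagged Wnt ligand, and the b, c
variations (c = 0.01; b = 0) are the scenarios whose decay lengths are the
package's headline numbers. Both fields carry the same per-node "amount"
units; no volume conversion between the 1-D line and a tissue volume is
attempted.

Steady-state bound peaks decay as c(x) = c0·exp(−x/λ). Averaging a(x) over a
period gives the analytic cross-check λ_hom = sqrt(D(b+c)/(ā c)) with
ā = a_max·p2/p1: eliminating v at steady state yields
u'' = (ā c)/(D(b+c))·u away from the source. For the defaults
λ_hom = √40 ≈ 6.32 µm, within 0.5% of the simulated 6.35 µm. The formula
requires c > 0; with c = 0 nothing removes ligand and no exponential steady
state exists.

## Numerics

Explicit forward-Euler with a centred Laplacian; reference steps dx = 0.1 µm,
dt = 1e-4 s (stability number D·dt/dx² = 0.2, checked at start; integration
aborts on non-finite values). Neumann boundaries are mirrored ghost nodes
(u[−1] := u[1]), the standard second-order treatment. The inner loop is a
numba kernel with fastmath disabled so runs are bit-reproducible; a
pure-numpy single step (`step_forward`) is kept as a reference path and the
two are cross-checked in the tests.

Node membership of intervals is the load-bearing discretisation choice. A
node represents a cell of width dx, so docking sites and the source region
are half-open ([p1·n, p1·n + p2), [0, R)): each site then covers exactly
p2/dx nodes and the mean binding rate equals ā = a_max·p2/p1. Closing both
ends would add one node per site (ā = 1.5 instead of 1.0 at the defaults)
and steepen every gradient by √1.5 — a 22% error in λ. The production node
at x = 0 carries double amplitude: under the mirrored boundary, node 0
represents only a half-cell, and including its image source makes the total
discrete production exactly g_max·R. With that convention the steady-state
flux balance (production = c·∫v dx) closes to better than 0.1%; the scheme
conserves the trapezoid-measure mass exactly (drift ~1e-15/s with g = c = 0).

The simulation protocol for the reference decay lengths deliberately stops at
t = 100 s, not at true steady state. The baseline and no-release scenarios
are effectively converged there; the slow-internalization scenario
(c = 0.01) is not — its fitted λ = 10.79 µm sits well below the steady-state
prediction of 14.83 µm, and that finite-time value is the quantity the
protocol defines. Peaks are fitted over x in (R, 100] µm — excluding the
source region and matching the displayed gradient window — by unweighted
nonlinear least squares on the untransformed values (initial guesses: first
peak value and the two-point log-slope). A log-linear estimator is provided
as a cross-check utility only, since it would re-weight errors on the small
tail values.

Steady-state detection compares successive snapshots node-wise,
|Δf|/(|f| + ε), with ε set to 1e-4 of the field maximum so that
numerically-zero tail nodes (which keep doubling from tiny values for a long
time) do not mask convergence of the actual gradient.

The in-silico photoconversion variant tags the sub-population inside a
window of a near-steady state and evolves it with the same D, a(x), b, c and
zero production. Because the equations are linear, the labelled pool evolves
independently of the total; both are integrated side by side.

## FDAP analysis

Traces are normalized red-channel intensities from a 1.66 µm-wide strip,
400 frames at 25 frames/s after photoconversion. Photobleaching is corrected
by dividing frame n by q^n; q defaults to 0.9991 per scan and can be
re-estimated from an immobilized (fixed-sample) control with
`PhotobleachControlModel` (pure q^n fit).

Two fitted models:

* **Dissociation (reaction-dominant):** I(t) = C + (1−C)·e^(−k_off·t), with
  immobile fraction C and off-rate k_off. Degenerate traces (fitted mobile
  amplitude 1−C below 1e-3) are flagged `k_off_identifiable = False` rather
  than reported as precise. Fit quality is summarised by SSE, R², the largest
  residual and the fractions of residuals within 0.05 and 0.10 — the bands
  used to judge FDAP fits in practice.
* **Effective diffusion:** free 1-D diffusion of the photoconverted top-hat,
  averaged over the same strip. With half-width w and s = √(4·D_a·t),

      I(t) = erf(2w/s) − s/(2w√π)·(1 − e^(−4w²/s²)),

  which satisfies I(0) = 1 and decays like 1/√t. The closed form was derived
  by integrating the error-function solution over the strip and is validated
  in the tests against a direct finite-difference simulation of the same
  initial condition (recovered D within ~1% on noiseless data). An optional
  immobile offset C can be freed.

Identifiability has hard limits the package reports rather than hides: from a
16-s window with 2% noise, off-rates around 0.01 s⁻¹ (half-life ~69 s) are
not recoverable by any estimator — the Cramér-Rao bound on the relative error
exceeds 150% because only the product (1−C)·k_off is constrained. Parameter-
recovery checks therefore quote pooled medians over a grid of conditions, and
the fitter is separately verified to sit near the information bound on the
identifiable part of the grid.

## FCS analysis

The autocorrelation model for a 3-D Gaussian detection volume (lateral 1/e²
radius w0, structure parameter S = z0/w0, default 5) is

    G(τ) = 1 + (1/N)·T(τ)·Σᵢ Fᵢ·(1 + τ/τᵢ)⁻¹·(1 + τ/(S²τᵢ))^(−1/2)

with one or two diffusing components and the triplet factor
T(τ) = 1 + T/(1−T)·e^(−τ/τ_trip). N is the mean particle number in
V_eff = π^(3/2)·w0²·z0 (instrument presets 0.3 fl and 0.12 fl);
D = w0²/(4τ_D) after calibrating w0 on Rhodamine 6G (D = 280 µm²/s).

Fitting is bounded least squares in log-space for N and the diffusion times,
multi-started from a heuristic guess (amplitude → N, half-decay lag → τ) plus
seeded random starts; bounds N ∈ (1e-3, 1e4), τ ∈ (1e-6, 1) s,
T ∈ [0, 0.5], τ_trip ∈ (1e-6, 1e-2) s. Model comparison uses the
least-squares AIC, n·ln(SSE/n) + 2k, with ties broken toward fewer
parameters; only ΔAIC matters, so the additive constant convention is
irrelevant. Quality filters drop fits with D_fast > 80 µm²/s (dark-state
blinking masquerading as ultrafast diffusion) and two-component fits with
D_fast/D_slow < 3 (configurable), where F_fast is meaningless because the
components are degenerate.

The multi-tau correlator uses 16 channels per octave with successive
factor-2 binning and symmetric normalization (lag-product mean divided by
the means of the two overlapping windows). A constant trace yields G ≡ 1.
Optionally the trace is split into segments and the per-lag standard error
across segments is attached as fit weights.

Two options exist specifically because finite simulated ensembles differ
from an embryo: `fit_baseline` frees an additive long-lag offset, and
`lag_range` restricts the fitted lags. A closed periodic box with exactly M
particles depresses G by ≈ 1/M at lags below the box-crossing time
(number fluctuations in the detection volume are not Poisson when the total
is fixed); below that crossover the deficit is constant and a free baseline
absorbs it exactly. Real measurements, with an effectively infinite
reservoir, do not need either option, though baseline fitting is common
instrument practice anyway.

## Synthetic data: what it emulates, and what it does not

All generators draw from named PCG64 streams (`RNGSpec(seed, stream)`); the
same seed and stream give bit-identical output on any platform.

* **FDAP traces:** I_n = (C + (1−C)e^(−k_off·n/fps))·q^n + ε_n with Gaussian
  ε. The noise default σ = 0.02 is a calibration choice — the reference
  measurements publish only their residual bands ("mostly within 5%, all
  within 10%"), and σ = 0.02 reproduces exactly that band structure. Real
  traces additionally contain occasional vesicular-internalization events;
  these are excluded manually upstream in practice and are not simulated.
* **Brownian photon traces:** point emitters random-walk
  (per-axis steps N(0, √(2D·dt))) in a periodic box and emit Poisson photons
  with rate brightness·exp(−2r²/w0² − 2z²/z0²). The box is a cuboid with
  axial edge S times the lateral edge, mirroring the elongated detection
  volume — a cube either clips the PSF axially or wastes particles. Defaults
  (lateral edge 1.5 µm = 7.5·w0, 228 particles ⇒ mean occupancy 3.0 in
  V_eff, dt = 2.5e-5 s = τ_fast/20, 10 s duration, brightness 3e5 counts/s)
  give full-pipeline recovery of D and N within ±10% across seeds. Triplet
  blinking is a position-independent two-state telegraph process with
  equilibrium dark fraction T and relaxation time τ_trip. Not emulated:
  detector afterpulsing, slow drift from bleaching of immobile material
  (flagged in real data, rejected here by construction), and scanning
  geometry beyond a static Gaussian volume.
* **Noisy gradients:** multiplicative lognormal noise on bound-peak series.

Passing the recovery tests therefore shows the estimators are correct and
near-efficient for data with this statistical structure; it does not certify
performance against instrument artifacts the generators do not model.

## Design choices where the design was open

* The random docking-site scenario draws per-site amplitudes as |N(0, σ)|
  with σ = a_max·√(π/2), so the half-normal mean equals the configured
  amplitude; the distribution's scale was otherwise unspecified.
* The explicit forms of the two FDAP fitting equations were chosen as the
  standard reaction-dominant exponential and the strip-averaged top-hat
  diffusion solution; both are consistent with the published parameter names
  and are validated against independent simulations in the tests.
* The degenerate-component exclusion threshold (D_fast/D_slow < 3) makes the
  qualitative rule "virtually the same D_fast and D_slow" operational; it is
  a configurable default, not a measured constant.
* Decay-length fits use peaks in (R, 100] µm; the exact peak set behind the
  published fits is not recorded, and the sub-percent agreement obtained
  suggests the choice matches.
* The CLI exposes the library verbs (`simulate`, `fit-decay`, `fdap-fit`,
  `fcs-fit`, `generate`, `scenarios`); the `scenarios` report compares each
  fitted λ to the homogenized closed form rather than to fixed constants.

## Problem sizes used in the checks

Full-resolution decay lengths use the reference protocol exactly
(10 001 nodes, 10⁶ steps, ~15 s each with the compiled kernel). Supporting
checks run on reduced domains chosen so each property is still cleanly
measurable: conservation and photoconversion invariants on L = 50 µm, flux
balance on L = 300 µm (the gradient is ~e⁻³⁰ of its peak at the far
boundary, so truncation is immaterial), refinement studies at dx ∈
{0.1, 0.2} µm, and Brownian FCS pipelines at 10-s traces. The dissociation
recovery grid uses 200 traces per (k_off, C) combination; AIC selection
power uses 100 replicates per direction.

## Known limitations

* 1-D geometry only; no tortuosity/hindered-diffusion modelling of the
  intercellular space, and no receptor-level signalling downstream of the
  scalar internalization rate c.
* The slow-internalization decay length is protocol-defined (t = 100 s), not
  a steady-state property; treating it as one would overestimate the range.
* FCS concentration conversion assumes the ideal 3-D Gaussian volume; real
  point-spread functions deviate at the few-percent level.
* The closed-box correction options (baseline, lag range) are analysis-side
  remedies for a simulation-side artifact; a grand-canonical simulation
  (particle exchange at the boundaries) would remove the artifact at the
  source and is not implemented.
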