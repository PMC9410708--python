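# Methods

## The nested-osmometer model

The cell and its nucleus are modelled as two nested spherical osmometers.
Each compartment contains an amount `N` of osmotically active
macromolecules (colloids that cannot cross the bounding membrane — for the
nuclear envelope, particles above its ~2.5 nm passive diffusion limit), a
non-osmotic "dry" volume `b` unavailable as free water, and a membrane
under effective tension `sigma`. Small membrane-permeant osmolytes (ions,
glycerol) equilibrate freely and drop out of the balance. At steady state
the colloid osmotic pressure jump across each membrane balances its Laplace
pressure:

    (C_cy − C_out) · R T = 2 σ_C / R_C        (cell surface)
    (C_n  − C_cy ) · R T = 2 σ_N / R_N        (nuclear envelope)

with `C_cy = N_cy/(V_C − V_N − b_cy)`, `C_n = N_n/(V_N − b_n)` and
`R_X = (3 V_X / 4π)^(1/3)`. Units: concentrations in mOsm (≡ mol/m³),
volumes in µm³, tensions in N/m, temperature in K (default 303.15 K, the
30 °C culture temperature). Osmolyte amounts are carried as
concentration × volume (mOsm·µm³; 1 mOsm·µm³ ≡ 6.022 × 10⁵ particles), which
makes the zero-tension law `V − b = N/C` exact arithmetic.

**Solver.** For fixed cell volume the nuclear balance residual diverges to
+∞ as `V_N → b_n` and to −∞ as `V_N → V_C − b_cy`, so a bracketed root
always exists; the outer cytoplasmic residual is likewise bracketed on
`(b_C, 10·(N_cell/C_out + b_C))`. Both one-dimensional roots are found by
Brent's method at relative tolerance 1e−12 on volumes. No Jacobian is
needed and convergence is guaranteed whenever a physical steady state
exists; a hypertonic medium so concentrated that the free volume collapses
raises a `SteadyStateError` naming the failing bracket. A brute-force 2-D
residual-grid search is kept as an independent oracle in the test suite.

**Closed form and sensitivity.** With `σ_N = 0` and matched normalized dry
volumes (`b_N/V_N,iso = b_C/V_C,iso`, equivalently `b_N = (N_n/N_cell)·b_C`),
the N/C volume ratio collapses to `N_nucleus/N_cell`, independent of the
external osmolarity — the osmotic explanation of N/C-ratio robustness.
Shock sensitivity is scored as `(max − min)/iso` of the N/C ratio over an
osmolarity sweep (default: C_iso/C_out log-spaced over [0.5, 2], 41 points;
recorded in the output). In the phase diagram the dry-volume ratio
`ν_bC/ν_bN` is realized by fixing `b_C` and solving `b_N` from the
zero-tension isotonic state, where `V_C` is independent of `b_N`; the
parameterization is exact at zero tension and a controlled approximation
otherwise. Both compartments are treated as spheres; wall elasticity and
nuclear shape changes are out of scope, and `σ_C` is a single effective
tension scalar.

## Boyle–Van't Hoff analysis

Shift records are mapped to BVH coordinates `x = C_iso/C_out`,
`y = V/V_iso`. Concentration units (molar sorbitol or total mOsm) only
enter as ratios, so any convention works if consistent within a group; the
loader enforces this. The BVH line is fitted by unweighted OLS with a free
intercept (the intercept is the normalized non-osmotic volume ν_b); a
constrained through-(1,1) mode is provided, and the free fit reports
whether slope + intercept = 1 within 2 SE as a consistency check.

Ideality (linearity) is tested with the pure-error lack-of-fit F-test when
x levels are replicated — the natural design here, since many cells are
measured per sorbitol level — with a quadratic-curvature t-test fallback
for unreplicated designs. Type-I error of the F-test is verified by
simulation to sit near the nominal level.

Per-cell osmolyte amounts come from the paired-shift algebra of the ideal
law: with `ΔC = C2 − C1` known,
`C1 = ΔC (V2 − b) / ((V1 − b) − (V2 − b))` and `N = C1 (V1 − b)`, with
`b = ν_b · V_iso` taken from the population BVH fit (dry volume does not
change under acute shifts). The estimate is exact on noiseless
forward-model data and independent of the shift size used. A volume change
inconsistent with the shift sign yields a flagged estimate, not an error.

## GEM nanorheology

Tracks of 40-nm multimeric nanoparticles (100 Hz, 10 s by default) are
summarized by the time-averaged MSD per track over all start points, pooled
across tracks weighted by displacement counts (an unweighted
mean-of-tracks mode is available; the ensemble-weighted mode is the
default and is recorded on the curve). Tracks shorter than 10 frames are
dropped, and frame gaps split a track into segments so no displacement
spans a gap.

The effective diffusivity is the through-origin least-squares slope of the
first 10 MSD lags against `4τ` (the 2D Brownian law has no offset). Static
localization error of standard deviation σ_loc inflates every lag by
`4 σ_loc²`; this is documented and verifiable with the optional
offset-fit mode but is not corrected by default. The anomalous exponent α
is the log-log MSD slope over lags 2–50 (configurable). The aqueous
reference `D_0 = k_B T / (6π η r)` uses water viscosity 7.97 × 10⁻⁴ Pa·s at
30 °C.

Crowding dependence follows the Phillies stretched-exponential law
`D_eff = D_0 exp(−β C^λ)`. With λ fixed the fit is the exact linear
regression of ln D on C^λ; with λ free a nonlinear least-squares fit is
initialized from the λ = 1 linear solution. For an ideal osmometer
`C ∝ 1/(V − b)`, giving the volume parameterization
`ln D = ln A − κ/(V − b)`, fitted linearly in `1/(V − b)`. Inverting the
λ = 1 law converts a relative D_eff change into a fractional concentration
change, `ΔC/C_ref = −ln(D_ratio)/(β C_ref)`, reported with dilution
positive.

## N/C-ratio homeostasis

Volume growth is exponential, `dV_C/dt = γ_C V_C` (biosynthesis scales with
cytoplasmic content), and a fixed fraction f0 of new osmotically active
material partitions to the nucleus, `dV_N/dt = f0 γ_C V_C`. The ratio
ρ = V_N/V_C then obeys `dρ/dt = γ_C (f0 − ρ)` with solution
`ρ(t) = f0 + (ρ0 − f0) e^(−γ_C t)`: any aberrant N/C ratio relaxes to f0
monotonically with rate constant γ_C and no feedback, so the correction
rate γ_NC equals −γ_C with no free parameters. γ_C is a rate constant in
min⁻¹ (ln 2/0.006 min⁻¹ ≈ 115 min doubling). Correcting a deviation to
within a tolerance takes `log2(|ρ0 − f0|/tol)` generations — multi-
generation for large deviations. A linear-growth mode (constant absolute
rate, no size feedback) is provided for contrast: at matched initial
conditions it corrects large-cell deviations more slowly.

**Estimators.** Mirroring the time-lapse protocol (imaging every 4 min for
40 min, mitotic timepoints excluded), each cell contributes an OLS slope of
volume (or N/C ratio) against time; γ_C is the population OLS slope of
dV/dt on initial volume, and the homeostasis fit regresses d(N/C)/dt on the
initial N/C ratio, whose slope is γ_NC and whose x-intercept estimates f0.
Two finite-window properties of this protocol are worth knowing:

* a linear fit to an exponential over a window [0, T] rescales the rate by
  the secant factor (≈ 1 + γ t̄ for the volume slope, ≈ 1 − γ t̄ for the
  relaxing N/C slope; about ±12% at γT = 0.24). The f0 estimate is immune —
  slope and intercept rescale together, leaving the x-intercept exact on
  noiseless data. The noiseless tests assert agreement with the exact
  closed-form secant oracle rather than with γ itself; consistency with γ
  holds in the short-window limit γT ≪ 1.
* with measurement noise, the first timepoint enters both the regressor
  (initial N/C) and the per-cell slope; the shared error adds a small
  γ-independent negative bias to the fitted slope (classic regression
  toward the mean). This partially offsets the secant attenuation at
  γ_C = 0.006 min⁻¹ but compresses ratios between cohorts with different
  growth rates; comparisons of correction rates across conditions are
  therefore made on defined (noise-free) cohorts.

## Perturbation scenarios

The export-block scenario moves a scheduled, cumulative fraction of the
cytoplasmic osmolyte pool into the nucleus while growth continues
(amounts grow exponentially at γ_C times a synthesis modifier, fraction f0
to the nucleus); the steady state is re-solved at each step. Transfer
conserves the total amount exactly. The default schedule is a linear ramp
over 60 min — the simplest shape consistent with a progressive
redistribution; it is fully configurable. Dry volume moves with the
solutes by default, keeping the normalized dry fractions matched (as
observed experimentally); moving ~1.4% of the cytoplasmic pool raises the
nuclear amount fraction from 8.0% to 9.28%, a 16% relative N/C increase.
The translation-block scenario scales both amounts by one factor; the
closed-form N/C ratio is exactly invariant under such uniform dilution,
which is the model's account of why slowed growth preserves the ratio.

## Synthetic data

The generators produce every input table with the statistical structure
the analysis assumes, from one integer seed (bit-identical reruns; each
generator draws from its own spawned stream):

* **Shifts** — lognormal isotonic volumes (CV 0.3, an asynchronous
  population; mean 100 µm³), dry volume ν_b V_iso (default 25%), post-shift
  volumes from the tension-σ forward model at sorbitol levels 0.2–1.0 M
  around the 0.4 M isotonic point, multiplicative lognormal measurement
  noise (CV 5%) on both measured volumes. The 5% volume CV stands in for a
  3-D segmentation error scale that is not independently known.
* **Tracks** — Brownian steps of variance 2 D dt per axis, or exact
  fractional Brownian motion with H = α/2 synthesized by Davies–Harte
  circulant embedding (exact covariance, so α-recovery tests are unbiased;
  no autoregressive approximation). Optional static localization noise.
* **Growth cohorts** — mothers at the N/C fixed point divide with a
  Normal(0.5, 0.10)-distributed septum position while nuclei split evenly,
  so daughters start at nc0 = f0/(2a); symmetric division collapses the
  dispersion to measurement noise (the wild-type-like regime) and the
  default asymmetry gives roughly threefold wider spread (the
  asymmetric-division mutant regime). Growth follows the exponential
  partitioning model.
* **Crowding curves** — Phillies-law D_eff at five osmolarities with 10%
  multiplicative noise; defaults (D0 = 13.9 µm²/s from Stokes–Einstein,
  β = 0.0071 mOsm⁻¹) put the isotonic D_eff near the cytoplasmic
  0.40 µm²/s.

What passing recovery tests on these data do **not** show: robustness to
segmentation artifacts, motion blur and tracking errors, cell-cycle stage
structure, adaptation kinetics during slow shifts, or non-spherical nuclei
— none of which the generators emulate.

## Problem sizes and numerical choices

Recovery checks use 400 shift records, 500–1000 tracks of 1000 frames, and
cohorts of 30–150 cells — sizes at which Monte-Carlo error sits comfortably
inside each assertion band. Solver tolerances are 1e−12 relative on
volumes (residuals land near machine precision in concentration units);
bracket endpoints are inset by a relative 1e−9 to avoid the free-volume
poles. OLS is used everywhere a line is fitted, matching the experimental
practice; weighted variants are intentionally omitted from defaults. Ties
and degenerate inputs fail loudly: empty tables, all-identical x values,
cohorts at the homeostasis fixed point (no nc0 spread) and volumes at or
below the dry volume are rejected with named errors rather than silently
fitted.
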