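# Methods

## Scope and model

`svengine` analyzes sedimentation-velocity AUC scans by direct boundary
modeling. The data — absorbance or interference traces `a(r, t)` acquired at
constant rotor speed in a sector-shaped cell — are fitted as

    a(r, t) = Σ_j c_j w_j χ(s_j, D_j, r, t) + β(r) + γ(t) + b + ε

with a discrete grid of sedimentation coefficients `s_j`, trapezoidal
quadrature weights `w_j` (so the solved `c_j` is a signal *density* per
svedberg and `Σ c_j w_j` is the total loading signal), time-invariant (TI)
radial baseline `β`, radial-invariant (RI) per-scan offsets `γ`, an optional
uniform baseline `b`, and white noise `ε`.

Two kernel families are available:

* **cofs** (diffusion-deconvoluted c(s)): `χ` solves the Lamm equation
  `∂c/∂t = (1/r) ∂/∂r [ r D ∂c/∂r − s ω² r² c ]` on `[meniscus, bottom]`
  with zero-flux boundaries and uniform unit initial concentration. All
  species share one frictional ratio f/f₀, which sets
  `D(s) = (√2/18π) kT s^(−1/2) (η f/f₀)^(−3/2) ((1 − v̄ρ)/v̄)^(1/2)`
  (CGS units internally; svedberg = 1e-13 s on entry). The buoyancy factor
  must be positive: floating species are rejected in this version.
* **lsgofs** (apparent ls-g\*(s)): non-diffusing step boundaries at
  `r_b = m·exp(s ω² t)` with plateau `exp(−2 s ω² t)` (radial dilution); a
  boundary past the bottom means a cleared cell (zero profile).

The temperature entering `D(s)` is taken from the scan headers (run-average,
converted to kelvin): the request schema carries solvent properties but no
temperature, and the headers are the authoritative record of the run.

## Lamm solver

Linear finite elements on a log-spaced radial grid, assembled with the
radial weight `r` (mass `∫φᵢφⱼ r`, stiffness `∫φᵢ′φⱼ′ r`, flux
`∫φᵢ′φⱼ r²`), integrated by Crank–Nicolson. Zero-flux boundary conditions
are natural in this weak form, and the discrete mass `Σᵢ cᵢ ∫φᵢ r dr` is
conserved exactly (the flux matrix columns sum to zero); tests verify this to
1e-8 with an independently computed quadrature.

Sedimentation is advection-dominated where `D` is small (Péclet number
`Pe = v h / 2D > 1`, `v = s ω² r`), and plain Galerkin oscillates there. Each
element therefore carries the classical optimal artificial diffusion
`D_art = (v h / 2)(coth Pe − 1/Pe)`, which vanishes as `O(Pe)` on resolved
elements and tends to full upwinding at sharp fronts. With it the solver
reproduces the closed-form non-diffusing boundary (half-height within one
radial cell, plateau to 1e-8) while remaining second-order accurate in the
diffusion-resolved regime. The time step is bounded so the boundary moves at
most one radial cell per step, with at least 200 steps per run; requested
scan times are obtained by linear interpolation between steps (consistent
with the scheme's temporal order). Solutions are cached by
`(s, D, geometry, rpm, times, grid size)` so repeated design-matrix builds
inside the nonlinear regression reuse them.

Analysis kernels use 300 radial points (`protocol.ANALYSIS_N_RADIAL`) — at
this resolution halving the step changes boundaries well below the noise
levels considered here.

## Systematic-noise elimination

TI, RI and uniform-baseline components span a linear subspace (one indicator
column per distinct radius, one per scan, one constant column). These
families are mutually collinear, so the subspace is orthonormalized by SVD
and both data and kernels are projected onto its complement; the
non-negative distribution is solved in the projected space, which is
algebraically identical to jointly fitting unbounded noise parameters (a
property test checks this against an explicit joint solve to 1e-8 RMS).
Afterwards the noise profiles are recovered as the minimum-norm least-squares
decomposition of the residual `y − Xc`, which fixes the gauge freedom among
TI/RI/baseline.

## Regularized inversion

The non-negative core is a Lawson–Hanson active-set NNLS operating on the
normal equations (Gram matrix); this lets a single kernel matrix serve every
regularization weight during the weight search. It is verified against an
exhaustive active-pattern oracle on small systems and against an independent
reference implementation on larger ones, and its KKT conditions are asserted
at exit.

Regularization follows the F-statistics convention: the weight λ is the
largest value whose SSR does not exceed `SSR_min · F(p; ν, ν)` with
`ν = N_points − N_model_parameters` (grid size plus noise-subspace rank),
found by bisection on log λ over a normalized bracket `[1e-6, 1e6]`
(target SSR matched to 0.1%; an unreachable target returns the bracket end
with a warning). Two penalties are implemented:

* **Tikhonov**: squared second differences of the density (natural ends).
* **Maximum entropy**: `Σ c ln(c/prior)` with a uniform prior at the mean
  signal level, minimized by iterated local quadratic approximation (each
  inner step an NNLS solve, at most 30 iterations, relative tolerance 1e-4).

Bayesian baseline-correlation suppression multiplies the prior weight of the
smallest grid node by 1e3 (an extra Tikhonov penalty row, or a 1e3-fold
lower maxent prior), discouraging the slowest grid species from absorbing
baseline signal.

## Nonlinear regression

Meniscus, bottom and f/f₀ can be floated. The objective is the SSR of the
*unregularized* linear fit: it is cheaper, has the same minimizer in
practice, and the F-statistics target of the regularization depends on the
converged SSR anyway; the regularized distribution is computed once at the
best-fit parameters. Two bound-projected algorithms satisfy the same
contract (converged when the relative SSR improvement stays below 1e-6 for
5 iterations, 200-iteration cap; failed trial points are penalized, not
fatal):

* **Simplex** (Nelder–Mead): the initial simplex perturbs the start by a
  seeded random ±2% of each bound span (one dominant coordinate per vertex);
  the seed derives deterministically from the handshake string, so repeat
  runs of the same request are bit-reproducible while distinct sessions
  genuinely exercise different start geometry.
* **Levenberg–Marquardt**: forward-difference Jacobian (step 1e-4 of the
  bound span), multiplicative damping adaptation, projection of every trial
  point into bounds.

The error surface along f/f₀ is locally flat for broad boundaries (diffusion
carries little information there); recovery tests therefore assert f/f₀ to
±0.05 and meniscus to ±0.002 cm at noise σ = 0.005.

## Fit statistics

Global and per-scan rmsd follow directly from the residual bookkeeping.
Residual randomness is summarized by the Wald–Wolfowitz runs-test
`Z = (R − μ)/σ` on the sign sequence ordered scan-by-scan, ascending radius
(zeros excluded). The histogram score `H` is the RMS deviation between the
unit-area histogram of the *standardized* residuals (Scott's-rule bins) and
the standard normal density at bin centers — zero means Gaussian-like, and
the standardization makes `H` scale-invariant. `H` is this engine's own
documented convention; no numeric parity with other software is claimed for
it or for the runs-test ordering.

## Protocol and outputs

A session is `svengine <mode> <handshake> <request.xml>`; mode 111 accepts
the full parameter set, mode 112 is a restricted profile that rejects
non-standard options (grid-from-file, log-spaced grids, bottom fitting).
Unset parameters take documented defaults: booleans default FALSE except
spike filtering (TRUE, threshold 0.4) and TI/RI noise fitting (TRUE); the
model defaults to cofs, regularization to Tikhonov at p = 0.68, the thread
count to 2 (accepted and recorded; the numerics are single-threaded and
thread-count invariant by construction). Meniscus/bottom fitting limits
default to the value itself (a collapsed bracket). Parameter names are
case-sensitive; unknown elements are ignored with a warning; `PassThrough`
is preserved verbatim including nested markup.

Outputs are written into a freshly created results directory —
`distribution.dat`, `TInoise.dat`, `RInoise.dat`, `ScanRMSD.dat`, `dfr.dat`
(noise profiles plus per-scan radius/raw/fit column triples, shorter columns
padded with empty fields), `ResultParameters.xml` (the request echoed at its
post-fit values plus engine version, file paths, metadata aggregates and fit
statistics), and `screenshot.bmp` (a rendered report plot kept under the
compatibility name; rendering failures degrade to a placeholder image and
never abort a session). The completion flag file is written strictly last.
An `sdist.<ext>` grid file and a JSON session log are left next to the scan
data; both writes are atomic/collision-free so concurrent sessions sharing a
data directory stay independent.

## Synthetic data

The simulator writes protocol-conformant numbered scan files: superposed
unit-loading Lamm solutions scaled by species loadings, a smooth seeded
two-sinusoid TI profile, Gaussian per-scan RI offsets, white noise, and
optionally isolated spikes (placed so both neighbours stay clean). Rotor
acceleration is instantaneous, so `ω²t = ω² · t` exactly. Everything is
deterministic under the seed.

The `nistmab_like_preset` emulates a stressed monoclonal-antibody sample:
four species at 4.2 / 6.5 / 9.5 / 16.8 S (f/f₀ 1.37) loading 0.010 / 0.290 /
0.125 / 0.520 signal units, 50,000 rpm, a 6.0–7.2 cm column, 20 scans from
500 to 6800 s at 0.003 cm radial spacing, noise σ = 0.005, TI amplitude
0.01, RI amplitude 0.005. These are the study conditions for the equivalence
analysis in `svengine.equivalence`: path A is one automated AutoFit session;
path B is a Run-only session followed by a fitting session restarted from
±0.5%-perturbed meniscus and f/f₀.

What the simulator does *not* emulate — and what passing tests therefore do
not demonstrate about real data: optical artifacts (fringe jumps, intensity
nonlinearity), rotor stretch, temperature drift, acceleration ramps, and
solver-model mismatch. The simulator and the analysis share the same
finite-element solver (the preset simulates on the same 300-point radial
grid the analysis uses); with a deliberately finer simulation grid the
residual discretization mismatch is about 0.004 signal units rmsd,
comparable to the study noise, so real-data accuracy is bounded by kernel
convergence as much as by noise.

## Known limitations

* One frictional ratio for the whole distribution (standard c(s)); no 2-D
  size-shape analysis, co-solute density gradients, band/zone geometries, or
  interacting-system models.
* Floating species (negative s, negative buoyancy) are rejected.
* No Monte-Carlo confidence intervals or error-surface mapping.
* The histogram statistic and runs-test ordering are engine conventions (see
  above).
* Scan files must follow the documented ASCII dialect and zero-padded naming;
  binary instrument formats are out of scope.
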