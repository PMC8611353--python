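# Methods

## Model

Cell colonies whose growth is restricted to an outer rim of viable,
proliferating cells are described by a non-local logistic law for the
normalized density `n(x, t) ∈ [0, 1]`:

    ∂t n = α (k ∗ n) (1 − n),

where `k` is the normalized indicator of a ball of radius `σ_k` (mm)
and `α` (1/day) the proliferation rate.  Division pressure at a point
is exerted by all cells within one kernel radius — daughter cells
appear next to their mothers without a diffusion term — while the local
factor `(1 − n)` enforces carrying capacity.  Units are days and
millimetres throughout.

For radially symmetric data the model reduces to one dimension.  The
radial density `p(R, t) = 4πR² n(R, t)` satisfies

    ∂t p(R, t) = (4πR² − p) ∫₀^∞ L(R, r) p(r, t) dr,

with the interaction kernel

    L(R, r) = 3α/(16π σ_k³) · [min{(R+r)², σ_k²} − min{(R−r)², σ_k²}] / (R r).

`L` is symmetric, nonnegative, bounded by `3α/(4π σ_k³)`, vanishes for
`|R − r| ≥ σ_k`, and has a removable singularity on the axes: as
`R → 0⁺`, `L → 3α/(4π σ_k³)·1{r < σ_k}`.  The implementation evaluates
the difference of minima branchwise (it equals `4Rr` exactly when
`R + r ≤ σ_k`), which avoids catastrophic cancellation near the axes,
and returns the analytic limit when `R·r` underflows.

## EBT particle scheme

The solution measure on a truncated domain `[0, R0]` is approximated by
`N` Dirac masses at fixed locations `x_i = i R0/N` whose weights solve

    dm_i/dt = (4π x_i² R0/N − m_i) Σ_j L(x_i, x_j) m_j(t),
    m_i(0) = ∫_{x_{i−1}}^{x_i} p(r, 0) dr.

The saturation prefactor is read with the particle mass `m_i` (not a
density): discretizing the continuum saturation term over cells of
width `R0/N` gives `(4π x_i² R0/N − m_i)`, the only reading in which
both summands carry mass units.  It also yields a discrete maximum
principle: masses initialized below the cap `4π x_i² R0/N` stay below
it, and since the interaction sum is nonnegative, masses never
decrease.

Numerics:

* `L(x_i, x_j)` vanishes beyond `|i − j| > σ_k N/R0`, so the
  interaction matrix is stored as a band; a matrix build costs
  `O(N σ_k N/R0)` and is repeated per parameter value (σ_k changes
  every MCMC proposal).
* Default integrator: adaptive Dormand–Prince (scipy RK45) at
  `rtol 1e-8 / atol 1e-12`; the system is smooth and non-stiff at the
  model's parameter scales.  A fixed-step classical RK4 (numba-compiled
  over the banded right-hand side) is the production path inside MCMC:
  bit-reproducible and ~10 ms per forward solve at desk scale.  For the
  scalar relaxation `m' = S (cap − m)` RK4's stability function stays
  positive for `S·dt < 2.78`, and `S ≤ α` here, so the cap is not
  overshot at the default steps (`dt = 0.05` day; `0.1` inside MCMC).
  Integrations that violate nonnegativity or the cap by more than 1e-9
  relative are treated as errors, then the solution is clipped within
  that tolerance.
* Truncation radius policy: `R0 = max(4σ_i, 2 r_final + 6σ_k)`.  When
  `r_final` is not known in advance it is bounded using a front-speed
  estimate `1.2 α σ_k` (the measured front speed is ≈ 0.67 α σ_k across
  the parameter ranges exercised here, so the policy over-provisions);
  if the realized mass in the outer tenth of the domain still exceeds
  1e-3 of the total, the domain is widened by 1.5× and the solve
  repeated.  Fits resolve `R0` once per dataset from the largest
  observed radius and the prior medians, so all posterior evaluations
  share one grid.

### Flat norm

Convergence of the scheme is measured in the bounded-Lipschitz (flat)
distance `sup {∫ψ d(μ−ν) : ‖ψ‖_∞ ≤ 1, Lip(ψ) ≤ 1}`.  For two discrete
measures the supremum is attained by a function determined by its
values at the atoms, subject to pairwise Lipschitz constraints; on a
line the adjacent-pair constraints imply the rest, so an exact linear
program (HiGHS) over the union of atom locations computes the distance.
The weighted variant divides atom masses by their location first (no
atom sits at the origin by construction).  Continuum references are
first projected onto the particle grid by cell integrals, consistent
with how the scheme defines its approximation.

### A numerical finding: front pinning

The flat-norm error between `N`- and `2N`-particle solutions decays at
first order, but the prefactor oscillates by more than an order of
magnitude with the alignment of `σ_k` to the grid spacing whenever the
kernel spans fewer than ~10 spacings: the travelling front locks onto
the particle lattice and its speed acquires alignment-dependent
corrections.  The convergence harness therefore uses a reference
configuration that resolves the kernel by ≥ 15 spacings at the
coarsest resolution tested (`σ_k = 0.12`, `R0 = 1.8`, `α = 0.35`,
`σ_i = 0.3`, `t = 10`), where the error cleanly halves as `N` doubles.
Production fits run at comparable or better kernel resolution.

## Observation model

The measurable colony radius is the 0.95-quantile radius

    r(t) = inf{s : ∫₀^s p dr > 0.95 ∫₀^∞ p dr},

evaluated on the discrete measure as the smallest particle location
whose cumulative mass strictly exceeds the threshold.  The strict
inequality matters only at exact ties, where the infimum moves to the
next atom; ties have measure zero in practice.  Two smoother variants
exist: convolution with a Laplace density of scale ε followed by
root-finding of the smoothed CDF (differs from the discrete value by
far less than the particle spacing, and is off by default — it
multiplies cost for no practical gain), and linear interpolation of the
step CDF between atoms.

Measured radii carry multiplicative lognormal noise, `r_obs = r(t)·Z`,
`log Z ~ N(0, σ_o²)`, giving the log-likelihood

    ℓ = Σ_i log N(log r_obs,i ; log r(t_i), σ_o²),

which is invariant to a common rescaling of observed and model radii.
Model radii at observation times come from including every `t_i` in the
integrator output grid; nothing is interpolated in time.  Growth-curve
CSVs may carry diameters (halved on ingest — the source figures report
mean diameters) or radii; printed standard deviations are carried as
metadata and not used in the likelihood, which assumes homogeneous
error over time.

The initial condition is a mollified ball,

    p(r, 0) = 4πr² (1 − (r/σ̃)^q) on [0, σ̃],   σ̃ = c σ_i,

with `q = 13` and `c = 1.065` (1.06 for B-16), calibrated so the
0.95-quantile radius of the initial profile lands within a few percent
of `σ_i`.  Its antiderivative is closed-form, so initial cell integrals
are exact.

## Inference

The parameter vector `(α, σ_k, σ_o, σ_i)` is sampled on the log scale,
where positivity is automatic and the independent lognormal priors
become Gaussians.  Conventions:

* Priors are parameterized by medians (scale-equivariant reading of the
  stated prior locations; with log-sds of 1 and 5, lognormal *means*
  would be inflated by e^{1/2} and e^{12.5}).  Per cell line the
  medians are: α = 1.4 / 1.04 / 0.9 (L-5178Y / V-79 / B-16, from
  suspension doubling times slowed 2.4× in a colony — treated as
  authoritative constants), σ_k = 0.06 / 0.06 / 0.09 mm (six cell
  diameters), σ_i = the initial colony radius.  Log-sds are 1, except 5
  for σ_o.  The σ_o prior needs a location; it is centred at median 0.1
  — at log-sd 5 the choice is practically immaterial.
* Sampling targets log σ rather than log σ²: the two differ by an
  exact factor-2 rescaling of prior and proposal scales (verified by a
  reparameterization test), and natural-unit reporting matches how the
  calibrated values are quoted (σ's, not σ²'s).

The sampler is random-walk Metropolis with isotropic Gaussian proposal
`θ' = θ + Z`, `Z ~ N(0, s·I₄)`, accepted with probability
`min{1, exp(Δ log-posterior)}`.  The scale `s` is tuned only during a
pilot phase by Robbins–Monro iteration on `log s` toward acceptance
0.234 (the classical random-walk optimum), followed by a frozen
verification batch; tuning fails loudly if the verified acceptance
leaves [0.15, 0.35].  Solver failures and parameters that outgrow the
truncation radius score −∞ and are rejected, keeping the chain valid.
Chains are bit-reproducible given a seed (fixed-step integrator,
single RNG stream) and checkpoint/resume exactly.

Desk-scale defaults — `N = 400` particles, `dt = 0.1`, 20 000
iterations with 2 000 burn-in — keep a full fit in the minutes range;
the `paper` profile (450 000 / 50 000, `N = 1000`, `dt = 0.05`) matches
the published protocol.  The MAP estimate is the highest-posterior
post-burn-in draw, optionally polished by Nelder–Mead (kept only if it
improves).  Diagnostics: FFT autocorrelation per log-parameter and a
pointwise 95% posterior-predictive band for diameter vs time from a
thinned subsample pushed through the solver.

## Synthetic data

The generator emulates the structure of the classical spheroid
growth-curve assays (Folkman–Hochberg cultures of L-5178Y, V-79 and
B-16 lines): measurements every 2 days across each line's quasi-linear
window (0–30, 0–38, 0–48 days), initial radii 0.264 / 0.403 / 0.733 mm,
forward radii from the model perturbed by lognormal noise.  Noise uses
an RNG stream separate from the MCMC proposal stream.  It does not
emulate: the early exponential (pre-necrotic) phase or the terminal
dormant phase (outside the model's applicability), replicate averaging
(the real curves are means over dozens of spheroids; the likelihood
treats point measurements), or digitized values of the original figures
(figure-read values are not ground truth).  Tests passing on synthetic
data therefore certify the solver/inference machinery under the
model's own assumptions, not the model's adequacy for any real colony.

### Parameter-recovery experiment

The recovery study (V-79 priors, truth at the prior medians,
`σ_o = 0.05`, 20 time points) generates data on the same particle grid
the posterior uses — the deliberate "inverse crime" that isolates the
inference machinery from discretization bias.  (With mismatched grids
the first-order solver differences of a few percent are comparable to
the noise and visibly bias the fit.)

Identifiability: the likelihood is nearly flat along a curved ridge
trading α against σ_k (faster division in a thinner rim produces almost
the same growth curve).  Across noise realizations the profile of the
posterior along the ridge varies by only ~1–2 log units; in roughly 7
of 10 realizations the global mode lands within a percent of the
generating α, in the rest it sits at a quasi-mode with α off by a
factor ≈ 0.6 or ≈ 1.7 and σ_k compensating.  Point (MAP) recovery of α
is therefore fragile by nature at these study conditions, while the
95% credible intervals cover the generating values robustly.  The same
α–σ_k correlation is visible in the published trace plots for the
slowest-growing line.

## Validation oracles

* **Homogeneous limit.**  With spatially constant density the
  convolution is the identity on constants and the model reduces to the
  logistic ODE with closed-form solution; interior particles of a
  near-uniform EBT state reproduce it to < 1e-3 relative over ten days.
* **3D grid solver.**  The full 3D equation solved by FFT convolution
  (antialiased, renormalized ball kernel; RK4 in time; grids capped at
  96³ — a brute-force oracle, not a feature).  Radial densities are
  estimated per shell using the *measured* voxel count of each shell,
  which cancels the voxelization staircase.  At matched resolution
  (particle spacing = grid spacing = σ_k/8, 64³) the EBT and 3D radial
  densities agree to < 5% relative L¹; both discretizations are first
  order, so the discrepancy shrinks linearly in the spacing (it is ≈ 9%
  at the minimum legal kernel resolution σ_k/4).
* **Posterior resolution stability.**  Posteriors computed with
  N = 250, 500, 1000 solver particles are compared by total-variation
  distances between weighted kernel-density estimates on a common
  support: one chain runs at the coarsest resolution and finer-
  resolution posteriors are importance-reweighted on its thinned draws.
  Reweighting removes the Monte-Carlo wander that otherwise swamps
  these small distances; first-order solver convergence then shows as
  `d(π_250, π_500) ≈ 2 d(π_500, π_1000)`.
* **Toy targets.**  Sampler moments on a correlated 2D Gaussian and
  step-size tuning bands.

## Problem sizes

Routine runs and the validation suite use desk-scale sizes chosen as
the package defaults: N = 400 particles (fits), 20 000-iteration
chains, 64³ oracle grids, 3 000-iteration stability base chains.  The
`paper` profile scales the chain and solver up to the published
protocol and is exercised via configuration, not in the default suite.

## Known limitations

* The quantile radius is piecewise constant in the parameters at the
  particle spacing, so likelihood surfaces carry a small staircase
  texture; the interpolated variant smooths it if needed.
* Front pinning (above) makes convergence measurements alignment-
  sensitive at coarse kernel resolution.
* `R0` is fixed per fit; posterior mass at parameter values whose
  colonies would outgrow the domain is suppressed via −∞ (with the
  0.9·R0 guard) rather than by enlarging the domain adaptively.
* The model itself excludes necrosis, nutrient limitation and the
  dormant phase; fits are meaningful only over the quasi-linear window.
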