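# Methods

This note documents the models, numerical choices and limitations of
`lgcpmap` in the package's own terms. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The point-process model and its discretisation

Cancer case locations are modelled as an inhomogeneous Poisson process
with intensity e(s)·r(s): e(s) carries the population structure via
indirectly standardised expected counts, r(s) is the relative risk.
The log risk is log r(s) = X(s)β + Z(s) with Z a zero-mean stationary
Gaussian random field with Matérn covariance, smoothness fixed at
ν = 1 (the standard choice that keeps the SPDE representation cheap
and is rarely identifiable from epidemiological data anyway).

For fitting, the continuous likelihood is discretised to cell-level
Poisson counts on the same 1 km² grid that defines the offset:
y_k ~ Poisson(E_k exp(η_k)), η = Xβ + AZ, where A projects mesh-node
field weights to cell centroids. Case coordinates are binned to cells;
at 1 km resolution the binning error is far below the posterior
uncertainty of any quantity the package reports. Cells with E_k = 0
are retained (they contribute nothing to the likelihood); a cell with
cases but zero expected count indicates inconsistent inputs and is
flagged with a warning rather than an error.

## Range convention

The range ρ is defined as the distance at which the Matérn correlation
falls to 0.10. For ν = 1 the correlation is c(d) = (κd)·K₁(κd), and κ
is calibrated by root-finding so that c(ρ) = 0.10 exactly. The common
alternative convention ρ = √(8ν)/κ puts the correlation at ≈ 0.139 at
its range; the √8/κ-equivalent value is exposed as
`MaternParams.rho_sqrt8` for comparison with other software. All
priors and reported ranges use the 0.10 convention.

## SPDE approximation

The field is expanded in piecewise-linear basis functions on a
structured triangular lattice: each lattice square is split along its
anti-diagonal into two triangles (the projector and the finite-element
assembly share this convention — they must, or the basis the precision
matrix describes would not be the basis the projector evaluates). The
precision of the basis weights is

    Q = τ² (κ⁴ C + 2κ² G + G C⁻¹ G),

with C the lumped (diagonal) mass matrix, G the stiffness matrix and
τ² = 1/(4π κ² σ²) fixing the stationary variance for ν = 1 in two
dimensions. A structured lattice rather than constrained Delaunay
refinement keeps the mesh deterministic and trivially reproducible;
at desk scale the accuracy loss is negligible when the node spacing is
≲ ρ/5 (the dense-inversion tests use ρ/10, where the marginal SD is
accurate to ~2–3%).

The mesh extends beyond the observation window by a buffer (default
1.5 × the prior median range) because the Neumann boundary condition of
the SPDE inflates the variance near the mesh edge; the tests verify the
inflation decreases monotonically with the buffer.

Latent precisions in this package are at most a few thousand rows, so
factorisations are done densely with LAPACK (Q itself is assembled and
stored sparse). A supernodal sparse Cholesky would win above roughly
10⁴ nodes; no scenario here comes near that.

## Priors

* β ~ N(0, 10·I) — the "10" is read as a variance, not an SD.
* σ: penalised-complexity prior, exponential with rate −ln(0.01)/1, so
  P(σ > 1) = 0.01. Base model σ = 0 (no spatial variation).
* ρ: penalised-complexity prior for the range of a 2-d Matérn field,
  π(ρ) = λρ⁻² exp(−λ/ρ) with λ = −ln(0.5)·60, so P(ρ < 60 km) = 0.5.
  Base model ρ = ∞ (infinitely smooth field).

## Inference: simplified INLA

For each point θ = (log σ, log ρ) on a deterministic grid — default
7 × 7, spanning ±3 prior SDs of log σ and log ρ (π/√6 each, from the
Gumbel/log-exponential forms of the PC priors) around the prior
medians — the joint conditional of (Z, β) is approximated by a
Gaussian at its mode. Modes are found by damped Newton iterations with
step-halving, converged when the gradient ∞-norm is below 1e-6; a
Newton-decrement criterion (< 1e-10 relative) covers near-improper
grid corners (very large σ or ρ) where round-off floors the achievable
gradient norm. β is absorbed into the joint latent block rather than
marginalised separately. The Laplace evidence plus PC-prior density
and log-scale Jacobian gives unnormalised grid weights; posteriors are
mixtures over the grid.

Consequences worth knowing:

* Hyperparameter posteriors are supported on the grid points, so σ²
  summaries are quantized to grid values. Functionals of (Z, β) mix
  over the grid and do not inherit this coarseness to any practical
  degree.
* Full INLA's nested corrections (refining the Gaussian conditional
  per latent coordinate) are omitted. On tiny instances the test suite
  bounds the resulting error against a long random-walk Metropolis
  chain evaluating the exact posterior: means agree within 3
  Monte-Carlo SEs and marginal SDs to a few percent.
* If substantial posterior mass lands on the grid boundary the fit
  records `edge_mass_warning`. This is expected, not an error, when
  the data favour σ → 0 (the base model) — the real study reports
  exactly this shrinkage for some diagnostic groups — and when the
  range is only weakly identified so its posterior follows the prior
  tail.
* Multiplying the offset by a constant c shifts the identifiable
  linear predictor by −log c uniformly. The posterior attributes the
  shift to the intercept except at near-improper corner grid points,
  where the field's constant mode is almost free under the prior and
  can absorb part of it; those points carry negligible weight, so the
  mixture posterior of β₀ shifts by −log c to within a tolerance set
  by the N(0, 10) intercept prior.

## Synthetic registry generator

The generator emulates the study's structure, not its geography:

* Population: census-year layers are smooth exponentiated random
  surfaces normalised to a configured national child population
  (default 1.3 million across three age groups — rates then sit near
  the realistic ~15 cases per 100 000 child-years); intercensal years
  use the same linear interpolation the standardisation module
  applies to real censuses, with constant extrapolation outside the
  census span (avoiding negative populations; the original study's
  exact interpolation scheme is not public).
* Covariates: smooth low-frequency random fields for NO₂, radiation
  and SEP surrogates, scaled to sample SD 1 with raw-unit SDs stored
  as metadata (radiation 60.2 nSv/h, SEP 8.7, registry-years 11.6;
  the NO₂ SD is stored with its printed unit label verbatim since the
  printed unit is ambiguous — nothing downstream interprets it);
  piecewise-constant registry-years over a canton-like nearest-seed
  partition; contiguous 3-level language and urbanisation partitions
  with German / rural reference levels.
* True effects default to values near the real study's adjusted
  estimates (e.g. log 1.17 per SD for the radiation surrogate) so
  recovery tests run at realistic effect sizes; true_sigma = 0.15 and
  true_rho = 50 km sit in the region the study's posteriors indicate
  (σ² of order 0.01–0.02; range below the 60 km prior median).
* Cases: cell counts Poisson(E_k · rr_k), positions uniform within
  the cell (the maximum-entropy choice consistent with a cell-level
  offset), age/year drawn proportional to q_ij·P_ijk within the cell,
  geocode-error classes drawn with ~94% in the two classes under
  100 m. Error classes are fixture realism only; nothing consumes
  them. The relative-risk surface is normalised so the person-time
  weighted national mean risk is 1 — RR is *defined* relative to the
  national level — which also makes the expected national case total
  equal the configured target (default 5 947).

What the generator does not emulate: real Swiss geography and
municipality shapes, real exposure surfaces (only SD-matched smooth
surrogates), temporal covariate trends, and registration
incompleteness mechanisms. Passing tests therefore demonstrate the
estimator's correctness under the model's own assumptions — they say
nothing about, e.g., confounding structures only real exposure
surfaces exhibit.

## Areal BYM comparator

Cells aggregate to pseudo-municipalities (rectangular blocks, hence
contiguous and connected by construction): counts and offsets summed,
continuous covariates population-weighted, categorical covariates by
modal cell. The model is the classic additive BYM —
η = β₀ + xβ + u + v with u an ICAR (graph-Laplacian) structured effect
under a sum-to-zero constraint and v independent Gaussian — not the
reparameterised BYM2, since the original study's exact areal
specification is not public. The ICAR improperness is handled by
parameterising u in an orthonormal basis of the sum-zero subspace,
where the prior is proper and full-rank; every posterior draw of u
then sums to zero by construction. Both random-effect SDs carry PC
priors with the same (1, 0.01) calibration as the field SD, and the
fit reuses the Laplace-on-a-grid machinery over (log σ_u, log σ_v).

## Validation experiments

* Coverage: 100 independent datasets from the generative process
  (30 × 30 km grid, one SD-scaled covariate at log-RR 0.15, ≈6 000
  expected cases, ~200-node mesh), each refitted; the 95% credibility
  interval for the covariate coefficient is checked against the truth.
  These sizes keep a full run in the tens of seconds while leaving
  binomial noise (±2 points SD) as the dominant uncertainty.
* MCMC oracles: 4-cell LGCP and 4-area BYM instances with
  hyperparameters fixed at a single grid point, compared against
  500k-step random-walk Metropolis chains targeting the exact
  posterior, with batch-means standard errors.
* Dense-inversion oracles for the SPDE precision, Monte-Carlo moment
  checks for the field sampler, conservation identities for
  standardisation, and arithmetic oracles for R².

## Known limitations

* Purely spatial: no spatiotemporal risk or covariate trends (the
  original analysis makes the same restriction and defers the
  extension).
* The hyperparameter grid is deterministic and moderately coarse;
  adaptive grid placement as in full INLA would sharpen σ² summaries.
* Laplace-only conditionals; skewness corrections are not applied.
* With the default generator hyperparameters the field range (50 km)
  exceeds the 30 km validation window, so (σ, ρ) are only weakly
  identified from a single realisation; fixed-effect credibility
  intervals can then run slightly narrow against their frequentist
  coverage at fixed (rather than prior-drawn) hyperparameters. This
  is a property of window-smaller-than-range designs generally, not
  of the implementation.
* The synthetic generator's confounding structure is benign by
  construction; see above for what passing tests do and do not show.
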