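# Methods

## Model

The outcome is binary at n planar locations (km, UTM-like frame):

    y_i | p_i ~ Bernoulli(p_i),   logit p_i = α + X_i β + U(z_i).

U is a zero-mean stationary Gaussian field with Matérn covariance of
smoothness λ = 1,

    cov(Δ) = σ² · (κΔ) K₁(κΔ),

κ > 0 an inverse-scale parameter (1/km) and σ² the marginal variance on
the logit scale. λ is frozen at 1: it is poorly identified from binary
data and the finite-element precision construction below assumes the
corresponding SPDE order. The **range of influence** is ρ = √8/κ — the
distance at which the correlation falls to x·K₁(x)|_{x=√8} ≈ 0.140,
conventionally described as "about 0.1". The variance is tied to a
precision-scale parameter τ by σ² = 1/(2π κ² τ²), so the hyperparameters
actually estimated are θ = (log κ, log τ).

## GMRF representation

`mesh.build_mesh` triangulates the data region: thinned data locations
(minimum vertex separation 0.75 km at full scale) seed the mesh, filler
vertices keep every triangle's longest edge under a per-zone cap (2 km in
the data region, 50 km in the surrounding extension zone at full scale),
and the meshed domain extends max(15 km, 1.5 × a prior range guess) beyond
the data to push boundary effects away. A regular grid mesh
(`mesh.grid_mesh`) is provided for convergence checks where mesher freedom
would add noise.

On the mesh, the field is a GMRF with sparse precision

    Q(κ, τ) = (τ²/2) · (κ⁴ C + 2 κ² G + G C⁻¹ G),

with C the lumped (diagonal) P1 mass matrix and G the stiffness matrix.
The standard α=2 finite-element operator with multiplier s yields marginal
variance 1/(4π κ² s); the τ²/2 multiplier is what makes the implied
variance equal the analytic parametrisation σ² = 1/(2π κ² τ²) used
throughout. Both the factorised form Q = KᵀK (K sparse, since C is
diagonal) and the log-determinant identity
log|Q| = V log(τ²/2) − Σ log c_v + 2 log|κ²C + G| are used downstream.
On a fine mesh (edge ≈ ρ/10) the GMRF covariance reproduces the analytic
Matérn to within a few percent at lags 0.5–1.5 ρ; the vertex variance is
inflated by ≈4% at that resolution, which is inside every tolerance used
here. Observation locations need not be vertices: a barycentric projector
A (≤3 non-zeros per row, rows summing to 1) interpolates the field.

## Inference

For fixed θ the latent vector x = (α, β, Ũ) has a log-concave posterior;
a damped Newton iteration (convergence at max|∇| < 1e-6, cap 50
iterations, failures flagged rather than raised) finds the mode, and the
Laplace approximation gives the marginal likelihood

    log p(y|θ) ≈ ℓ(x*) − ½ x*ᵀPx* + ½ log|P| − ½ log|H|,

with P = blockdiag(0.001·I, Q) the joint prior precision and H = P + BᵀWB
the negative Hessian. Two numerical guards matter in practice: (i) the
line search tolerates floating-point noise near the mode and treats a
stalled search with max|∇| < 1e-3 as converged; (ii) the Laplace value is
non-positive in exact arithmetic (Bernoulli log-likelihood ≤ 0, prior
quadratic ≤ 0, H ⪰ P), so a positive computed value — possible only when
sparse LU breaks down at an absurd hyperparameter corner — is replaced by
−10¹² and flagged. Without guard (ii), a single broken corner node can
swallow the entire grid weight.

The hyperposterior over θ is explored empirical-Bayes style: Nelder-Mead
locates the mode of (Laplace marginal × hyper prior), a finite-difference
Hessian sets the scale, and a g×g grid (default 15, ±3 posterior SDs,
trapezoid weights) mixes the conditional summaries. Three policies handle
weak identification, which is common at reduced sample sizes and heavy
missingness:

* the Hessian's eigenvalues are floored at the hyper prior precision, so a
  flat marginal likelihood yields a grid spanning the prior rather than a
  collapsed or runaway one;
* the half-span is capped at 6 log-units (range factor e⁶ ≈ 400) — beyond
  that the fit is a "no detectable spatial correlation" case that the
  study-level exclusion rule (below) handles;
* if >5% of the weight sits on the grid boundary the grid expands (max 3
  times) unless the span was already capped.

A fit is declared converged when ≥95% of the grid weight sits on nodes
whose inner Newton converged.

Posterior summaries: σ² and ρ are deterministic transforms of θ, so their
posteriors are the weighted grid mixtures (median by weighted
interpolation; log-scale mean/variance retained for pooling). For α and β
the default is a **profile-Laplace marginal**: at each active node the
joint posterior is re-maximised with the parameter pinned on a 13-point
grid (fixed-Hessian chord Newton, bordered solve), and
log p(a|θ) = ℓ(x*_a) − ½(log|H| + log(H⁻¹)_jj) captures the skew that the
Gaussian-at-the-mode summary misses; node densities are mixed by grid
weight. On a 40-point dense-field benchmark this moves the posterior mean
of α from 0.17 to under 0.05 of a long-run MCMC run. The simulation loops
use the cheaper Gaussian summary (`marginal_strategy="gaussian"`): they
report medians over replicates, where the per-fit skew correction is
immaterial, and the cost difference is ~4×.

Priors: α, β ~ N(0, 1/0.001) each; log κ and log τ normal with precision
0.001 by default (0.1 where the study protocol switches — see below).
Prior means are weakly data-scaled: prior range = 20% of the domain
diameter, prior σ² = 1. The reported per-fit "estimate" is the posterior
mean for α and β and the posterior median for σ² and ρ (the posteriors of
the latter are right-skewed).

`fields.DenseFieldModel` swaps the GMRF for the exact dense Matérn
covariance at the data locations (A = I); it scales only to small n and
exists so that cross-checks against sampling-based inference run on the
identical model, not on the mesh approximation.

## Missingness machinery

Missing indicators are independent Bernoulli draws with
logit π_i = μ (MCAR), μ + ν X_i (MAR) or μ + ν y_i (MNAR), ν = log OR with
OR ∈ {1/3, 3}. μ is calibrated by monotone root-finding so the *mean* of
π over the realised driver values equals the target fraction
(finite-population calibration, |error| < 1e-8); MCAR has the closed form
μ = logit(target). Masks never destroy data: the dataset keeps the full
outcome vector and an observation flag, and the likelihood simply skips
unobserved rows — a masked dataset and its observed-row subset give
bit-identical fits.

## Multiple imputation

The imputation model is the same spatial logistic model with *both*
covariates (log herd size, herd density); a comparator mode drops the
spatial term (same code path, `field_model=None`). One imputation samples
a hyper-grid node by weight, draws the latent vector from that node's
Gaussian (via H = SᵀS with S = [R; √W·B], so x* + H⁻¹Sᵀz has covariance
H⁻¹), and draws Bernoulli outcomes from the implied probabilities at
unobserved rows. M follows the missing fraction (3/5/10 at 5% / 10–25% /
50–75%). Pooling: Rubin's rules (point = mean, total variance =
W + (1+1/M)B) on the identity scale for α, β with posterior SD² as the
within-imputation variance; for σ² and ρ the rules are applied to the
log-scale posterior mean/variance and back-transformed with the lognormal
identities E = exp(m + V/2), Var = (exp(V)−1)exp(2m+V). When a member fit
is nearly flat, V is large and the back-transform can explode — that is a
property of the lognormal combination, and such sets are almost always
removed by the exclusion rule below.

## Study rules

* **Exclusion**: a fit whose range estimate reaches 75 km (the region's
  span is 76 km) shows no detectable spatial correlation; the replicate is
  excluded from the summaries. The boundary is excluded too (retain iff
  ρ̂ < 75; configurable). For an imputation set, *one* flat member drops
  the whole set, keeping M equal across retained sets.
* **Prior switch**: hyper prior precision 0.001 normally; 0.1 for
  missing-data fits at ≥75% missingness and for all imputation-stage fits
  at ≥50% — the informative setting that stabilises estimation when the
  data carry little information.
* **RMeSE** = sqrt(median((estimate_incomplete − estimate_complete)²)),
  computed against the complete-data *fit* (not the generative truth).
* Per-replicate seeds derive deterministically from (master seed, scenario
  label, replicate, stage), so every stage is independently reproducible
  and a rerun is byte-identical. An optional process pool fans out
  replicates; it is off by default and never affects results.

## Synthetic data generator

The generator emulates a regional cattle register without reproducing any
real point pattern:

* **Region**: a smoothed random blob (radial cosine perturbations of a
  circle) rather than an administrative polygon; coordinates are rescaled
  so the maximum pairwise distance is exactly 76 km.
* **Locations**: a parent–offspring (Thomas-type) cluster process clipped
  to the region — herds cluster along valleys and roads, and a clustered
  pattern stresses the mesh and projector more realistically than uniform
  points.
* **Herd size**: log herd size ~ N(3.9, 1.4²) (median herd ≈ 50 head,
  right-skewed sizes). The SD was chosen once so that, through the
  logistic effect β = 0.63 alone, corr(log size, outcome) lands near 0.35;
  no tuning loop touches the outcome.
* **Herd density**: computed literally from the generated points — herds
  within 5 km (the focal herd *included*, so an isolated herd has density
  1/(25π)) divided by the disc area. Density is uncorrelated with herd
  size by construction.
* **Outcome**: the latent field is drawn exactly (dense Cholesky) at
  (σ² = 0.49, ρ = 12.7 km) and outcomes from the same logistic model the
  inference fits, with α = −4.3, β = 0.63 — so parameter recovery is a
  clean end-to-end test. An option recalibrates α to hit a target
  prevalence (≈17.4% in the emulated register).

What the generator does **not** reproduce: the real spatial point pattern,
dairy/non-dairy structure, temporal dimension, or the exact real-data
estimates — passing tests demonstrate the machinery's calibration on data
of the same structure, not agreement with any particular registry.

## Problem sizes

The default generator produces n = 1593 herds in a 76 km region; the test
suite and the analysis scripts run the expensive end-to-end stages at
n = 400 with a coarser mesh (inner edge 5–6 km, vertex separation
2–2.5 km, ≈250–600 vertices) and a 5–7 point hyper grid, which keeps a
full study cell in seconds per fit. Replicate counts in the desk-scale
scripts are 5–20 versus the protocol's 1000. Two reduced configurations
are used deliberately: parameter recovery thins herds inside the full
76 km region (n = 400), where the field is often weakly identified —
flat-posterior fits with very wide σ²/ρ posteriors are expected there and
are exactly what the exclusion rule and prior switch exist for; the
missing-data/imputation study instead shrinks the region together with n
(400 herds, 40 km domain), preserving the herd density and hence the
detectability of the 12.7 km field that the study design presumes of its
complete data.

## Known limitations

* The hyperposterior exploration is a dense grid, not CCD; marginal skew
  corrections are applied to the regression block only (profile Laplace),
  not to transforms of θ.
* The profile marginal assumes the constrained modes stay in the chord
  Newton's basin; it falls back to the Gaussian summary per node when the
  constrained optimisation fails.
* Dense-field generation and the dense oracle are O(n³); they are for
  n ≲ 2000 and n ≲ 100 respectively.
* MNAR scenarios are *simulated* MNAR but *imputed* under a MAR-type
  model, deliberately: the point is to measure what standard imputation
  does under mechanism misspecification.
* The mesher is a refinement loop over scipy's Delaunay triangulation; it
  enforces edge caps and minimum vertex spacing but does not optimise
  triangle quality beyond that.
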