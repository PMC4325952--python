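# spatmiss

Estimating the **range of influence** in binary spatial data when outcomes
are missing — and whether multiple imputation helps.

## The problem

In point-referenced binary data (here: *Salmonella*-style infection status
of cattle herds in a ~76 km region), the range of influence is the distance
beyond which outcomes at two locations are effectively uncorrelated. It is
estimated from a logistic regression with a latent spatial random effect:

    logit P(y_i = 1) = α + X_i β + U(z_i),

where U is a stationary Gaussian field with Matérn covariance (smoothness
λ = 1)

    cov(Δ) = σ² · (κΔ) · K₁(κΔ),

and the range of influence is ρ = √8 / κ, the distance at which the
correlation has dropped to ≈ 0.1. Surveillance data are rarely complete:
herds go unsampled for reasons that may be random (MCAR), tied to observed
covariates (MAR), or tied to the unobserved status itself (MNAR). This
package implements the full simulation machinery to study how each
mechanism, at missingness fractions from 5% to 75%, distorts ρ̂ — and
whether posterior-predictive multiple imputation with Rubin's-rules pooling
repairs it.

The latent field is represented as a Gaussian Markov random field on a
triangulation (the SPDE/finite-element construction), giving a sparse
precision matrix Q(κ, τ) with σ² = 1/(2π κ² τ²). Inference is
empirical-grid Laplace: a Laplace approximation of the latent posterior
nested in a trapezoid-weighted grid over (log κ, log τ), with
profile-Laplace (skew-corrected) marginals for the regression block — the
core of the nested-Laplace (INLA) approach without its higher-order
machinery.

Because the original registry data are not public, a first-class synthetic
generator reproduces their structure: an irregular region with 76 km
maximum span, a clustered point pattern, lognormal herd sizes, herd density
computed from the generated points, and outcomes simulated from the exact
model above at (α = −4.3, β = 0.63, σ² = 0.49, ρ = 12.7 km).

## Worked example

```python
import spatmiss as sm
from spatmiss.synthetic import GeneratorConfig, generate_dataset
from spatmiss.mesh import build_mesh
from spatmiss.fields import SpdeFieldModel

ds = generate_dataset(GeneratorConfig(n=400, seed=1))
mesh = build_mesh(ds.locations, max_edge_inner=5.0, max_edge_outer=50.0,
                  min_vertex_dist=2.0, range_guess=12.7)
fit = sm.fit(ds, field_model=SpdeFieldModel(mesh, ds.locations),
             grid=sm.GridSettings(size=7),
             covariate_columns=["log_herd_size"])
for name in ("alpha", "beta_log_herd_size", "sigma2", "range"):
    s = fit.summary[name]
    print(f"{name:>20}: median {s['median']:7.3f}  sd {s['sd']:6.3f}")
```

prints (≈15 s on a laptop core):

```
               alpha: median  -4.735  sd  0.760
  beta_log_herd_size: median   0.641  sd  0.142
              sigma2: median   1.482  sd  1.158
               range: median   7.190  sd  4.070
```

The intercept and covariate effect recover their generative values (−4.3,
0.63) well within their posterior uncertainty; at n = 400 the field
parameters (σ² = 0.49, ρ = 12.7 km truth) are weakly identified, which is
exactly why the study protocol reports medians over many replicates and
excludes fits whose estimated range exceeds the 75 km region span ("no
detectable spatial correlation").

The numbered scripts under `analysis/` run the study stages end to end at
desk scale and write their tables to `results/`:

1. `01_generate_data.py` — synthetic register + descriptive statistics,
2. `02_fit_complete.py` — complete-data fit (the example above),
3. `03_missingness_study.py` — replicate masks × mechanisms × fractions,
4. `04_imputation_study.py` — multiple imputation, spatial vs non-spatial
   imputation model, Rubin/lognormal pooling.

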