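# lgcpmap

Bayesian spatial disease mapping for rare-disease registries, built
around the log-Gaussian Cox process (LGCP). The package re-implements,
as a tested and reusable pipeline, a nationwide analysis of childhood
cancer incidence from exact residential geocodes: indirect
standardisation for age and calendar year, a continuously indexed
Matérn latent field fitted through its sparse SPDE representation,
penalised-complexity priors, posterior relative-risk and
exceedance-probability maps, a Bayesian R² for spatial variance
explained, an areal Besag–York–Mollié (BYM) comparator and a
range-prior sensitivity scan. Registry data of this kind are
confidential, so the package ships a synthetic-registry generator that
reproduces the statistical structure of the real study (three age
groups 0–4 / 5–9 / 10–15, years 1985–2015, censuses in 1990, 2000 and
2010–2015, roughly 6 000 cases, SD-scaled covariate surfaces) and every
stage is exercised end-to-end against it.

It is aimed at spatial epidemiologists and biostatisticians who want a
transparent, dependency-light reference implementation of this model
class to study, extend, or validate against.

## Model

Cases form an inhomogeneous Poisson process on the observation window
W with random intensity e(s)·r(s), where e(s) is the intensity of
expected cases under indirect standardisation and r(s) the relative
risk. Expected counts per 1 km² grid cell k are

    E_k = Σ_i Σ_j q_ij · P_ijk

with q_ij the nationwide incidence rate and P_ijk person-years in age
group i, year j, cell k (census years linearly interpolated). The
log-risk surface is a spatial mixed-effects model

    log r(s) = X(s)β + Z(s),      Z ~ GRF(0, Matérn(σ, ρ, ν=1)),

where the range ρ is the distance at which the field correlation falls
to 0.10. Z is approximated by a piecewise-linear finite-element basis
on a triangulation, making the basis weights a Gaussian Markov random
field with sparse precision Q(ρ, σ). Priors: β ~ N(0, 10·I),
σ ~ PC prior with P(σ > 1) = 0.01, ρ ~ PC prior with P(ρ < 60 km) = 0.5.
Fitting discretises the likelihood to cell-level Poisson counts with
offset E_k and uses a simplified INLA scheme: a Laplace (Gaussian)
approximation of (Z, β) at each point of a deterministic grid over
(log σ, log ρ), mixed with normalised evidence weights. Outputs are
posterior medians of RR = exp{Z(s)} per cell, exceedance probabilities
P(RR > 1 | data), fixed-effect tables exp{β_i} with 95% credibility
intervals, and the explained-variance statistic
R² = V(Xβ) / (V(Xβ) + V(Z)) over the K spatial units.

## Worked example

```python
import numpy as np
from lgcpmap import synthdata, standardise, spdecore, lgcpfit, posterior

grid = synthdata.GridSpec(synthdata.square_window(30.0), cell_size=1.0)
cfg = synthdata.ScenarioConfig(seed=4, true_rho=15.0, true_sigma=0.15,
                               national_population=400_000,
                               target_total_cases=6000)
mesh = spdecore.build_mesh(grid, node_spacing=5.0, buffer=20.0)
scen = synthdata.simulate_scenario(grid, cfg, mesh=mesh)

rates = standardise.national_rates(scen.cases, scen.panel)
expected = standardise.expected_cases(rates, scen.panel)
data = lgcpfit.ModelData(counts=scen.cases.counts_per_cell(grid),
                         offset=expected.E, design=scen.covariates,
                         projector=spdecore.make_projector(mesh, grid.centroids))
fit = lgcpfit.fit_lgcp(data, mesh)
samples = lgcpfit.posterior_samples(fit, 2000, seed=1)

print(posterior.fixed_effects_table(samples).round(3).to_string(index=False))
r2 = posterior.bayesian_r2(samples)
print(f"R2 = {r2.median:.2f} ({r2.ci_low:.2f}, {r2.ci_high:.2f})")
rm = posterior.rr_map(samples)
print(f"RR range [{rm.rr_min:.2f}, {rm.rr_max:.2f}]")
```

prints (radiation was simulated at RR 1.17 per SD, French language
region at 1.18 against the German reference):

```
       covariate  rr_median  rr_lo  rr_hi
       intercept      0.822  0.581  1.211
             no2      0.977  0.894  1.056
       radiation      1.172  1.072  1.278
             sep      1.046  0.947  1.151
  registry_years      1.063  1.013  1.116
     lang:French      1.178  0.954  1.421
    lang:Italian      1.067  0.839  1.326
urban:semi-urban      0.869  0.723  1.047
     urban:urban      0.983  0.833  1.153
R2 = 0.83 (0.43, 0.92)
RR range [0.87, 1.20]
```

The simulated radiation and language-region effects are recovered
near their true values with the truth inside every interval; 83% of
this realisation's spatial variation is attributed to the covariates,
and the residual relative-risk surface spans 0.87–1.20 across cells. A full experiment —
unadjusted/adjusted × diagnosis/birth variants, BYM comparator,
sensitivity scan — runs from one config:

```sh
lgcpmap run-all --config config.yaml --seed 1
lgcpmap sensitivity --config config.yaml
```

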