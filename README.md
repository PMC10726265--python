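# streamocc

Hierarchical multispecies, multiscale occupancy modelling for nested
stream-survey designs with imperfect detection.

`streamocc` is for fish and stream ecologists analysing repeat-visit,
two-gear survey data — snorkeling and seining passes over riffle-run-pool
complexes ("sites") nested within stream reaches across ecoregions — who
want occurrence-habitat relationships that are not confounded by imperfect
detection.  The motivating system is spring-associated fishes (least
darter, redspot chub, southern redbelly dace, and two smallmouth bass age
classes) in two separated karst ecoregions, but the machinery is generic.

## The model

True occurrence of species *i* at site *j* is latent and each survey *k*
conditions on it:

    z_ij  ~ Bernoulli(Ψ_ij)
    y_ijk ~ Bernoulli(z_ij · p_ijk)

with logistic regressions on standardized covariates at both scales:

    logit(Ψ_ij)  = x'_occ(j) β_i + u_{r(j),i}          (site + reach covariates)
    logit(p_ijk) = x'_det(j,k) α_i + x'_shared(j,k) γ  (survey covariates)

Species coefficients are deflections around community hypermeans
(α_ic ~ N(μ_c, σ_c), likewise β), gear × covariate detection responses γ
are shared among species, and u is a reach random intercept absorbing the
spatial correlation of nested sites.  The latent z is marginalized
analytically in the likelihood.  Inference is by component-wise adaptive
Metropolis MCMC with split-R-hat/ESS diagnostics, posterior-mode and 95%
highest-density-interval summaries, backward covariate selection, and
marginal-effect curves on natural covariate scales.  A synthetic-data
generator reproduces the study design (153 sites in 61 reaches, 64/89
ecoregion split, ≤ 2 gears × 2 occasions, 5 taxa, field covariate
distributions) with known truth for every recovery test.
See `docs/methods.md` for the full model and design choices.

## Worked example

```python
import numpy as np
import streamocc as so

# a compact synthetic survey: 2 species, 40 sites in 16 reaches
spec = so.ModelSpec(
    det_covariates=("depth",), det_quadratic=(), det_gear=True,
    det_ecoregion=False, gear_by_covariate=False,
    occ_covariates=("temperature", "rpd"), occ_interactions=(),
    occ_ecoregion=False, occ_year=False, vary_by_ecoregion=())
cfg = so.GeneratorConfig(
    n_sites=40, n_reaches=16, site_split=(18, 22), reach_split=(7, 9),
    year_split=(8, 8), species=("sp1", "sp2"), spec=spec,
    effects=so.TrueEffects(
        det=(("intercept", 0.0), ("gear", 1.0)),
        occ=(("intercept", 0.0), ("temperature", 0.8), ("rpd", -0.8))))
syn = so.generate(cfg, seed=11)

ps = so.run_mcmc(spec, syn.dataset, n_chains=2, n_iter=1500,
                 n_warmup=750, seed=1)
for name in ("mu_beta[temperature]", "mu_beta[rpd]", "mu_alpha[gear]"):
    lo, hi = so.hdi(ps.pooled(name))
    print(f"{name}: median {np.median(ps.pooled(name)):+.2f} "
          f"95% HDI [{lo:+.2f}, {hi:+.2f}]")
```

prints (true hypermeans +0.8, −0.8, +1.0):

```
mu_beta[temperature]: median +1.04 95% HDI [-0.39, +2.21]
mu_beta[rpd]: median -1.14 95% HDI [-2.93, +0.60]
mu_alpha[gear]: median +0.67 95% HDI [-0.93, +2.01]
```

The community temperature and RPD hypermeans land near their generating
values, with the wide HDIs a 2-species assemblage on 40 sites warrants,
and the gear hypermean points at the snorkeling detection advantage on
the logit scale.
From a fitted posterior, `so.detection_table(ps)` gives per-species ×
gear × ecoregion detection probabilities (mode and 95% HDI) at mean
covariates, `so.effect_curve(ps, "rpd", "sp1")` a marginal occurrence
curve over the observed RPD range, and `so.backward_select(spec,
syn.dataset)` the covariate-selection trace.

A CLI mirrors these surfaces:

```sh
streamocc simulate --out data/ --seed 1
streamocc validate data/
streamocc fit --data data/ --chains 3 --iter 4000 --seed 1 --out posterior/
streamocc select --data data/ --seed 1
```

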