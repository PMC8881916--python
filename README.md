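# fishdyn

Size-structured population dynamics for stream fish monitoring data.

Long-term electrofishing programs record individual body lengths and catch
counts at many sites.  `fishdyn` turns such data into site-level demographic
inference in four stages:

1. **Length classes** — per sampling event, body lengths are split into
   young-of-the-year (0+) and older (>0+) fish with a two-normal mixture
   (EM); the class boundary is the crossing point of the weighted component
   densities.  A random-forest classifier calibrated on clearly bimodal
   events (features: length, event catch, degree-days above 12 °C) extends
   the split to weakly bimodal events, validated by repeated split-sample
   cross-validation with Cohen's κ.
2. **Hierarchical Bayesian dynamics** — log-abundances of the two classes
   follow coupled state equations: recruitment of 0+ fish driven by same-year
   >0+ density, and a modified stochastic Gompertz model for >0+ fish with
   productivity α, density dependence β, apparent survival δ of 0+ fish, and
   linear + quadratic effects γ of z-scored temperature mean and variability,
   all with sampling-area offsets:

       X0[i,t] ~ N(α0ᵢ + β0ᵢ·X1[i,t]/log Sᵢₜ + Σⱼ γ0ᵢⱼ·Uⱼᵢₜ + log Sᵢₜ, σ0)
       X1[i,t] ~ N(α1ᵢ + X1[i,t−1] + β1ᵢ·X1[i,t−1]/log Sᵢ,ₜ₋₁
                   + δ1ᵢ·X0[i,t−1]/log Sᵢ,ₜ₋₁ + Σⱼ γ1ᵢⱼ·Uⱼᵢₜ
                   + log(Sᵢₜ/Sᵢ,ₜ₋₁), σ1)

   Site coefficients are exchangeable draws from normal hyper-distributions
   (Normal(0, 10) priors on the means, half-Cauchy on all SD scales).
   Inference is a blocked Gibbs sampler (conjugate updates for coefficients,
   hyper-means and latent missing years; slice sampling for SD scales), with
   R̂ convergence checks, HPD intervals, posterior-overlap comparisons and
   χ² posterior predictive checks.
3. **Elasticities** — posterior-median coefficients project log-abundance
   deterministically over the study period; each parameter family is
   perturbed by 10% (temperature linear + quadratic terms jointly) and the
   elasticity e = Δθ/θ per unit relative perturbation measures its
   contribution to the dynamics.
4. **Spatial hypotheses** — site-mean elasticities are regressed on
   elevation, latitude, and haversine distance to the range center
   (quadratic OLS models) and compared by AIC against an intercept-only
   null: elevation/latitude wins support a range-shift interpretation,
   distance wins an abundant-center one.

A first-class synthetic-data generator (`fishdyn.synthetic`) produces
site-structured studies with known ground truth — including length mixtures,
elevation-correlated temperature covariates, injected spatial gradients and
filter-compliant missing-year patterns — so the entire pipeline is testable
without any monitoring data.

## Worked example

```python
import fishdyn as fd

study = fd.make_study(n_sites=30, n_years=20, seed=11)   # known ground truth
model = fd.build_model(study["panel"], study["U"])
draws = fd.fit(model, seed=1)        # 3 chains x 11,000, burn-in 1,000, thin 10

summary = draws.summary()
print(summary[summary.parameter.isin(
    ["mu_beta0", "mu_alpha1", "mu_beta1", "mu_delta1"])].round(3))
```

```
parameter  median  hpd_low  hpd_high  rhat
 mu_beta0   1.651    1.145     2.257 1.002
mu_alpha1   1.455    0.885     2.007 1.015
 mu_beta1  -4.269   -4.759    -3.732 1.000
mu_delta1   0.393   -0.011     0.885 1.016
```

Every R̂ is below 1.1 (max 1.016 here) and each 95% HPD interval covers the
generating hyper-mean (the study was simulated with recruitment 1.5,
productivity 1.5, density dependence −4.5, survival 0.5).  The posterior
predictive p-values are central, indicating a well-specified model:

```python
fd.posterior_predictive_check(draws, model, seed=0)
# {'p_0plus': 0.556, 'p_oldplus': 0.514, 'n_draws': 500}

res = fd.elasticity_analysis(draws.site_medians(), study["panel"], study["U"])
res.species_mean["beta1"], res.species_mean["beta0"]
# (-11.385, +0.095)
```

The elasticities say that on these simulated populations a 10% increase in
the strength of density dependence would depress projected >0+
log-abundance by far more than a 10% change in recruitment would raise 0+
log-abundance — the dynamics are dominated by the biotic terms, with
temperature contributions an order of magnitude smaller
(`res.species_mean["tmean1"] == -0.032`).

The same analysis runs from the shell, stage by stage or end to end:

```bash
fishdyn run-all --out-dir run1 --seed 1
fishdyn fit --out-dir run1 --chains 3 --iterations 11000 --burn-in 1000 --thin 10
```

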