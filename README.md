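# reefcast

Forecasting percent coral cover on Indo-Pacific reefs through 2100 under
warming scenarios, for reef ecologists and modellers who want a transparent,
fully reproducible alternative to matrix projection models.

## The model

Coral cover *P* (% of substrate) follows a hybrid stochastic-dynamical
system.  Between acute thermal-stress events, cover obeys logistic growth
depressed by background sea-surface temperature *T*:

    dP/dt = r P (1 − P/K) − γ T(t) P

with intrinsic rate of increase *r* (yr⁻¹), carrying capacity *K* (% cover)
and temperature-impact coefficient *γ*.  During an event starting at *t_k*
with intensity ε (the "extreme-event coefficient"), growth is suspended and
cover decays exponentially:

    P(t) = P(t_k) · exp(f(ε)·(t − t_k)),   f(ε) = −ε³

for the event's duration (2–8 weeks, truncated-gamma).  Event start years
are spaced by truncated-Poisson gaps (3–9 years, mean 6, matching historical
El Niño return periods; 3–6 years in the high-frequency variant).
Temperature follows a seasonal harmonic plus a linear warming trend with
climate-change coefficient λ (°C/yr): 0 (modern), 0.015 (RCP 4.5), 0.021
(RCP 6.0), 0.039 (RCP 8.5).

With constant *T* the growth law has equilibria P₁ = 0 and
P₂ = (K/r)(r − γT); P₂ is positive and stable iff γT/r < 1, and the system
passes a transcritical bifurcation — persistence gives way to extinction —
at γT/r = 1.

Recovery parameters are estimated from yearly cover series by Bayesian
inversion of the logistic solution with lag-1 autoregressive residuals
(posterior over r, K, P₀, ρ, σ via an affine-invariant ensemble sampler);
posterior *r* draws are condensed into a Beta(α, β) distribution from which
forward simulations redraw *r* every simulated year.  γ is estimated from
the constant-temperature closed form with *r* integrated over its posterior.

## Worked example

```python
import numpy as np
import reefcast as rc

# 1. fit recovery parameters to a (here: synthetic) cover series
df = rc.generate_synthetic_cover(r=0.39, K=52.63, p0=10.0, rho=0.3, sigma=2.0,
                                 n_years=14, rng=np.random.default_rng(1))
model = rc.CoralRecoveryModel.from_dataframe(df)
result = model.fit(rc.McmcConfig(seed=1))
print(result.summary().round(3))
beta = result.beta_fit()
print(f"Beta({beta.alpha:.2f}, {beta.beta:.2f}), mean r = {beta.mean:.2f}")

# 2. project an ensemble to 2100 under a conservative warming pathway
cfg = rc.make_scenario("rcp45", "japan", n_runs=300, seed=0)
summary = rc.run_ensemble(cfg)
print(summary.summary().round(2))
```

This prints the posterior table (means, SDs, 95% intervals and R-hat for
r, K, P₀, ρ, σ), the fitted Beta condensation of the posterior *r* draws —

```
         mean     sd  95% lower  95% upper  r_hat
r       0.391  0.048      0.296      0.494  1.048
K      52.721  2.517     48.346     58.479  1.036
p0     10.631  2.017      7.268     15.374  1.047
rho     0.256  0.384     -0.479      0.933  1.040
sigma   1.585  0.447      0.954      2.670  1.031
Beta(39.39, 61.45), mean r = 0.39
```

— the posterior means land on the generating values (r = 0.39, K = 52.63) —
and the ensemble summary for the Sesoko-Island-style parameter set
(K = 52.63, Beta(3.16, 5.14) *r* draws) under RCP 4.5, whose terminal
median is 43.2% cover with modality `recovered` and `frac_recovered = 1.0`.

A terminal median of 43.2% against K = 52.63% means the ensemble holds near
carrying capacity through 2100; every run ends above the 25%-cover
"recovered" threshold.  Swapping in `"rcp60"` yields a bimodal
recovery-or-collapse split, and `"rcp85_high_frequency"` (λ = 0.039,
γ = 0.005, ε = 8, 3–6-year intervals) collapses below 1% cover.

The same operations are available from the shell via the `reefcast` CLI
(`fit`, `gamma`, `enso`, `simulate`, `ensemble`, `synth`), each honouring
`--seed`.

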