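# mhmcf

Control-function estimation of the causal effect of **menstrual hygiene
management (MHM)** — a binary, endogenous exposure — on **fertility**
(children ever born, a count outcome), in the setting of a MICS-style
cross-sectional survey of ever-married women aged 15–49, with household
**WASH** (water, sanitation and hygiene) availability as the excluded
instruments.

The package is aimed at applied health economists and epidemiologists who
want a tested, reproducible implementation of the two-stage residual
inclusion (2SRI) design for a binary treatment and a count outcome — plus a
synthetic survey generator with known ground truth, so every stage of the
pipeline can be validated end to end without access to restricted survey
microdata.

## The model

Outcome and selection equations share a latent error:

```
CEB_i  :  E[CEB_i | X_i, MHM_i] driven by  x1_i'β + γ·MHM_i + e_i
MHM_i  =  1[ x_i'α + ε_i ≥ 0 ],        ε_i ~ N(0, 1)
E[e_i | ε_i] = δ·ε_i
```

`x_i = (w_i, x1_i)` where `w_i` are the WASH availability dummies
(instruments, excluded from the outcome equation) and `x1_i` the
socio-demographic controls. Estimation is the standard two-step
control-function procedure:

1. **Probit first stage** `Pr(MHM_i | x_i) = Φ(x_i'α)`, reported as average
   marginal effects (discrete change from the base category for factors).
2. **Generalized residual** (probit score residual)

   ```
   m̂_i = MHM_i·μ(x_i'α̂) − (1 − MHM_i)·μ(−x_i'α̂),    μ(z) = φ(z)/Φ(z)
   ```

3. **Poisson second stage** with log link over `(x1, MHM, m̂)`:
   `E[CEB | ·] = exp(x1'β + γ·MHM + δ·m̂)`. The coefficient on `m̂` is the
   endogeneity test; effects are reported as incidence-rate-ratio
   percentage changes `(e^β − 1)·100`.

Inference for the two-step estimator uses a pairs bootstrap that re-runs
both stages per replicate. Companion tools: NB2 negative-binomial
sensitivity stage (variance `μ + αμ²`), OLS/2SLS placebo harness,
subsample runners, and linear-IV diagnostics (Kleibergen–Paap rk LM and
Wald F, Cragg–Donald F, Hansen J, Stock–Yogo 10%-bias critical values).

## Worked example

```python
from mhmcf import (SimulationConfig, simulate, split_visible, prepare_table,
                   fit_cf_2sri, BootstrapConfig, endogeneity_test,
                   run_diagnostics)
from mhmcf.pipeline import default_roles

cfg = SimulationConfig(seed=7)          # 4,989 women, gamma=0.05, delta=0.3
visible, _ = split_visible(simulate(cfg))
table, audit, imp, _ = prepare_table(visible)

roles = default_roles()
first, resid, fit = fit_cf_2sri(table, roles,
                                bootstrap=BootstrapConfig(reps=200, seed=1))
print(fit.irr_table().loc[["mhm", "m_hat"]])
z, p = endogeneity_test(fit)
print(run_diagnostics(table, roles, endogeneity=(z, p)).to_dict())
```

prints (bootstrap confidence intervals):

```
prepared 4989 rows; 245 MHM values imputed
       coefficient  ci_low  ci_high  irr_pct   family
mhm          0.181  -0.026    0.387     19.8  poisson
m_hat        0.211   0.086    0.335     23.4  poisson
KP rk LM = 178.69 (df 4, p = 0.0000)
KP rk Wald F = 49.74  (10% bias critical value 10.27)
Hansen J = 1.117 (df 3, p = 0.7730)
endogeneity z = 3.73 (p = 0.0002)
```

Reading it: at survey scale (n≈5,000) a single draw is noisy — the MHM
coefficient 0.181 carries a wide bootstrap CI that covers the generating
γ = 0.05 — but the significant generalized residual (z = 3.73) correctly
detects the built-in endogeneity (δ = 0.3), the rank tests show the WASH
instruments are strong, and the Hansen J test does not reject their joint
validity. Across 200 replicates at n = 20,000 the 2SRI estimate is closer
to the truth than the naive Poisson fit in ~100% of draws (the naive
estimate is biased upward by roughly 0.49 at δ = 0.3).

A command-line surface wraps the same pipeline:

```bash
mhmcf simulate --seed 3 --n 5000 --out survey.csv
mhmcf prepare survey.csv --out prepared.csv
mhmcf fit prepared.csv --bootstrap-reps 200
mhmcf diagnose prepared.csv
mhmcf run-all --config run.yaml --seed 1
```

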