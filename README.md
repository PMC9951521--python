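# purepremium

Statistical-actuarial pricing of capitated health-insurance premiums
with copula-coupled GLM frequency-severity models.

Health systems that pay insurers a fixed per-capita amount (a
*capitation* premium) must set that amount by risk group so that it
covers expected claim costs. This package estimates the **pure risk
premium** — frequency x severity, with no loadings — for the 56 risk
cells used by Colombian regulation (4 regions x 14 age/sex categories),
and is aimed at actuaries and health-economics researchers who want a
reproducible, fully statistical alternative to deterministic
sufficiency-study arithmetic.

## The model

Severity `X_i` (mean cost per person served) and user counts `Y_i` per
group-year follow GLMs with log links,

    X_i ~ F(x | mu_i, sigma),   ln mu_i     = alpha_0 + Sum_l alpha_l Region + Sum_k alpha_k AgeSex
    Y_i ~ G(y | lambda_i),      ln lambda_i = beta_0  + Sum_l beta_l Region + Sum_k beta_k AgeSex + offset(ln Exposed)

with severity families {Normal, Weibull, Lognormal, Gamma, Inverse
Gamma, Inverse Gaussian} and frequency families {Poisson, Negative
Binomial}. A bivariate copula `C_theta` (Gaussian, t, Clayton, Gumbel,
Frank or Joe) couples the margins; because `Y` is discrete the joint
density is

    h(x, y) = f(x) * [ D(G(y) | F(x)) - D(G(y-1) | F(x)) ],   D(v|u) = dC/du,

and all parameters are estimated by joint maximum likelihood. Premiums
are Monte-Carlo medians of `x_s * y_s / exposure` over 300 joint draws,
with 2.5/97.5-percentile intervals. The best of the 72 family
combinations is chosen per year by Borda's rule over five metrics (MSE,
MAPE, a copula-distance RSCE, a cross-validated copula information
criterion, and a bootstrap goodness-of-fit flag). Exposures two years
ahead come from a three-layer feed-forward network on lagged values,
and severity/frequency adjustment factors translate year-t estimates
into year-t+2 pricing conditions. The confidential source databases
are emulated by a calibrated synthetic generator (`purepremium.synthetic`),
so the whole pipeline runs end to end out of the box. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from purepremium import SyntheticConfig, simulate_panel, fit_joint, simulate_premiums
from purepremium.groups import RiskGroup

cfg = SyntheticConfig(seed=1)            # 56 groups x 7 years, calibrated defaults
panel = simulate_panel(cfg)

model = fit_joint(panel, "lognormal", "negbin", "frank", compute_se=False)
print(f"theta = {model.copula.theta:.2f}, loglik = {model.loglik:.1f}")

est = simulate_premiums(model, RiskGroup("cities", ">=75"), exposure=9000.0,
                        n_sims=300, seed=1)
print(f"premium = {est.point:.3f} [{est.lower:.3f}, {est.upper:.3f}] million COP")
```

prints

    theta = 4.92, loglik = -1895.3
    premium = 4.253 [3.140, 5.641] million COP

i.e. the fitted frequency-severity dependence is strong (Frank
`theta ~ 5`, Kendall tau ~ 0.43), and the oldest city-region group is
priced at about 4.3 million COP per exposed person-year with a 95%
Monte-Carlo interval from 3.1 to 5.6.

The same flow is scriptable from the shell:

    purepremium simulate --seed 1 --out panel.csv
    purepremium select   --panel panel.csv --out scoreboard.csv
    purepremium run-all  --seed 1 --outdir runs/

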