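# Methods

`purepremium` prices a capitated health-insurance **pure risk premium**
per risk group: the expected annual claim cost per person exposed, with
no expense or profit loading,

    premium = frequency x severity
            = (distinct people served / people exposed)
              x (total cost of care / distinct people served).

The risk groups are the 56 cells used by Colombian capitation
regulation: 4 geographic regions (normal, remote, cities, special)
crossed with 14 age/sex categories (<1y; 1-4; 5-14; 15-18 and 19-44
split by sex; then five-year bands to >=75). Costs are handled in
millions of COP at constant prices throughout.

## The statistical model

For group-year records, severity `X_i` (mean cost per person served)
and the user count `Y_i` follow GLM margins with a shared linear
predictor over region and age/sex main effects (reference-cell coding,
baseline `(normal, <1y)`):

    X_i ~ F(x | mu_i, sigma),      ln mu_i     = alpha' z_i
    Y_i ~ G(y | lambda_i),         ln lambda_i = beta' z_i + ln(exposed_i)

Severity families: Normal, Weibull, Lognormal, Gamma, Inverse Gamma,
Inverse Gaussian, all re-parameterised GAMLSS-style to (mean `mu`,
dispersion `sigma`) so one generic form `F(x | mu_i, sigma)` covers the
six (maps documented in `marginals.py`; Inverse Gamma requires
`sigma < 1` for the mean to exist and errors otherwise). Frequency:
Poisson or NB2 Negative Binomial (`Var = lambda + kappa lambda^2`).
The exposure offset makes `lambda_i / exposed_i` the frequency rate. A
single dispersion `sigma` is shared across groups; a per-group
dispersion would be a natural extension but is not implemented.

Dependence between the margins is a bivariate copula `C_theta` from six
families: Gaussian, t-Student, Clayton, Gumbel, Frank, Joe. Because the
count margin is discrete, the joint density mixes a density with a
conditional-copula difference ("the bracket"):

    h(x, y) = f(x | mu, sigma) * [ D(G(y) | F(x)) - D(G(y-1) | F(x)) ],

where `D(v|u) = dC(u,v)/du`. All parameters
`(alpha, sigma, beta, [kappa], theta)` are estimated by maximising the
resulting log likelihood, started from inference-functions-for-margins
(IFM) stage-1 fits (margins first, then `theta` alone by the bracket
likelihood); the full optimisation runs L-BFGS-B on an unconstrained
parameterisation (`log sigma`, `log kappa`, `atanh rho` /
`log(theta - c)` per family). Standard errors come from the numeric
observed information with delta-method back-transformation. The
t copula's degrees of freedom are profiled over {4, 8, 12, 30} at the
IFM stage rather than continuously optimised — more robust at
56-observations-per-year scale.

### Numerical choices

* Copula inputs are clipped to `[1e-10, 1 - 1e-10]`; the conditional's
  *second* argument `v` is only floored per family where powers would
  overflow (`exp(-600/theta)` for Clayton, `1e-50` for t, else
  `1e-300`), because `G(y-1)` carries genuinely tiny tail mass and a
  blanket floor distorts the bracket.
* The bracket is floored at `1e-300` before the log; floor hits are
  counted on the fitted model (`n_floor`).
* Frank at `|theta| < 1e-6` uses its independence-limit expressions.
* The bivariate normal CDF uses Owen's T (deterministic, ~1e-15). The
  t-copula CDF integrates the closed-form conditional over a fixed
  200-node Gauss-Legendre rule, so finite differences of `C` in `u`
  recover `D(v|u)` to ~1e-6; a cheaper 64-node scale-mixture variant
  backs the bootstrap goodness-of-fit statistics (~2e-6).
* Sampling is by conditional inversion: `u, w ~ U(0,1)`,
  `v = D^{-1}(w|u)` — closed form where available, otherwise 50
  bisection halvings plus Newton polish (tolerance well below 1e-10).

## Premiums

For each group, 300 joint draws (the default working size) are
transformed through the marginal quantile functions; each draw's
premium is `x_s * y_s / exposure`. The point estimate is the median
(robust to the heavy right tail) and the interval the 2.5/97.5
percentiles. Premiums are simulated per group from its own
`(mu_i, lambda_i)`; the exposure in the denominator is the forecast
exposure of the target year.

## Model selection

All 72 frequency x severity x copula combinations are scored per
pricing year; for grid-scale work the copula parameter uses the IFM
bracket likelihood (the winner can be refitted by full joint MLE).
Five metrics enter Borda's rule — each of the four continuous metrics
ranks the models 1, 2, ... (ties share the averaged rank), the
goodness-of-fit flag adds its 0/1 value, and the least total wins, with
a deterministic (RSCE, xvCIC, model id) tie-break:

* **MSE, MAPE** — of per-group premiums (model median vs observed
  `users/exposed x cost/users`) on the held-out latest year. Premium
  space is the decision-relevant scale. Common random numbers are used
  across models so rank differences reflect the models, not the draws.
* **RSCE** — root of summed squared differences between the fitted
  copula CDF and the empirical copula at the observation points.
* **xvCIC** — cross-validated copula log-score, negated so smaller is
  better. For the discrete margin the predictive contribution of an
  observation is the bracket mass `D(G(y)|u) - D(G(y-1)|u)`, and the
  grid scoring uses exactly that (6-fold, theta refitted per fold); a
  continuous-pair variant is available for uniform data.
* **RGOFC** — an Anderson-Darling-type distance between fitted and
  empirical copula (squared differences weighted by `C(1-C)`; an
  unweighted Cramer-von-Mises variant is configurable), with the null
  distribution obtained by parametric bootstrap (sample from the fitted
  copula, re-rank, refit, re-measure; default 200 replicates). The flag
  is 1 when p < 0.05. The observed pairs are re-ranked within the
  sample before the statistic so that the observed and bootstrap
  statistics are built identically — without this the test over-rejects
  badly (empirical size ~90%).

Pseudo-observations for the dependence metrics are **model-based PIT
residuals**: `u = F_hat(x)` for the continuous margin and the
mid-distribution transform `(G_hat(y) + G_hat(y-1))/2` for the count
margin (a randomised/jittered variant is a documented switch). Pooled
raw ranks are deliberately not used: with strong region/age effects
they measure the GLM means, not the copula. For the empirical-copula
metrics the PIT pairs are additionally rank-retransformed so margins
are exactly uniform and only dependence mismatch is scored.

Because RGOFC is the costliest metric, it is evaluated on the models
leading the four ranked metrics (default 12) on at most 200 observation
pairs; models outside the shortlist keep flag 0. The flag is worth one
point, which cannot promote a model from deep in the ranking, so the
shortlist is a safe economy.

## Exposure forecasting

Exposures per group are forecast with a three-layer feed-forward
network: `r` lagged values -> one hidden layer of `rs` logistic units ->
one output. Defaults `r = 3`, `rs = 5`, min-max scaling, full-batch
Adam (learning rate 0.02, up to 4000 epochs) with early stopping on the
last 20% of training pairs, seeded initial weights.

Two representation choices matter:

* Training operates on **increments relative to the newest lag**
  (prediction adds the modelled increment back). A bounded activation
  cannot extrapolate a trending level, but a trend's increments are
  interior points of the training range; on a noiseless linear trend
  the held-out MAPE is ~0 and always beats the last-value forecast.
* Annual exposure histories are 7-10 points per group — far too short
  for per-group networks — so the default is one **pooled** network
  over all 56 groups' log-exposure lag windows with a group-index
  input (per-group mode is available). Log-transforming makes ~2%/year
  growth an additive signal shared across groups of very different
  sizes.

Forecasts are chained: the t+1 output feeds the t+2 input window.

## Adjustment factors

Year-t estimates are transformed to year-t+2 pricing conditions by
multiplicative factors: five on severity (IBNR, benefit-basket
inclusions, comparable-technology recoveries, variation in attentions
per user, inflation) and two on frequency (effective-coverage advance,
burden-of-disease change). IBNR, inclusions, comparable and inflation
are exogenous config inputs (regulatory/sufficiency-study values are
not public; defaults 1.0). The three dynamic factors are ratios of the
forecast year-t+2 monthly average to the observed year-t average of
the corresponding monthly series (attentions per user, coverage ratio,
ICD-10 diagnoses per capita), forecast with the same network (or a
naive drift fallback). Factors are applied multiplicatively to the
simulated premium's median and interval ends — the frequency factor is
applied to the rate, the severity factor to the cost, and the premium
scales by both. Applying factors to quantiles and re-simulating with
scaled `(mu, lambda)` differ for non-linear summaries; the quantile
route is the default.

## The synthetic study

The confidential affiliate (BDUA) and service (GD/SISPRO) databases
cannot be redistributed, so the package ships a generator whose
defaults emulate the published contributory-regime descriptives for
2013-2019: regional frequencies 0.884 / 0.867 / 0.810 / 0.689 (normal,
cities, special, remote), regional severities 0.9 / 1.1 / 0.7 / 1.34
million COP, infant severity 1.8 and elderly severities up to 3.8
million COP, exposure shares 75% cities / 21.2% normal / 3.6% special /
0.2% remote growing ~2.2%/year, total 560,000 person-years (a
1-in-40 scale of the real system, keeping cell counts realistic).
Where the sources state no value the defaults are: severity dispersion
`sigma = 0.15` (year-to-year stability of group mean costs), NB2
overdispersion `kappa = 2e-4` (~3% extra relative dispersion at
group-level counts; group frequencies move a few percent per year),
Frank copula with `theta = 5` (Kendall tau ~ 0.43, positive
frequency-severity dependence), lognormal severity and NB frequency
(the most frequently selected combination in the application domain),
2% lognormal exposure noise.

The generator draws copula pairs by conditional inversion, maps them
through the marginal quantile functions, clips users at
`ceil(exposed)` (people served cannot exceed the covered population)
and sets `total_cost = x * users` — group-level severity is the group
mean cost, matching the premium's ratio definition; whether severity is
aggregated per user-year or per attention is a config switch
(`severity_unit`), since the source aggregation is not public.

What the generator does *not* emulate: person-level claim histories,
within-year seasonality of costs, structural breaks (e.g. epidemics),
migration between regions, and reporting lags. Passing tests therefore
demonstrate the statistical machinery under the stated generating
process, not robustness to those real-data features.

## Problem sizes used in the checks

Estimation checks run on 56 groups x 30 years with uniform base
exposures of 3,000 person-years per cell — away from the
users-at-ceiling boundary that tiny remote cells occupy under the
descriptive calibration, so likelihood theory applies cleanly.
Selection consistency uses 20 seeded repetitions of the full 72-model
grid with RGOFC at 200 bootstrap replicates on 200-pair subsamples;
goodness-of-fit size uses 200 null data sets of 200 pairs. Premium
convergence compares 300 draws against a 30,000-draw reference band.
The pipeline's determinism check reruns a 4-model grid end to end and
compares output bytes.

## Known limitations

* The likelihood ignores the (rare) truncation of users at the exposure
  ceiling; under the descriptive calibration the smallest remote cells
  do clip, which biases dispersion estimates slightly downward there.
* MSE/MAPE on a single held-out year carry substantial observation
  noise; frequency-family discrimination rests mainly on the
  mixed-data xvCIC.
* The RGOFC bootstrap treats the PIT pairs as given; it does not
  propagate marginal-estimation uncertainty (the full double bootstrap
  would refit all margins per replicate).
* Premium intervals reflect process risk only (parameter uncertainty is
  not propagated into the Monte Carlo).
* No loadings, expenses, copayments or income-side modelling: the pure
  premium only.
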