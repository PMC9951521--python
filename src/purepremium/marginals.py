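"""GLM marginal models for claim severity and claim frequency.

Severity X (group-mean cost per person served, continuous) follows one of
six families -- Normal, Weibull, Lognormal, Gamma, Inverse Gamma, Inverse
Gaussian -- each re-parameterised GAMLSS-style to a mean ``mu`` and a
dispersion ``sigma`` with a log link on the mean:

    ln(mu_i) = alpha_0 + sum_l alpha_l Region + sum_k alpha_k AgeSex

Frequency Y (distinct people served, a count) is Poisson or Negative
Binomial (NB2: Var = lambda + kappa lambda^2) with a log link and an
``ln(exposed)`` offset, so ``lambda_i / exposed_i`` is the frequency rate:

    ln(lambda_i) = beta_0 + sum_l beta_l Region + sum_k beta_k AgeSex
                   + offset(ln exposed)

Mean/dispersion-to-natural-parameter maps
-----------------------------------------
normal       loc = mu, scale = sigma
lognormal    meanlog = ln mu - sigma^2/2, sdlog = sigma   (mu is the mean)
gamma        shape = 1/sigma^2, scale = mu sigma^2        (Var = sigma^2 mu^2)
weibull      shape k = 1/sigma, scale = mu / Gamma(1 + sigma)
invgamma     shape a = 1/sigma^2 (requires a > 1), scale = mu (a - 1)
invgauss     Var = sigma^2 mu^3  (scipy invgauss(mu sigma^2, scale=1/sigma^2))

``sigma = 0`` is accepted by the evaluation functions as the documented
degenerate (point-mass) boundary used to exercise the premium machinery;
fitting always requires ``sigma > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .groups import N_COEF, design_matrix

SEVERITY_FAMILIES = ("normal", "weibull", "lognormal", "gamma", "invgamma", "invgauss")
FREQUENCY_FAMILIES = ("poisson", "negbin")


@dataclass
class SeverityMarginal:
    family: str
    coef: np.ndarray  # length 17
    sigma: float

    def __post_init__(self) -> None:
        if self.family not in SEVERITY_FAMILIES:
            raise ValueError(f"unknown severity family {self.family!r}")
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (N_COEF,):
            raise ValueError(f"coef must have length {N_COEF}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def mu(self, covariates) -> np.ndarray:
        """GLM mean exp(X alpha) for design rows / groups / panel frame."""
        X = _as_design(covariates)
        return np.exp(X @ self.coef)


@dataclass
class FrequencyMarginal:
    family: str
    coef: np.ndarray  # length 17
    kappa: float = 0.0  # NB2 overdispersion; ignored for poisson

    def __post_init__(self) -> None:
        if self.family not in FREQUENCY_FAMILIES:
            raise ValueError(f"unknown frequency family {self.family!r}")
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != (N_COEF,):
            raise ValueError(f"coef must have length {N_COEF}")
        if self.family == "negbin" and self.kappa <= 0:
            raise ValueError("negbin requires kappa > 0")

    def lam(self, covariates, exposure) -> np.ndarray:
        """GLM mean exp(X beta + ln exposure)."""
        exposure = np.asarray(exposure, dtype=float)
        if np.any(exposure <= 0):
            raise ValueError("exposure must be positive")
        X = _as_design(covariates)
        return np.exp(X @ self.coef) * exposure


def _as_design(covariates) -> np.ndarray:
    if isinstance(covariates, np.ndarray):
        return np.atleast_2d(covariates)
    if isinstance(covariates, pd.DataFrame):
        return design_matrix(covariates)
    if isinstance(covariates, (list, tuple)):
        return design_matrix(list(covariates))
    return design_matrix([covariates])


# ---------------------------------------------------------------------------
# distribution builders on the (mu, sigma) scale


def severity_dist(family: str, mu, sigma: float):
    """Frozen scipy distribution for severity at mean mu, dispersion sigma."""
    mu = np.asarray(mu, dtype=float)
    if np.any(~np.isfinite(mu)) or np.any(mu <= 0) and family != "normal":
        if np.any(~np.isfinite(mu)):
            raise ValueError("non-finite severity mean")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if family == "normal":
        return stats.norm(loc=mu, scale=sigma)
    if family == "lognormal":
        return stats.lognorm(s=sigma, scale=mu * np.exp(-0.5 * sigma**2))
    if family == "gamma":
        shape = 1.0 / sigma**2
        return stats.gamma(a=shape, scale=mu / shape)
    if family == "weibull":
        k = 1.0 / sigma
        return stats.weibull_min(c=k, scale=mu / special.gamma(1.0 + sigma))
    if family == "invgamma":
        a = 1.0 / sigma**2
        if a <= 1.0:
            raise ValueError("invgamma mean requires shape > 1, i.e. sigma < 1")
        return stats.invgamma(a=a, scale=mu * (a - 1.0))
    if family == "invgauss":
        lam = 1.0 / sigma**2
        return stats.invgauss(mu=mu * sigma**2, scale=lam)
    raise ValueError(f"unknown severity family {family!r}")


def sev_logpdf(family: str, x, mu, sigma: float):
    """Severity log-density on the (mu, sigma) scale.

    Direct special-function implementation (no scipy frozen-distribution
    overhead); used inside likelihood loops.  Matches ``severity_dist``.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if family == "normal":
        z = (x - mu) / sigma
        return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    if family == "lognormal":
        z = (np.log(x) - (np.log(mu) - 0.5 * sigma**2)) / sigma
        return -0.5 * z * z - np.log(x * sigma) - 0.5 * np.log(2 * np.pi)
    if family == "gamma":
        k = 1.0 / sigma**2
        th = mu / k
        return (k - 1.0) * np.log(x) - x / th - k * np.log(th) - special.gammaln(k)
    if family == "weibull":
        k = 1.0 / sigma
        c = mu / special.gamma(1.0 + sigma)
        z = x / c
        return np.log(k / c) + (k - 1.0) * np.log(z) - z**k
    if family == "invgamma":
        a = 1.0 / sigma**2
        s = mu * (a - 1.0)
        return a * np.log(s) - special.gammaln(a) - (a + 1.0) * np.log(x) - s / x
    if family == "invgauss":
        lam = 1.0 / sigma**2
        return 0.5 * (np.log(lam) - np.log(2 * np.pi) - 3.0 * np.log(x)) - lam * (
            x - mu
        ) ** 2 / (2.0 * mu**2 * x)
    raise ValueError(f"unknown severity family {family!r}")


def sev_cdf(family: str, x, mu, sigma: float):
    """Severity CDF on the (mu, sigma) scale (fast path, matches severity_dist)."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if family == "normal":
        return special.ndtr((x - mu) / sigma)
    if family == "lognormal":
        return special.ndtr((np.log(x) - (np.log(mu) - 0.5 * sigma**2)) / sigma)
    if family == "gamma":
        k = 1.0 / sigma**2
        return special.gammainc(k, x * k / mu)
    if family == "weibull":
        k = 1.0 / sigma
        c = mu / special.gamma(1.0 + sigma)
        return -np.expm1(-((x / c) ** k))
    if family == "invgamma":
        a = 1.0 / sigma**2
        s = mu * (a - 1.0)
        return special.gammaincc(a, s / x)
    if family == "invgauss":
        lam = 1.0 / sigma**2
        rt = np.sqrt(lam / x)
        a = special.ndtr(rt * (x / mu - 1.0))
        # second term in log space to dodge exp(2 lam / mu) overflow
        b = np.exp(2.0 * lam / mu + special.log_ndtr(-rt * (x / mu + 1.0)))
        return np.clip(a + b, 0.0, 1.0)
    raise ValueError(f"unknown severity family {family!r}")


def freq_cdf(family: str, y, lam, kappa: float = 0.0):
    """Count-margin CDF at integer y, with cdf(-1) = 0 (fast path)."""
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    yf = np.floor(y)
    if family == "poisson":
        val = special.gammaincc(np.maximum(yf, 0.0) + 1.0, lam)
    elif family == "negbin":
        n = 1.0 / kappa
        p = 1.0 / (1.0 + kappa * lam)
        val = special.betainc(n, np.maximum(yf, 0.0) + 1.0, p)
    else:
        raise ValueError(f"unknown frequency family {family!r}")
    return np.where(yf < 0, 0.0, val)


def freq_logpmf(family: str, y, lam, kappa: float = 0.0):
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if family == "poisson":
        return y * np.log(lam) - lam - special.gammaln(y + 1.0)
    if family == "negbin":
        n = 1.0 / kappa
        p = 1.0 / (1.0 + kappa * lam)
        return (
            special.gammaln(y + n)
            - special.gammaln(n)
            - special.gammaln(y + 1.0)
            + n * np.log(p)
            + y * np.log1p(-p)
        )
    raise ValueError(f"unknown frequency family {family!r}")


def severity_pdf_cdf(x, marginal: SeverityMarginal, covariates):
    """(density, cumulative) of the severity marginal at x for the given group."""
    mu = marginal.mu(covariates)
    x = np.asarray(x, dtype=float)
    if marginal.sigma == 0.0:  # degenerate point mass at mu
        return np.where(x == mu, np.inf, 0.0), (x >= mu).astype(float)
    dist = severity_dist(marginal.family, mu, marginal.sigma)
    return dist.pdf(x)[()], dist.cdf(x)[()]


def severity_ppf(q, marginal: SeverityMarginal, covariates):
    mu = marginal.mu(covariates)
    if marginal.sigma == 0.0:
        return np.broadcast_to(mu, np.broadcast(np.asarray(q), mu).shape).copy()[()]
    return severity_dist(marginal.family, mu, marginal.sigma).ppf(q)[()]


def frequency_dist(family: str, lam, kappa: float = 0.0):
    """Frozen scipy distribution for the count margin at mean lam."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda must be non-negative")
    if family == "poisson":
        return stats.poisson(mu=lam)
    if family == "negbin":
        n = 1.0 / kappa
        p = 1.0 / (1.0 + kappa * lam)
        return stats.nbinom(n=n, p=p)
    raise ValueError(f"unknown frequency family {family!r}")


def frequency_pmf_cdf(y, marginal: FrequencyMarginal, covariates, exposure):
    """(mass, cumulative) at integer y; the CDF convention gives cdf(-1) = 0."""
    lam = marginal.lam(covariates, exposure)
    y = np.asarray(y)
    dist = frequency_dist(marginal.family, lam, marginal.kappa)
    pmf = np.where(y < 0, 0.0, dist.pmf(np.maximum(y, 0)))
    cdf = np.where(y < 0, 0.0, dist.cdf(np.maximum(y, 0)))
    return pmf[()], cdf[()]


def frequency_ppf(q, marginal: FrequencyMarginal, covariates, exposure):
    lam = marginal.lam(covariates, exposure)
    return frequency_dist(marginal.family, lam, marginal.kappa).ppf(q)[()]


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedMarginal:
    """Stage-1 (margin-only) maximum-likelihood fit."""

    marginal: SeverityMarginal | FrequencyMarginal
    loglik: float
    converged: bool
    se: np.ndarray | None = None
    boundary: bool = False  # e.g. all-zero counts pushing lambda to 0


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient: records must span all regions "
            "and age/sex categories"
        )


def severity_observations(panel: pd.DataFrame) -> pd.DataFrame:
    """Rows with users > 0 (severity total_cost/users is defined there only)."""
    return panel[panel["users"] > 0]


def fit_marginal(panel: pd.DataFrame, family: str) -> FittedMarginal:
    """Maximum-likelihood fit of one marginal on a group x year panel.

    ``panel`` needs columns region, age_sex, exposed, users, total_cost.
    Severity families are fitted by direct ML on (alpha, log sigma);
    frequency families via statsmodels with an exposure offset.
    """
    if family in SEVERITY_FAMILIES:
        return _fit_severity(panel, family)
    if family in FREQUENCY_FAMILIES:
        return _fit_frequency(panel, family)
    raise ValueError(f"unknown family {family!r}")


def _fit_severity(panel: pd.DataFrame, family: str) -> FittedMarginal:
    obs = severity_observations(panel)
    X = design_matrix(obs)
    _check_design(X)
    x = (obs["total_cost"] / obs["users"]).to_numpy(dtype=float)

    # moment start: regress log severity on the design
    lx = np.log(np.maximum(x, 1e-12))
    alpha0, *_ = np.linalg.lstsq(X, lx, rcond=None)
    resid_sd = float(np.std(lx - X @ alpha0)) or 0.1
    sigma0 = min(resid_sd, 0.8) if family == "invgamma" else resid_sd

    def negll(params):
        alpha = params[:N_COEF]
        sigma = np.exp(params[N_COEF])
        if family == "invgamma" and sigma >= 1.0:
            return 1e12
        mu = np.exp(np.clip(X @ alpha, -30, 30))
        with np.errstate(all="ignore"):
            ll = severity_dist(family, mu, sigma).logpdf(x)
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(ll.sum())

    p0 = np.concatenate([alpha0, [np.log(max(sigma0, 1e-3))]])
    res = optimize.minimize(negll, p0, method="L-BFGS-B")
    # polish with Nelder-Mead if L-BFGS-B stalled on a rough surface
    if not res.success:
        res = optimize.minimize(negll, res.x, method="Nelder-Mead",
                                options={"maxiter": 20000, "fatol": 1e-10})
    alpha = res.x[:N_COEF]
    sigma = float(np.exp(res.x[N_COEF]))
    se = _numeric_se(negll, res.x)
    return FittedMarginal(
        marginal=SeverityMarginal(family, alpha, sigma),
        loglik=-float(res.fun),
        converged=bool(res.success or res.fun < negll(p0)),
        se=se,
    )


def _fit_frequency(panel: pd.DataFrame, family: str) -> FittedMarginal:
    X = design_matrix(panel)
    _check_design(X)
    y = panel["users"].to_numpy(dtype=float)
    exposure = panel["exposed"].to_numpy(dtype=float)
    if y.sum() == 0:
        # lambda-hat collapses to the 0 boundary; no finite MLE of beta_0
        coef = np.full(N_COEF, 0.0)
        coef[0] = -30.0
        marg = (
            FrequencyMarginal("poisson", coef)
            if family == "poisson"
            else FrequencyMarginal("negbin", coef, kappa=1e-6)
        )
        return FittedMarginal(marginal=marg, loglik=0.0, converged=False, boundary=True)
    if family == "poisson":
        mod = sm.Poisson(y, X, exposure=exposure)
        res = mod.fit(disp=0, maxiter=200)
        marg = FrequencyMarginal("poisson", res.params)
        se = np.asarray(res.bse)
    else:
        mod = sm.NegativeBinomial(y, X, exposure=exposure, loglike_method="nb2")
        res = mod.fit(disp=0, maxiter=500, method="bfgs")
        kappa = float(max(res.params[-1], 1e-8))
        marg = FrequencyMarginal("negbin", res.params[:-1], kappa=kappa)
        se = np.asarray(res.bse)
    return FittedMarginal(
        marginal=marg,
        loglik=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        se=se,
    )


def _numeric_se(negll, xopt: np.ndarray) -> np.ndarray | None:
    """Standard errors from the numeric observed information (central diffs)."""
    n = len(xopt)
    H = np.empty((n, n))
    h = 1e-4 * np.maximum(np.abs(xopt), 1.0)
    f0 = negll(xopt)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = xopt.copy(); xp[i] += h[i]
                xm = xopt.copy(); xm[i] -= h[i]
                H[i, i] = (negll(xp) - 2 * f0 + negll(xm)) / h[i] ** 2
            else:
                xpp = xopt.copy(); xpp[[i, j]] += [h[i], h[j]]
                xpm = xopt.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = xopt.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = xopt.copy(); xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (negll(xpp) - negll(xpm) - negll(xmp) + negll(xmm)) / (
                    4 * h[i] * h[j]
                )
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.any(d <= 0):
            return None
        se = np.sqrt(d)
        # delta method: last coordinate is log sigma -> se(sigma)
        se[-1] *= np.exp(xopt[-1])
        return se
    except np.linalg.LinAlgError:
        return None


def marginal_to_dict(fit: FittedMarginal) -> dict:
    m = fit.marginal
    out = {
        "family": m.family,
        "coef": list(map(float, m.coef)),
        "loglik": fit.loglik,
        "converged": fit.converged,
        "boundary": fit.boundary,
    }
    if isinstance(m, SeverityMarginal):
        out["sigma"] = m.sigma
    else:
        out["kappa"] = m.kappa
    return out
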