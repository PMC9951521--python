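"""Joint frequency-severity estimation and pure-premium simulation.

The mixed continuous-discrete joint density couples the severity density
f and the frequency CDF G through the conditional copula D(.|u):

    h(x, y) = f(x | mu, sigma) * [ D(G(y | lambda) | F(x | mu, sigma))
                                   - D(G(y - 1 | lambda) | F(x | mu, sigma)) ]

All GLM coefficients, the dispersion(s) and the copula parameter are
estimated by maximising the resulting log likelihood (observations
treated as independent), started from inference-functions-for-margins
(IFM) stage-1 fits.  The pure premium per group is then obtained by
Monte Carlo: draw (x_s, y_s) from the joint via copula sampling and
marginal quantile transforms, form premium_s = x_s * y_s / exposure, and
report the median with a 2.5/97.5-percentile interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import copulas as cop
from .copulas import CopulaSpec, T_DF_GRID
from .groups import N_COEF, RiskGroup, design_matrix, design_row
from .marginals import (
    FittedMarginal,
    FrequencyMarginal,
    SeverityMarginal,
    fit_marginal,
    freq_cdf,
    freq_logpmf,
    frequency_ppf,
    sev_cdf,
    sev_logpdf,
    severity_ppf,
)

#: floor applied to the bracketed conditional-copula difference before log
BRACKET_FLOOR = 1e-300

_UEPS = 1e-10


@dataclass
class FittedJointModel:
    severity: SeverityMarginal
    frequency: FrequencyMarginal
    copula: CopulaSpec
    loglik: float
    converged: bool
    n_floor: int = 0  # observations that hit BRACKET_FLOOR at the optimum
    se: dict | None = None

    @property
    def model_id(self) -> str:
        return f"{self.frequency.family}+{self.severity.family}+{self.copula.family}"


@dataclass
class PremiumEstimate:
    """Per-group Monte-Carlo premium: median point with 2.5/97.5 interval."""

    group: RiskGroup
    point: float
    lower: float
    upper: float
    n_sims: int

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not self.lower <= self.point <= self.upper:
            raise ValueError("interval must bracket the point estimate")


def _freq_cdf_pair(family, y, lam, kappa):
    """(G(y), G(y-1)) with one incomplete-beta/gamma pass: G(y-1) = G(y) - g(y)."""
    gy = freq_cdf(family, y, lam, kappa)
    gym1 = np.clip(gy - np.exp(freq_logpmf(family, y, lam, kappa)), 0.0, None)
    return gy, gym1


def _bracket(u, gy, gym1, spec: CopulaSpec):
    """D(G(y)|u) - D(G(y-1)|u), clipped below at BRACKET_FLOOR."""
    d1 = cop.conditional_copula(gy, u, spec)
    d0 = cop.conditional_copula(gym1, u, spec)
    return np.maximum(d1 - d0, BRACKET_FLOOR)


def joint_log_density(x, y, model: FittedJointModel, covariates, exposure):
    """Log of the mixed joint density at (x, y) for the given group/exposure."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if np.any(np.asarray(y) < 0) or np.any(np.asarray(y) != np.floor(np.asarray(y))):
        raise ValueError("y must be a non-negative integer count")
    mu = model.severity.mu(covariates)
    lam = model.frequency.lam(covariates, exposure)
    if mu.shape == (1,):  # single group: let the observation shape win
        mu, lam = mu[0], lam[0]
    sfam, sig = model.severity.family, model.severity.sigma
    ffam, kap = model.frequency.family, model.frequency.kappa
    logf = sev_logpdf(sfam, x, mu, sig)
    u = np.clip(sev_cdf(sfam, x, mu, sig), _UEPS, 1.0 - _UEPS)
    gy, gym1 = _freq_cdf_pair(ffam, np.asarray(y, dtype=float), lam, kap)
    return (logf + np.log(_bracket(u, gy, gym1, model.copula)))[()]


# ---------------------------------------------------------------------------
# joint maximum likelihood


def _theta_to_unconstrained(family: str, theta: float) -> float:
    if family in ("gaussian", "t"):
        return float(np.arctanh(np.clip(theta, -0.999, 0.999)))
    if family == "clayton":
        return float(np.log(max(theta, 1e-6)))
    if family in ("gumbel", "joe"):
        return float(np.log(max(theta - 1.0, 1e-8)))
    return float(theta)  # frank


def _theta_from_unconstrained(family: str, z: float) -> float:
    if family in ("gaussian", "t"):
        return float(np.tanh(z))
    if family == "clayton":
        return float(np.exp(np.clip(z, -30, 4.0)))
    if family in ("gumbel", "joe"):
        return float(1.0 + np.exp(np.clip(z, -30, 4.0)))
    return float(np.clip(z, -40, 40))


def _panel_arrays(panel: pd.DataFrame):
    """Design matrix and observation vectors for records with users > 0."""
    obs = panel[panel["users"] > 0]
    X = design_matrix(obs)
    x = (obs["total_cost"] / obs["users"]).to_numpy(dtype=float)
    y = obs["users"].to_numpy(dtype=float)
    e = obs["exposed"].to_numpy(dtype=float)
    return X, x, y, e


def fit_copula_ifm(
    panel: pd.DataFrame,
    severity_fit: FittedMarginal,
    frequency_fit: FittedMarginal,
    copula_family: str,
    df_grid=T_DF_GRID,
    xatol: float = 1e-7,
) -> CopulaSpec:
    """Stage-2 IFM: fit the copula parameter with marginals held fixed.

    Maximises the discrete-margin copula likelihood sum log[D(G(y)|u) -
    D(G(y-1)|u)] in theta alone; the t copula's df is profiled over
    ``df_grid``.
    """
    X, x, y, e = _panel_arrays(panel)
    sev = severity_fit.marginal
    frq = frequency_fit.marginal
    mu = np.exp(X @ sev.coef)
    lam = np.exp(X @ frq.coef) * e
    u = np.clip(sev_cdf(sev.family, x, mu, sev.sigma), _UEPS, 1.0 - _UEPS)
    gy, gym1 = _freq_cdf_pair(frq.family, y, lam, frq.kappa)

    lo, hi = cop._FIT_BOUNDS[copula_family]
    best = None
    for df in df_grid if copula_family == "t" else (8.0,):
        def negll(th):
            spec = CopulaSpec(copula_family, th, df)
            return -float(np.sum(np.log(_bracket(u, gy, gym1, spec))))

        res = optimize.minimize_scalar(
            negll, bounds=(lo + 1e-6, hi - 1e-6), method="bounded",
            options={"xatol": xatol},
        )
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x, df)
    _, th, df = best
    return CopulaSpec(copula_family, float(th), float(df))


def fit_joint(
    panel: pd.DataFrame,
    severity_family: str,
    frequency_family: str,
    copula_family: str,
    df_grid=T_DF_GRID,
    compute_se: bool = True,
    maxiter: int = 400,
) -> FittedJointModel:
    """Full joint MLE of GLM and copula parameters on a group x year panel.

    Two-stage: IFM fits provide the starting point, then all parameters
    are maximised together on an unconstrained parameterisation
    (log sigma, log kappa, mapped theta) with L-BFGS-B.
    """
    sev_fit = fit_marginal(panel, severity_family)
    frq_fit = fit_marginal(panel, frequency_family)
    spec0 = fit_copula_ifm(panel, sev_fit, frq_fit, copula_family, df_grid)

    X, x, y, e = _panel_arrays(panel)
    loge = np.log(e)
    has_kappa = frequency_family == "negbin"
    nk = N_COEF

    def unpack(params):
        alpha = params[:nk]
        sigma = float(np.exp(np.clip(params[nk], -20, 5)))
        beta = params[nk + 1 : 2 * nk + 1]
        idx = 2 * nk + 1
        kappa = float(np.exp(np.clip(params[idx], -20, 5))) if has_kappa else 0.0
        idx += int(has_kappa)
        theta = _theta_from_unconstrained(copula_family, params[idx])
        return alpha, sigma, beta, kappa, theta

    def negll(params):
        alpha, sigma, beta, kappa, theta = unpack(params)
        if severity_family == "invgamma" and sigma >= 1.0:
            return 1e12
        mu = np.exp(np.clip(X @ alpha, -30, 30))
        lam = np.exp(np.clip(X @ beta + loge, -30, 30))
        with np.errstate(all="ignore"):
            logf = sev_logpdf(severity_family, x, mu, sigma)
            u = np.clip(sev_cdf(severity_family, x, mu, sigma), _UEPS, 1.0 - _UEPS)
            gy, gym1 = _freq_cdf_pair(frequency_family, y, lam, kappa)
            spec = CopulaSpec(copula_family, theta, spec0.df)
            ll = logf + np.log(_bracket(u, gy, gym1, spec))
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(ll.sum())

    p0 = np.concatenate(
        [
            sev_fit.marginal.coef,
            [np.log(sev_fit.marginal.sigma)],
            frq_fit.marginal.coef,
            [np.log(max(frq_fit.marginal.kappa, 1e-8))] if has_kappa else [],
            [_theta_to_unconstrained(copula_family, spec0.theta)],
        ]
    )
    res = optimize.minimize(
        negll, p0, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    if res.fun > negll(p0):  # never accept a step below the IFM start
        res.x, res.fun = p0, negll(p0)

    alpha, sigma, beta, kappa, theta = unpack(res.x)
    spec = CopulaSpec(copula_family, theta, spec0.df)

    # count floor hits at the optimum
    mu = np.exp(X @ alpha)
    lam = np.exp(X @ beta + loge)
    u = np.clip(sev_cdf(severity_family, x, mu, sigma), _UEPS, 1.0 - _UEPS)
    gy, gym1 = _freq_cdf_pair(frequency_family, y, lam, kappa)
    n_floor = int(np.sum(_bracket(u, gy, gym1, spec) <= BRACKET_FLOOR))

    se = _joint_se(negll, res.x, unpack, has_kappa, copula_family) if compute_se else None
    return FittedJointModel(
        severity=SeverityMarginal(severity_family, alpha, sigma),
        frequency=FrequencyMarginal(frequency_family, beta, kappa if has_kappa else 0.0),
        copula=spec,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_floor=n_floor,
        se=se,
    )


def _joint_se(negll, xopt, unpack, has_kappa, copula_family) -> dict | None:
    """Delta-method standard errors from the numeric observed information."""
    n = len(xopt)
    h = 1e-4 * np.maximum(np.abs(xopt), 1.0)
    H = np.empty((n, n))
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
                H[i, j] = H[j, i] = (
                    negll(xpp) - negll(xpm) - negll(xmp) + negll(xmm)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    se_u = np.sqrt(d)
    nk = N_COEF
    alpha, sigma, beta, kappa, theta = unpack(xopt)
    out = {
        "alpha": se_u[:nk],
        "sigma": se_u[nk] * sigma,  # delta method through exp
        "beta": se_u[nk + 1 : 2 * nk + 1],
    }
    idx = 2 * nk + 1
    if has_kappa:
        out["kappa"] = se_u[idx] * kappa
        idx += 1
    # delta method through the theta map
    z = xopt[idx]
    if copula_family in ("gaussian", "t"):
        grad = 1.0 - np.tanh(z) ** 2
    elif copula_family == "frank":
        grad = 1.0
    else:  # clayton, gumbel, joe use a log(-shifted) map
        grad = np.exp(np.clip(z, -30, 4.0))
    out["theta"] = se_u[idx] * grad
    return out


# ---------------------------------------------------------------------------
# premium simulation


def simulate_premiums(
    model: FittedJointModel,
    group: RiskGroup,
    exposure: float,
    n_sims: int = 300,
    seed=None,
) -> PremiumEstimate:
    """Monte-Carlo pure premium for one group at the given exposure.

    Draws (x_s, y_s) from the fitted joint distribution by copula
    sampling plus marginal quantile transforms; each draw's premium is
    severity x frequency rate, x_s * (y_s / exposure).  300 draws is the
    default working size; the point estimate is the median and the
    interval the 2.5/97.5 percentiles.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    row = design_row(group)
    u, v = cop.sample_copula(n_sims, model.copula, seed)
    x = np.atleast_1d(severity_ppf(u, model.severity, row))
    y = np.atleast_1d(frequency_ppf(v, model.frequency, row, exposure))
    premiums = x * y / exposure
    lower, point, upper = np.percentile(premiums, [2.5, 50.0, 97.5])
    return PremiumEstimate(group=group, point=float(point), lower=float(lower),
                           upper=float(upper), n_sims=n_sims)


def simulate_premiums_batch(
    model: FittedJointModel,
    groups: list[RiskGroup],
    exposures,
    n_sims: int = 300,
    seed=None,
) -> list[PremiumEstimate]:
    """Vectorised premium simulation for many groups at once.

    One copula draw matrix (len(groups) x n_sims) feeds every group's
    quantile transforms; equivalent to per-group simulation but ~50x
    faster across the 56-cell table.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    exposures = np.asarray(exposures, dtype=float)
    rng = np.random.default_rng(seed)
    m = len(groups)
    u = rng.uniform(size=(m, n_sims))
    w = rng.uniform(size=(m, n_sims))
    v = np.asarray(cop.inverse_conditional(w, u, model.copula))
    X = design_matrix(groups)
    mu = np.exp(X @ model.severity.coef)[:, None]
    lam = (np.exp(X @ model.frequency.coef) * exposures)[:, None]
    from .marginals import frequency_dist, severity_dist

    if model.severity.sigma == 0.0:
        x = np.broadcast_to(mu, (m, n_sims))
    else:
        x = severity_dist(model.severity.family, mu, model.severity.sigma).ppf(u)
    y = frequency_dist(model.frequency.family, lam, model.frequency.kappa).ppf(v)
    prem = x * y / exposures[:, None]
    lo, med, hi = np.percentile(prem, [2.5, 50.0, 97.5], axis=1)
    return [
        PremiumEstimate(group=g, point=float(med[i]), lower=float(lo[i]),
                        upper=float(hi[i]), n_sims=n_sims)
        for i, g in enumerate(groups)
    ]


def premiums_table(
    model: FittedJointModel,
    exposures: dict[RiskGroup, float],
    n_sims: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Premium estimates for every group; one independent substream each."""
    rows = []
    for g, e in exposures.items():
        est = simulate_premiums(model, g, e, n_sims=n_sims,
                                seed=np.random.default_rng([seed, g.index]))
        rows.append((g.region, g.age_sex, est.point, est.lower, est.upper, n_sims))
    return pd.DataFrame(rows, columns=["region", "age_sex", "point", "lower", "upper", "n_sims"])


def model_to_dict(model: FittedJointModel) -> dict:
    return {
        "severity": {"family": model.severity.family,
                     "coef": list(map(float, model.severity.coef)),
                     "sigma": model.severity.sigma},
        "frequency": {"family": model.frequency.family,
                      "coef": list(map(float, model.frequency.coef)),
                      "kappa": model.frequency.kappa},
        "copula": cop.spec_to_dict(model.copula),
        "loglik": model.loglik,
        "converged": model.converged,
        "n_floor": model.n_floor,
    }


def model_from_dict(d: dict) -> FittedJointModel:
    return FittedJointModel(
        severity=SeverityMarginal(d["severity"]["family"],
                                  np.asarray(d["severity"]["coef"]),
                                  d["severity"]["sigma"]),
        frequency=FrequencyMarginal(d["frequency"]["family"],
                                    np.asarray(d["frequency"]["coef"]),
                                    d["frequency"].get("kappa", 0.0)),
        copula=cop.spec_from_dict(d["copula"]),
        loglik=d.get("loglik", float("nan")),
        converged=d.get("converged", True),
        n_floor=d.get("n_floor", 0),
    )
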