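"""Severity and frequency adjustment factors: year t evidence -> year t+2.

Pricing is prospective: estimates built on year-t data must represent the
economic conditions two years ahead.  Severity is adjusted by five
multiplicative factors -- incurred-but-not-reported costs (IBNR), benefit-
basket inclusions, "comparable" technology recoveries, the variation in
attentions per user, and inflation -- and frequency by two: the effective-
coverage advance and changes in the burden of disease.

IBNR, inclusions and comparable come from regulatory sufficiency studies
and are exogenous config inputs (defaults 1.0).  The three dynamic
factors are forecast from monthly series: each series is projected two
years ahead, and the factor is the ratio of the forecast year-(t+2)
monthly average to the observed year-t average.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .forecast import forecast_series
from .joint import PremiumEstimate


@dataclass
class AdjustmentFactorSet:
    """Multiplicative factors; severity and frequency compose separately."""

    # severity
    ibnr: float = 1.0
    inclusions: float = 1.0
    comparable: float = 1.0
    attentions_variation: float = 1.0
    inflation: float = 1.0
    # frequency
    coverage_advance: float = 1.0
    disease_burden: float = 1.0

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"factor {name} must be finite and positive, got {val}")


def compose_severity_factor(factors: AdjustmentFactorSet) -> float:
    """Product of the five severity components."""
    return float(
        factors.ibnr
        * factors.inclusions
        * factors.comparable
        * factors.attentions_variation
        * factors.inflation
    )


def compose_frequency_factor(factors: AdjustmentFactorSet) -> float:
    """Product of the two frequency components."""
    return float(factors.coverage_advance * factors.disease_burden)


def _ratio_factor(series: np.ndarray, method: str, seed: int) -> float:
    """Forecast 24 months ahead; mean of forecast months 13-24 (year t+2)
    over the mean of the last 12 observed months (year t)."""
    series = np.asarray(series, dtype=float)
    if len(series) < 24:
        raise ValueError("monthly series must cover at least 24 months")
    fc = forecast_series(series, horizon=24, method=method, seed=seed)
    base = float(np.mean(series[-12:]))
    if base <= 0:
        raise ValueError("year-t average must be positive")
    return float(np.mean(fc[12:24]) / base)


def estimate_dynamic_factors(
    attentions_per_user: np.ndarray,
    coverage_ratio: np.ndarray,
    diagnoses_per_capita: np.ndarray,
    inflation: float = 1.0,
    ibnr: float = 1.0,
    inclusions: float = 1.0,
    comparable: float = 1.0,
    method: str = "ann",
    seed: int = 0,
) -> AdjustmentFactorSet:
    """Build a factor set from monthly series plus exogenous inputs.

    The attentions-per-user series drives the severity attentions
    factor; the coverage ratio and the ICD-10 diagnoses-per-capita proxy
    drive the two frequency factors.  ``method`` selects the forecaster
    ('ann' or 'naive_drift').  Inflation and the regulatory components
    are passed through unchanged.
    """
    return AdjustmentFactorSet(
        ibnr=ibnr,
        inclusions=inclusions,
        comparable=comparable,
        attentions_variation=_ratio_factor(attentions_per_user, method, seed),
        inflation=inflation,
        coverage_advance=_ratio_factor(coverage_ratio, method, seed + 1),
        disease_burden=_ratio_factor(diagnoses_per_capita, method, seed + 2),
    )


def apply_factors(premium: PremiumEstimate, factors: AdjustmentFactorSet) -> PremiumEstimate:
    """Scale a year-t premium estimate to t+2 conditions.

    The severity factor scales the cost draw and the frequency factor the
    rate draw; their product -- the premium -- scales by both.  Applied
    multiplicatively to the point and both interval ends (positive
    scaling preserves the interval ordering).
    """
    scale = compose_severity_factor(factors) * compose_frequency_factor(factors)
    return PremiumEstimate(
        group=premium.group,
        point=premium.point * scale,
        lower=premium.lower * scale,
        upper=premium.upper * scale,
        n_sims=premium.n_sims,
    )


def factors_to_dict(factors: AdjustmentFactorSet) -> dict:
    return asdict(factors)


def factors_from_dict(d: dict) -> AdjustmentFactorSet:
    return AdjustmentFactorSet(**d)
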