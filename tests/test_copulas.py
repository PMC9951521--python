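"""Copula family properties: boundaries, bounds, conditionals, sampling, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from purepremium import copulas as cop
from purepremium.copulas import CopulaSpec

# representative interior parameter per family
SPECS = [
    CopulaSpec("gaussian", 0.6),
    CopulaSpec("t", 0.5, df=4.0),
    CopulaSpec("clayton", 2.0),
    CopulaSpec("gumbel", 2.0),
    CopulaSpec("frank", 5.0),
    CopulaSpec("joe", 2.5),
]


@pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.family)
class TestFamilyProperties:
    def test_uniform_margin_boundaries(self, spec):
        u = np.linspace(0.0, 1.0, 11)
        assert np.allclose(cop.copula_cdf(u, np.ones_like(u), spec), u, atol=1e-9)
        assert np.allclose(cop.copula_cdf(np.ones_like(u), u, spec), u, atol=1e-9)
        assert np.allclose(cop.copula_cdf(u, np.zeros_like(u), spec), 0.0)
        assert np.allclose(cop.copula_cdf(np.zeros_like(u), u, spec), 0.0)

    def test_frechet_hoeffding_bounds(self, spec):
        g = np.linspace(0.01, 0.99, 25)
        U, V = np.meshgrid(g, g)
        c = np.asarray(cop.copula_cdf(U.ravel(), V.ravel(), spec))
        lower = np.maximum(U.ravel() + V.ravel() - 1.0, 0.0)
        upper = np.minimum(U.ravel(), V.ravel())
        assert np.all(c >= lower - 1e-8)
        assert np.all(c <= upper + 1e-8)

    def test_two_increasing_on_random_rectangles(self, spec):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.02, 0.5, 50)
        b = a + rng.uniform(0.05, 0.45, 50)
        c_ = rng.uniform(0.02, 0.5, 50)
        d = c_ + rng.uniform(0.05, 0.45, 50)
        vol = (
            np.asarray(cop.copula_cdf(b, d, spec))
            - np.asarray(cop.copula_cdf(a, d, spec))
            - np.asarray(cop.copula_cdf(b, c_, spec))
            + np.asarray(cop.copula_cdf(a, c_, spec))
        )
        assert np.all(vol >= -1e-8)

    def test_conditional_matches_finite_difference(self, spec):
        rng = np.random.default_rng(1)
        u = rng.uniform(0.05, 0.95, 50)
        v = rng.uniform(0.05, 0.95, 50)
        eps = 3e-5
        fd = (
            np.asarray(cop.copula_cdf(u + eps, v, spec))
            - np.asarray(cop.copula_cdf(u - eps, v, spec))
        ) / (2 * eps)
        an = np.asarray(cop.conditional_copula(v, u, spec))
        assert np.max(np.abs(fd - an)) < 1e-6

    def test_conditional_boundaries_and_monotonicity(self, spec):
        u = np.full(5, 0.37)
        assert np.allclose(cop.conditional_copula(np.zeros(5), u, spec), 0.0)
        assert np.allclose(cop.conditional_copula(np.ones(5), u, spec), 1.0)
        v = np.linspace(0.01, 0.99, 40)
        d = np.asarray(cop.conditional_copula(v, np.full_like(v, 0.37), spec))
        assert np.all(np.diff(d) >= -1e-10)

    def test_inverse_conditional_roundtrip(self, spec):
        rng = np.random.default_rng(2)
        u = rng.uniform(0.05, 0.95, 200)
        w = rng.uniform(0.01, 0.99, 200)
        v = np.asarray(cop.inverse_conditional(w, u, spec))
        w_back = np.asarray(cop.conditional_copula(v, u, spec))
        assert np.max(np.abs(w_back - w)) < 1e-8

    def test_sampling_deterministic_and_tau_consistent(self, spec):
        u1, v1 = cop.sample_copula(4000, spec, 123)
        u2, v2 = cop.sample_copula(4000, spec, 123)
        assert np.array_equal(u1, u2) and np.array_equal(v1, v2)
        tau_hat = stats.kendalltau(u1, v1).statistic
        tau = cop.kendall_tau(spec)
        se = np.sqrt(2 * (2 * 4000 + 5) / (9 * 4000 * (4000 - 1)))
        assert abs(tau_hat - tau) < 4 * se

    def test_mle_recovers_theta(self, spec):
        u, v = cop.sample_copula(5000, spec, 7)
        fit = cop.fit_copula(u, v, spec.family, df_grid=(spec.df,))
        assert fit.theta_se == fit.theta_se  # not nan
        assert abs(fit.spec.theta - spec.theta) < 3 * fit.theta_se


def test_clayton_closed_form_oracle():
    # independently coded formula at a fixed point
    th = 2.0
    u, v = 0.5, 0.5
    expected = (u**-th + v**-th - 1.0) ** (-1.0 / th)
    assert np.isclose(float(cop.copula_cdf(u, v, CopulaSpec("clayton", th))), expected,
                      atol=1e-12)
    assert np.isclose(expected, 7.0 ** (-0.5), atol=1e-12)


def test_frank_independence_limit():
    spec = CopulaSpec("frank", 1e-9)
    rng = np.random.default_rng(3)
    u = rng.uniform(0.05, 0.95, 100)
    v = rng.uniform(0.05, 0.95, 100)
    assert np.allclose(cop.copula_cdf(u, v, spec), u * v, atol=1e-7)
    assert np.allclose(cop.conditional_copula(v, u, spec), v, atol=1e-7)
    assert np.allclose(cop.copula_pdf(u, v, spec), 1.0, atol=1e-6)


def test_closed_form_taus():
    assert cop.kendall_tau(CopulaSpec("clayton", 2.0)) == pytest.approx(0.5)
    assert cop.kendall_tau(CopulaSpec("gumbel", 2.0)) == pytest.approx(0.5)
    assert cop.kendall_tau(CopulaSpec("gaussian", np.sin(np.pi / 8))) == pytest.approx(0.25)
    # tau inversion round-trips
    for fam in cop.FAMILIES:
        th = cop.theta_from_tau(fam, 0.4)
        spec = CopulaSpec(fam, th, 8.0)
        assert cop.kendall_tau(spec) == pytest.approx(0.4, abs=1e-4)


def test_theta_domain_validation():
    for fam, bad in [("clayton", -1.0), ("gumbel", 0.5), ("joe", 0.9),
                     ("gaussian", 1.5), ("t", -1.0)]:
        with pytest.raises(ValueError):
            CopulaSpec(fam, bad)
    with pytest.raises(ValueError):
        CopulaSpec("t", 0.5, df=1.5)
    with pytest.raises(ValueError):
        CopulaSpec("ali-mikhail-haq", 0.5)


def test_density_integrates_to_one():
    # quadrature on the unit square for one asymmetric family
    from scipy import integrate

    spec = CopulaSpec("joe", 2.5)
    val, _ = integrate.dblquad(
        lambda v, u: float(cop.copula_pdf(u, v, spec)), 0, 1, 0, 1, epsabs=1e-6
    )
    assert val == pytest.approx(1.0, abs=1e-4)


def test_margins_of_samples_are_uniform():
    for spec in (CopulaSpec("gumbel", 2.0), CopulaSpec("clayton", 2.0)):
        u, v = cop.sample_copula(10_000, spec, 11)
        for margin in (u, v):
            p = stats.kstest(margin, "uniform").pvalue
            assert p > 0.01


def test_empirical_copula_hand_count():
    # comonotone toy sample: ranks (1,1),(2,2),(3,3),... of 12 points
    z = np.arange(1.0, 13.0)
    u, v = cop.pseudo_observations(z, z)
    emp = cop.empirical_copula((u, v))
    # C_n(6/13, 6/13): 6 of 12 points fall in the corner box
    assert emp(6 / 13, 6 / 13) == pytest.approx(0.5)
    assert emp(1.0, 1.0) == pytest.approx(1.0)
    assert emp(0.3, 0.0) == pytest.approx(0.0)


def test_empirical_copula_requires_ten_pairs():
    z = np.arange(5.0)
    with pytest.raises(ValueError):
        cop.empirical_copula((z / 6, z / 6))


def test_pseudo_observations_midrank_vs_jitter():
    y = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 3.0])
    mid = cop.pseudo_observations(y)
    assert mid[0] == mid[1]  # tied values share mid-rank
    jit = cop.pseudo_observations(y, ties="jitter", rng=0)
    assert len(set(np.round(jit, 12))) == len(y)  # jitter breaks ties


def test_bvn_cdf_matches_scipy():
    rng = np.random.default_rng(5)
    h, k = rng.normal(size=30), rng.normal(size=30)
    for rho in (-0.85, -0.2, 0.4, 0.95):
        ref = np.array(
            [stats.multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([a, b])
             for a, b in zip(h, k)]
        )
        assert np.allclose(cop.bvn_cdf(h, k, rho), ref, atol=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    u=st.floats(0.01, 0.99),
    v=st.floats(0.01, 0.99),
    fam=st.sampled_from(cop.FAMILIES),
)
def test_cdf_within_bounds_property(u, v, fam):
    theta = {"gaussian": 0.3, "t": 0.3, "clayton": 1.5, "gumbel": 1.7,
             "frank": 3.0, "joe": 1.8}[fam]
    c = float(cop.copula_cdf(u, v, CopulaSpec(fam, theta)))
    assert max(u + v - 1.0, 0.0) - 1e-9 <= c <= min(u, v) + 1e-9
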