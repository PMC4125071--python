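"""Finite-size no-error probability, covariance, capacity and optimisation."""
import numpy as np
import pytest
from scipy import stats as sps

from synmem.learning import PlasticityParams, learn_sp, sp_occupancy
from synmem.patterns import generate_prototypes
from synmem.theory_asymptotic import sp_asymptotic_optimum
from synmem.theory_finite import (
    FiniteFieldModel,
    SPFiniteModel,
    WillshawFiniteModel,
    average_over_pattern_size,
    binomial_tail_expansion,
    capacity_half,
    leading_order_capacity,
    optimal_inhibition,
    optimize_finite,
    p_noerror_binomial,
    p_noerror_gaussian,
    p_noerror_given_M,
    sp_capacity_continuous,
    sp_row_covariance,
)


def sp_condition(N):
    """Asymptotically optimal SP parameters scaled to network size N."""
    opt = sp_asymptotic_optimum()
    f = opt.beta * np.log(N) / N
    params = PlasticityParams(q_plus=opt.params["q_plus"], g_ratio=opt.params["g_ratio"])
    return opt, f, params


class TestTailExpansion:
    def test_matches_exact_tail_in_exponent(self):
        """Stirling + geometric-series tail approximation tracks the exact
        binomial tail within a few percent of the log for moderate n."""
        for n, g, x in [(200, 0.3, 0.6), (500, 0.25, 0.5), (300, 0.7, 0.45)]:
            lower = x < g
            exp = binomial_tail_expansion(n, g, x, lower=lower)
            assert exp["valid"]
            t = int(round(x * n))
            exact = (sps.binom.logcdf(t, n, g) if lower else sps.binom.logsf(t - 1, n, g))
            assert exp["log_p"] == pytest.approx(exact, rel=0.05)

    def test_flags_invalid_regime(self):
        # tail on the wrong side of the mean
        assert not binomial_tail_expansion(100, 0.5, 0.4, lower=False)["valid"]
        # geometric ratio too close to 1 (threshold at the mean)
        assert not binomial_tail_expansion(100, 0.5, 0.505, lower=False)["valid"]


class TestPNoError:
    def test_threshold_above_g_plus_kills_retrieval(self):
        fm = FiniteFieldModel(N=2000, f=0.01, g_plus=0.5, g_minus=0.2,
                              theta_scaled=0.9, M=20)
        assert p_noerror_given_M(fm, 20).p_noerror < 1e-6

    def test_huge_margin_retrieves(self):
        fm = FiniteFieldModel(N=2000, f=0.05, g_plus=1.0, g_minus=0.01,
                              theta_scaled=0.5, M=100)
        assert p_noerror_given_M(fm, 100).p_noerror > 0.999

    def test_matches_monte_carlo_field_oracle(self):
        """Exact-tail evaluation vs direct sampling of binomial fields."""
        rng = np.random.default_rng(8)
        N, M, gp, gm, theta, f = 800, 25, 0.85, 0.3, 0.65, 25 / 800
        fm = FiniteFieldModel(N=N, f=f, g_plus=gp, g_minus=gm, theta_scaled=theta, M=M)
        thr = theta * f * N
        n_mc = 4000
        ok = 0
        for _ in range(n_mc):
            h_sel = rng.binomial(M - 1, gp, size=M)
            h_ns = rng.binomial(M, gm, size=N - M)
            ok += bool((h_sel > thr).all() and (h_ns <= thr).all())
        p = p_noerror_given_M(fm, M).p_noerror
        se = np.sqrt(p * (1 - p) / n_mc)
        assert abs(ok / n_mc - p) < 4 * se

    def test_gaussian_moments_match_simulated_fields(self):
        """Gaussian means/variances agree with fields measured in learn_sp."""
        N, f, K = 500, 0.06, 20
        params = PlasticityParams(q_plus=0.5, g_ratio=1.0)
        mus, vars = [], []
        for rep in range(150):
            stream = generate_prototypes(N, K, f=f, seed=300 + rep)
            J = learn_sp(stream, params, seed=800 + rep, init="stationary").J
            sel = stream.selective_indices(0)
            if sel.size < 3:
                continue
            h_sel = J[np.ix_(sel, sel)].sum(axis=1)
            mus.append(h_sel.mean() / (sel.size - 1))
        occ = sp_occupancy(K, params, f)
        emp = np.mean(mus)
        se = np.std(mus, ddof=1) / np.sqrt(len(mus))
        assert abs(emp - occ.g_plus) < 4 * se

    def test_gaussian_at_or_above_binomial_sparse(self):
        """In the sparse regime the Gaussian tails underestimate the error
        probabilities, so the Gaussian curve overestimates retrieval."""
        opt, f, params = sp_condition(4000)
        m = SPFiniteModel(N=4000, f=f, theta_scaled=opt.theta, params=params,
                          fixed_size=True)
        K50 = capacity_half(m).capacity_P50
        for K in np.unique(np.geomspace(max(1, K50 / 10), 1.8 * K50, 10).astype(int)):
            pb = p_noerror_binomial(m, int(K)).p_noerror
            pg = p_noerror_gaussian(m, int(K)).p_noerror
            assert pg >= pb - 0.01

    def test_covariance_requires_sp(self):
        m = WillshawFiniteModel(N=1000, f=0.02, theta_scaled=0.8)
        with pytest.raises(NotImplementedError):
            p_noerror_gaussian(m, 100, with_covariance=True)


class TestRowCovariance:
    def test_against_history_monte_carlo(self):
        """Closed-form moment recursions vs direct sampling of the shared
        postsynaptic-history process."""
        f, q_plus, q_minus, K = 0.15, 0.8, 0.3, 12
        params = PlasticityParams(q_plus=q_plus, q_minus=q_minus)
        cov_p, cov_m = sp_row_covariance(K, params, f)
        rng = np.random.default_rng(17)
        n_mc, burn = 40_000, 400
        a, d = f * q_plus, f * q_minus
        m = np.full(n_mc, 0.5)
        for _ in range(burn):
            xi = rng.random(n_mc) < f
            m = np.where(xi, m * (1 - a) + a, m * (1 - d))
        # storage event on a selective postsynaptic neuron, then K-1 steps
        ms = m * (1 - q_plus) + q_plus
        mn = m * (1 - q_minus)
        for _ in range(K - 1):
            xi = rng.random(n_mc) < f
            ms = np.where(xi, ms * (1 - a) + a, ms * (1 - d))
            mn = np.where(xi, mn * (1 - a) + a, mn * (1 - d))
        for emp, closed in ((ms, cov_p), (mn, cov_m)):
            var_emp = emp.var(ddof=1)
            se = var_emp * np.sqrt(2.0 / (n_mc - 1))  # SE of a variance estimate
            assert abs(var_emp - closed) < 5 * se, (var_emp, closed)

    def test_covariance_grows_with_coding_level(self):
        params = PlasticityParams(q_plus=1.0, g_ratio=2.0)
        c_small = sp_row_covariance(50, params, 0.002)
        c_large = sp_row_covariance(50, params, 0.02)
        assert c_large[1] > c_small[1] > 0

    def test_covariance_reduces_capacity_at_large_f(self):
        N = 4000
        params = PlasticityParams(q_plus=1.0, g_ratio=2.456)
        f = 0.02  # dense enough for correlations to matter
        m_g = SPFiniteModel(N=N, f=f, theta_scaled=0.72, params=params, approx="gaussian")
        m_c = SPFiniteModel(N=N, f=f, theta_scaled=0.72, params=params, approx="gaussian_cov")
        assert capacity_half(m_c).capacity_P50 <= capacity_half(m_g).capacity_P50


class TestAveraging:
    def test_constant_function(self):
        assert average_over_pattern_size(lambda M: 0.37, 5000, 0.01) == pytest.approx(0.37)

    def test_degenerate_on_fixed_size_model(self):
        fm = FiniteFieldModel(N=2000, f=0.01, g_plus=0.9, g_minus=0.2,
                              theta_scaled=0.6, M=20)
        single = p_noerror_given_M(fm, 20).p_noerror
        assert p_noerror_binomial(
            SPWrapper(fm), 1).p_noerror == pytest.approx(single)

    def test_gaussian_surrogate_close_to_exact_sum(self):
        """The normal-weight surrogate for the pattern-size average tracks the
        exact binomial sum to ~1% across the whole retrieval curve (the
        residual is the skewness of Binomial(N, f) that the surrogate drops)."""
        N, f = 10_000, 5e-3
        params = PlasticityParams(q_plus=1.0, g_ratio=2.456)
        m = SPFiniteModel(N=N, f=f, theta_scaled=0.72, params=params)
        for K in (100, 1000, 2400, 5000):
            fm = m.field_model(K)
            p_fn = lambda M: p_noerror_given_M(fm, M).p_noerror
            exact = average_over_pattern_size(p_fn, N, f)
            surr = average_over_pattern_size(p_fn, N, f, gaussian_surrogate=True)
            assert surr == pytest.approx(exact, abs=0.01)


class SPWrapper:
    """Minimal model family returning a fixed field model (test helper)."""

    def __init__(self, fm):
        self._fm = fm
        self.N = fm.N
        self.approx = fm.approx
        self.inhibition_I = fm.inhibition_I
        self.theta_scaled = fm.theta_scaled
        self.f = fm.f
        self.fixed_size = fm.M is not None

    def field_model(self, load):
        return self._fm


class TestCapacityHalf:
    def test_zero_when_even_fresh_patterns_fail(self):
        params = PlasticityParams(q_plus=0.01, g_ratio=1.0)
        m = SPFiniteModel(N=500, f=0.02, theta_scaled=0.95, params=params)
        assert capacity_half(m).capacity_P50 == 0

    def test_monotone_in_network_size(self):
        caps = []
        for N in (2000, 4000, 8000):
            opt, f, params = sp_condition(N)
            m = SPFiniteModel(N=N, f=f, theta_scaled=opt.theta, params=params,
                              fixed_size=True)
            caps.append(capacity_half(m).capacity_P50)
        assert caps[0] <= caps[1] <= caps[2]

    def test_willshaw_capacity_positive(self):
        m = WillshawFiniteModel(N=2000, f=0.02, theta_scaled=0.8, fixed_size=True)
        cap = capacity_half(m)
        assert cap.capacity_P50 > 0
        assert p_noerror_binomial(m, cap.capacity_P50).p_noerror >= 0.5
        assert p_noerror_binomial(m, cap.capacity_P50 + 1).p_noerror < 0.5


class TestLeadingOrder:
    def test_positive_and_scaling(self):
        opt = sp_asymptotic_optimum()
        g, beta = opt.params["g_ratio"], opt.beta
        theta = 0.78
        scaled = []
        for N in (1e6, 1e9, 1e12):
            out = leading_order_capacity(N, beta, theta, g)
            assert out["capacity"] > 0
            scaled.append(out["scaled_capacity"])
        # dominant term: capacity / (N/lnN)^2 approaches the constant A1
        A1 = leading_order_capacity(1e6, beta, theta, g)["A1"]
        gaps = [abs(s - A1) for s in scaled]
        assert gaps[0] > gaps[1] > gaps[2]

    def test_agrees_with_continuous_calculation_at_large_N(self):
        opt = sp_asymptotic_optimum()
        g, beta = opt.params["g_ratio"], opt.beta
        theta = 0.78
        N = 1e7
        full = sp_capacity_continuous(N, beta, theta, g)
        lead = leading_order_capacity(N, beta, theta, g)["capacity"]
        assert lead == pytest.approx(full, rel=0.25)

    def test_invalid_regime_rejected(self):
        with pytest.raises(ValueError):
            leading_order_capacity(1e6, 2.5, 0.1, 2.456)  # theta below g_inf


@pytest.fixture(scope="module")
def opt_2000():
    return optimize_finite(2000, model="sp", refine=1)


class TestOptimizeFinite:

    def test_dominates_asymptotic_parameters(self, opt_2000):
        opt, f, params = sp_condition(2000)
        m = SPFiniteModel(N=2000, f=f, theta_scaled=opt.theta, params=params)
        base = capacity_half(m).capacity_P50
        assert opt_2000.capacity_P50 >= base

    def test_fixed_size_roughly_doubles_capacity(self):
        fl = optimize_finite(2000, model="sp", refine=1)
        fx = optimize_finite(2000, model="sp", fixed_size=True, refine=1)
        ratio = fx.capacity_P50 / fl.capacity_P50
        assert 1.4 < ratio < 2.8

    def test_larger_network_sparser_and_larger(self, opt_2000):
        big = optimize_finite(8000, model="sp", refine=1)
        assert big.capacity_P50 > opt_2000.capacity_P50
        assert big.params["f"] < opt_2000.params["f"]


class TestInhibition:
    def test_ordering_fixed_ge_inhibited_ge_plain(self):
        N = 2000
        res = optimize_finite(N, model="sp", refine=1)
        f, g = res.params["f"], res.params["g_ratio"]
        params = PlasticityParams(q_plus=1.0, g_ratio=g)
        g_inf, g1 = 1 / (1 + g), (1 + g) / (1 + g)
        thetas = np.linspace(g_inf * 1.05, 0.98, 15)
        cap0 = max(capacity_half(SPFiniteModel(N=N, f=f, theta_scaled=float(t),
                                               params=params)).capacity_P50
                   for t in thetas)
        I_star, cap_I = optimal_inhibition(N, f, params)
        cap_fix = max(capacity_half(SPFiniteModel(N=N, f=f, theta_scaled=float(t),
                                                  params=params,
                                                  fixed_size=True)).capacity_P50
                      for t in thetas)
        assert cap_fix >= cap_I.capacity_P50 >= cap0
        assert cap_I.capacity_P50 > cap0  # fluctuating sizes: inhibition helps
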