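"""Marginal likelihoods and the four interval Bayes factors."""

import math

import numpy as np
import pytest
from scipy import stats

from bayesequiv import (CauchyPrior, EquivalenceRegion, hybrid_bf01, jzs_bf01,
                        marginal_t_density, noh_bf01, oh_bf01, pooled_t,
                        summarize)
from bayesequiv.errors import DegenerateRegionError, InvalidDataError
from bayesequiv.simulation import builtin_settings, simulate_dataset


class TestMarginalTDensity:
    def test_degenerate_interval_recovers_central_density(self):
        # prior truncated to (-1e-6, 1e-6) is effectively a point mass at 0
        t, df, neff = 1.3, 28.0, 7.5
        m = marginal_t_density(t, df, neff, CauchyPrior(0, 1), (-1e-6, 1e-6))
        assert m.value == pytest.approx(stats.t.pdf(t, df), rel=1e-6)

    def test_matches_monte_carlo_prior_average(self):
        t, df, neff = 1.5, 18.0, 5.0
        prior = CauchyPrior(0.0, 1.0)
        m = marginal_t_density(t, df, neff, prior)
        rng = np.random.default_rng(4)
        draws = rng.standard_cauchy(1_000_000)  # C(0,1) deviates
        vals = stats.nct.pdf(t, df, math.sqrt(neff) * draws)
        vals = np.nan_to_num(vals, nan=0.0)
        mc, mc_se = vals.mean(), vals.std(ddof=1) / 1000
        assert abs(m.value - mc) < 3 * mc_se

    def test_interval_plus_complement_equals_full_line(self):
        t, df, neff = 0.9, 38.0, 10.0
        prior = CauchyPrior(0.0, 1 / math.sqrt(2))
        c = 0.15
        full = marginal_t_density(t, df, neff, prior).value
        w_in = prior.interval_mass(-c, c)
        inside = marginal_t_density(t, df, neff, prior, (-c, c)).value * w_in
        below = marginal_t_density(t, df, neff, prior, (-np.inf, -c)).value \
            * prior.cdf(-c)
        above = marginal_t_density(t, df, neff, prior, (c, np.inf)).value \
            * (1 - prior.cdf(c))
        assert inside + below + above == pytest.approx(full, rel=1e-8)

    def test_reports_error_bound(self):
        m = marginal_t_density(2.0, 58.0, 15.0, CauchyPrior(0, 1))
        assert 0 <= m.error < 1e-6 * max(m.value, 1)


class TestJzsBF:
    def test_data_at_null_support_the_null(self):
        s = summarize([0.0, 0.1, -0.1, 0.2, -0.2] * 10,
                      [0.0, 0.1, -0.1, 0.2, -0.2] * 10)
        tt = pooled_t(s)
        assert jzs_bf01(tt.t, tt.df, tt.effective_n, CauchyPrior(0, 1)).bf01 > 1

    def test_dense_grid_trapezoid_oracle(self):
        # independent quadrature route: trapezoid on a very dense wide grid
        t, n = 2.1, 30
        df, neff = 2 * n - 2.0, n / 2
        prior = CauchyPrior(0.0, 1 / math.sqrt(2))
        grid = np.linspace(-30, 30, 2_000_001)
        like = stats.nct.pdf(t, df, math.sqrt(neff) * grid)
        like = np.nan_to_num(like, nan=0.0)
        marg = np.trapezoid(like * stats.cauchy.pdf(grid, 0, prior.scale), grid)
        expected = stats.t.pdf(t, df) / marg
        r = jzs_bf01(t, df, neff, prior)
        assert r.bf01 == pytest.approx(expected, rel=1e-6)
        assert r.bf01 == pytest.approx(math.exp(r.log_bf01))

    def test_symmetric_in_t_for_centered_prior(self):
        a = jzs_bf01(1.7, 48.0, 12.5, CauchyPrior(0, 1))
        b = jzs_bf01(-1.7, 48.0, 12.5, CauchyPrior(0, 1))
        assert a.bf01 == pytest.approx(b.bf01, rel=1e-8)

    def test_grows_with_prior_scale(self):
        # wider priors spread the alternative thin: evidence tilts to the null
        bfs = [jzs_bf01(1.2, 58.0, 15.0, CauchyPrior(0, g)).bf01
               for g in (0.5, 1 / math.sqrt(2), 1.0, math.sqrt(2), 2.0)]
        assert all(x < y for x, y in zip(bfs, bfs[1:]))


class TestOhBF:
    def test_identical_scales_give_unit_bf(self):
        r = oh_bf01(1.1, 38.0, 10.0, r1=1.0, r0=1.0)
        assert r.bf01 == pytest.approx(1.0, rel=1e-10)

    def test_transitivity_equals_marginal_ratio(self, moderate_t):
        t, df, neff = moderate_t.t, moderate_t.df, moderate_t.effective_n
        r = oh_bf01(t, df, neff, r1=1.0, r0=0.1)
        m0 = marginal_t_density(t, df, neff, CauchyPrior(0, 0.1)).value
        m1 = marginal_t_density(t, df, neff, CauchyPrior(0, 1.0)).value
        assert r.bf01 == pytest.approx(m0 / m1, rel=1e-8)

    def test_vanishing_null_scale_recovers_point_null_bf(self, moderate_t):
        t, df, neff = moderate_t.t, moderate_t.df, moderate_t.effective_n
        r = oh_bf01(t, df, neff, r1=1.0, r0=1e-6)
        jzs = jzs_bf01(t, df, neff, CauchyPrior(0, 1.0))
        assert r.bf01 == pytest.approx(jzs.bf01, rel=1e-4)

    def test_default_null_scale_is_a_tenth(self, moderate_t):
        t, df, neff = moderate_t.t, moderate_t.df, moderate_t.effective_n
        assert oh_bf01(t, df, neff, r1=1.0).bf01 == \
            pytest.approx(oh_bf01(t, df, neff, r1=1.0, r0=0.1).bf01)


class TestNohBF:
    def test_shrinking_region_recovers_point_null_bf(self, moderate_t):
        t, df, neff = moderate_t.t, moderate_t.df, moderate_t.effective_n
        prior = CauchyPrior(0, 1.0)
        r = noh_bf01(t, df, neff, prior, EquivalenceRegion(-1e-5, 1e-5))
        jzs = jzs_bf01(t, df, neff, prior)
        assert r.bf01 == pytest.approx(jzs.bf01, rel=1e-4)

    def test_matches_monte_carlo_split_oracle(self):
        t, n, c = 0.8, 100, 0.1
        df, neff = 2 * n - 2.0, n / 2
        prior = CauchyPrior(0.0, 1.0)
        rng = np.random.default_rng(11)
        draws = rng.standard_cauchy(1_000_000)
        vals = np.nan_to_num(stats.nct.pdf(t, df, math.sqrt(neff) * draws), nan=0.0)
        inside = np.abs(draws) < c
        m0, m1 = vals[inside].mean(), vals[~inside].mean()
        se0 = vals[inside].std(ddof=1) / math.sqrt(inside.sum())
        se1 = vals[~inside].std(ddof=1) / math.sqrt((~inside).sum())
        mc_bf = m0 / m1
        mc_se = mc_bf * math.hypot(se0 / m0, se1 / m1)
        r = noh_bf01(t, df, neff, prior, EquivalenceRegion(-c, c))
        assert abs(r.bf01 - mc_bf) < 3 * mc_se

    def test_grows_with_region_width(self, moderate_t):
        # a wider interval null captures more likelihood: BF01 increases
        t, df, neff = moderate_t.t, moderate_t.df, moderate_t.effective_n
        prior = CauchyPrior(0, 1.0)
        widths = (0.05, 0.1, 0.15, 0.3)
        bfs = [noh_bf01(t, df, neff, prior, EquivalenceRegion(-c, c)).bf01
               for c in widths]
        assert all(x < y for x, y in zip(bfs, bfs[1:]))

    def test_consistent_under_interval_null(self):
        # data from delta = 0: evidence for the interval null grows with n
        null = builtin_settings()[0]
        prior = CauchyPrior(0, 1.0)
        region = EquivalenceRegion(-0.1, 0.1)
        medians = []
        for n in (30, 150):
            bfs = []
            for rep in range(30):
                g1, g2 = simulate_dataset(null, n, 1000 + rep)
                tt = pooled_t(summarize(g1, g2))
                bfs.append(noh_bf01(tt.t, tt.df, tt.effective_n, prior, region).bf01)
            medians.append(np.median(bfs))
        assert medians[1] > medians[0]

    def test_symmetric_in_t(self, default_region):
        a = noh_bf01(1.4, 58.0, 15.0, CauchyPrior(0, 1), default_region)
        b = noh_bf01(-1.4, 58.0, 15.0, CauchyPrior(0, 1), default_region)
        assert a.bf01 == pytest.approx(b.bf01, rel=1e-8)

    def test_general_t_prior_not_implemented(self, default_region):
        with pytest.raises(NotImplementedError):
            noh_bf01(1.0, 18.0, 5.0, CauchyPrior(0, 1), default_region, nu0=3)

    def test_massless_region_rejected(self):
        tiny = EquivalenceRegion(-1e-14, 1e-14)
        with pytest.raises(DegenerateRegionError):
            noh_bf01(1.0, 18.0, 5.0, CauchyPrior(0, 1), tiny)


class TestHybridBF:
    def test_zero_point_weight_equals_interval_bf(self, moderate_t, default_region):
        t, df, neff = moderate_t.t, moderate_t.df, moderate_t.effective_n
        prior = CauchyPrior(0, 1.0)
        h = hybrid_bf01(t, df, neff, prior, default_region, pi0=0.0)
        n = noh_bf01(t, df, neff, prior, default_region)
        assert h.bf01 == pytest.approx(n.bf01, rel=1e-12)

    def test_unit_point_weight_is_point_null_over_interval_alt(
            self, moderate_t, default_region):
        t, df, neff = moderate_t.t, moderate_t.df, moderate_t.effective_n
        prior = CauchyPrior(0, 1.0)
        h = hybrid_bf01(t, df, neff, prior, default_region, pi0=1.0)
        l, u = default_region.lower, default_region.upper
        m1 = (marginal_t_density(t, df, neff, prior, (-np.inf, l)).value
              * prior.cdf(l)
              + marginal_t_density(t, df, neff, prior, (u, np.inf)).value
              * (1 - prior.cdf(u))) / (1 - prior.interval_mass(l, u))
        assert h.bf01 == pytest.approx(stats.t.pdf(t, df) / m1, rel=1e-8)

    def test_numerator_linear_in_point_weight(self, moderate_t, default_region):
        t, df, neff = moderate_t.t, moderate_t.df, moderate_t.effective_n
        prior = CauchyPrior(0, 1.0)
        h0 = hybrid_bf01(t, df, neff, prior, default_region, pi0=0.0)
        h1 = hybrid_bf01(t, df, neff, prior, default_region, pi0=1.0)
        h_mid = hybrid_bf01(t, df, neff, prior, default_region, pi0=0.5)
        assert h_mid.bf01 == pytest.approx(0.5 * h0.bf01 + 0.5 * h1.bf01, rel=1e-8)

    def test_invalid_point_weight_rejected(self, moderate_t, default_region):
        with pytest.raises(InvalidDataError):
            hybrid_bf01(moderate_t.t, moderate_t.df, moderate_t.effective_n,
                        CauchyPrior(0, 1), default_region, pi0=1.5)
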