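"""Tests, bootstrap, Monte Carlo draws, and interval construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

import groupmediate as gm
from conftest import make_multi_fit, make_single_fit
from groupmediate.errors import EstimationError


class TestZAndWald:
    def test_z_from_printed_coefficients(self):
        # a3 = -0.058 with se 0.020 -> z = -2.90, p just under 0.004
        fit = make_single_fit(a1=0.292, a2=0.0, a3=-0.058, b=0.496,
                              c_prime=0.0, se_a3=0.020)
        res = gm.z_test_a3(fit)
        assert round(res.statistic, 2) == -2.90
        assert 0.003 < res.p_value < 0.005
        assert res.df is None

    def test_null_a3(self):
        fit = make_single_fit(a1=0.3, a2=0.0, a3=0.0, b=0.4, c_prime=0.0)
        res = gm.z_test_a3(fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_wald_equals_z_squared_when_b_is_deterministic(self, rng):
        # Y = M exactly: b-hat = 1 with zero variance, so avar(a3*b) reduces
        # to var(a3) and W = z^2
        n = 60
        x = rng.normal(size=n)
        g = np.repeat([0.0, 1.0], n // 2)
        m = 0.4 * x + 0.2 * x * g + rng.normal(size=n)
        y = m.copy()
        data = gm.MediationDataset(x=x, m=m, y=y, group=np.where(g > 0, "B", "A"))
        fit = gm.fit_single_group(data)
        assert fit.b == pytest.approx(1.0, abs=1e-10)
        z = gm.z_test_a3(fit).statistic
        W = gm.wald_product_test(fit).statistic
        assert W == pytest.approx(z * z, rel=1e-8)

    def test_wald_zero_when_a3_zero(self):
        fit = make_single_fit(a1=0.3, a2=0.0, a3=0.0, b=0.4, c_prime=0.0)
        res = gm.wald_product_test(fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("which", ["single", "multi"])
    def test_wald_matches_finite_difference_delta_oracle(self, small_dataset, which):
        d = small_dataset
        h = 1e-6
        if which == "single":
            fit = gm.fit_single_group(d)
            cov = gm.asymptotic_cov_products(fit)
            theta = np.array([fit.a3, fit.b])
            f = lambda t: t[0] * t[1]
            W = gm.wald_product_test(fit).statistic
        else:
            fit = gm.fit_multi_group(d)
            cov = gm.asymptotic_cov_products(fit)
            l1, l2 = fit.order
            theta = np.array([fit.a(l1), fit.b(l1), fit.a(l2), fit.b(l2)])
            f = lambda t: t[0] * t[1] - t[2] * t[3]
            W = gm.wald_diff_test(fit).statistic
        grad = np.array(
            [
                (f(theta + h * e) - f(theta - h * e)) / (2 * h)
                for e in np.eye(len(theta))
            ]
        )
        avar = grad @ cov.matrix @ grad
        W_oracle = f(theta) ** 2 / avar
        assert W == pytest.approx(W_oracle, rel=1e-8)

    def test_difference_tests_invariant_to_label_swap(self, small_dataset):
        d = small_dataset
        c = d.default_coding()
        f1, f2 = gm.fit_single_group(d, c), gm.fit_single_group(d, c.swapped())
        assert gm.z_test_a3(f1).statistic == pytest.approx(
            -gm.z_test_a3(f2).statistic, abs=1e-12
        )
        assert gm.wald_product_test(f1).statistic == pytest.approx(
            gm.wald_product_test(f2).statistic, rel=1e-12
        )
        m1 = gm.fit_multi_group(d, order=d.labels)
        m2 = gm.fit_multi_group(d, order=d.labels[::-1])
        assert gm.wald_diff_test(m1).statistic == pytest.approx(
            gm.wald_diff_test(m2).statistic, rel=1e-12
        )
        u1, u2 = m1, m2
        for cons in ({"a_equal"}, {"ab_product_equal"}):
            l1 = gm.lr_test(u1, gm.fit_multi_group(d, cons, order=d.labels))
            l2 = gm.lr_test(u2, gm.fit_multi_group(d, cons, order=d.labels[::-1]))
            assert l1.statistic == pytest.approx(l2.statistic, rel=1e-6, abs=1e-8)

    def test_wald_diff_zero_for_duplicated_groups(self, rng):
        n = 40
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.4 * m + rng.normal(size=n)
        dup = gm.MediationDataset(
            x=np.r_[x, x], m=np.r_[m, m], y=np.r_[y, y],
            group=np.array(["A"] * n + ["B"] * n, dtype=object),
        )
        fit = gm.fit_multi_group(dup)
        res = gm.wald_diff_test(fit)
        assert res.statistic == pytest.approx(0.0, abs=1e-16)


class TestLikelihoodRatio:
    def test_identical_fits_give_zero(self, small_dataset):
        u = gm.fit_multi_group(small_dataset)
        res = gm.lr_test(u, gm.fit_multi_group(small_dataset))
        assert res.statistic == 0.0
        assert res.df == 0
        assert res.p_value == 1.0

    def test_non_nested_rejected(self, small_dataset):
        u = gm.fit_multi_group(small_dataset, {"b_equal"})
        c = gm.fit_multi_group(small_dataset, {"a_equal"})
        with pytest.raises(ValueError):
            gm.lr_test(u, c)

    def test_different_data_rejected(self, small_dataset, medium_dataset):
        u = gm.fit_multi_group(small_dataset)
        c = gm.fit_multi_group(medium_dataset, {"a_equal"})
        with pytest.raises(gm.DataError):
            gm.lr_test(u, c)

    def test_equal_a_statistic_matches_deviance_oracle(self, medium_dataset):
        # oracle: direct Nelder-Mead maximization of the pooled-slope
        # heteroscedastic likelihood, all five mean parameters free
        d = medium_dataset
        u = gm.fit_multi_group(d)
        c = gm.fit_multi_group(d, {"a_equal"})
        res = gm.lr_test(u, c)
        arrays = [d.arrays(lab) for lab in d.labels]

        def m_neg2ll(theta):
            i1, i2, a = theta
            tot = 0.0
            for (x, m, _), i0 in zip(arrays, (i1, i2)):
                psi = np.mean((m - i0 - a * x) ** 2)
                tot += len(x) * (np.log(2 * np.pi) + np.log(psi) + 1.0)
            return tot

        con = optimize.minimize(
            m_neg2ll, [0, 0, 0.2], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        ).fun
        unc = sum(
            len(x) * (np.log(2 * np.pi) + np.log(u.psi_m(lab)) + 1.0)
            for lab, (x, _, _) in zip(d.labels, arrays)
        )
        assert res.statistic == pytest.approx(con - unc, abs=1e-6)
        assert res.method == "LRaM"
        assert res.df == 1

    def test_product_lr_equals_a_lr_under_shared_b(self, medium_dataset):
        # with b constrained equal (and b-hat != 0), a1*b = a2*b iff a1 = a2
        d = medium_dataset
        base = gm.fit_multi_group(d, {"b_equal", "cprime_equal"})
        lr_a = gm.lr_test(
            base, gm.fit_multi_group(d, {"a_equal", "b_equal", "cprime_equal"})
        )
        lr_ab = gm.lr_test(
            base,
            gm.fit_multi_group(d, {"ab_product_equal", "b_equal", "cprime_equal"}),
        )
        assert lr_a.statistic == pytest.approx(lr_ab.statistic, abs=1e-4)
        assert lr_a.df == lr_ab.df == 1


class TestBootstrap:
    def test_deterministic_relation_is_exact_in_every_replicate(self, rng):
        # Y = 0.4*M exactly: every bootstrap refit recovers b* = 0.4, so the
        # multi-group indirect-effect draws are exactly 0.4 * a*
        n = 50
        x = np.r_[rng.normal(size=n), rng.normal(size=n)]
        m = 0.5 * x + np.r_[rng.normal(size=n), rng.normal(size=n)]
        y = 0.4 * m
        data = gm.MediationDataset(
            x=x, m=m, y=y, group=np.array(["A"] * n + ["B"] * n, dtype=object)
        )
        draws_ab = gm.bootstrap_draws(data, "A", approach="multi", B=200, seed=5)
        draws_a = gm.bootstrap_draws(data, "A", approach="multi", B=200, seed=5)
        assert np.array_equal(draws_ab.values, draws_a.values)
        fit = gm.fit_multi_group(data)
        assert fit.b("A") == pytest.approx(0.4, abs=1e-12)
        # b* is pinned at 0.4 in all replicates => values/0.4 are LS slopes
        assert np.all(np.isfinite(draws_ab.values))
        assert draws_ab.values.std() > 0  # a* still varies

    def test_same_seed_bit_identical(self, medium_dataset):
        for approach in ("single", "multi"):
            d1 = gm.bootstrap_draws(
                medium_dataset, "difference", approach=approach, B=150, seed=42
            )
            d2 = gm.bootstrap_draws(
                medium_dataset, "difference", approach=approach, B=150, seed=42
            )
            assert np.array_equal(d1.values, d2.values)
            assert d1.n_dropped == d2.n_dropped == 0

    def test_matches_independent_resampler(self, catalog):
        # independently coded loop resampler (its own RNG stream): the two
        # bootstrap means agree within 3 combined bootstrap SEs
        data = gm.generate_dataset(catalog["I-0"], 40, 40, seed=9)
        B = 2000
        ours = gm.bootstrap_draws(data, "difference", approach="multi", B=B, seed=1)
        r = np.random.default_rng(987)
        vals = []
        arrays = {lab: data.arrays(lab) for lab in data.labels}
        for _ in range(B):
            est = {}
            for lab, (x, m, y) in arrays.items():
                k = r.integers(0, len(x), len(x))
                xs, ms, ys = x[k], m[k], y[k]
                a = np.polyfit(xs, ms, 1)[0]
                X = np.column_stack([np.ones(len(xs)), ms, xs])
                b = np.linalg.lstsq(X, ys, rcond=None)[0][1]
                est[lab] = a * b
            vals.append(est[data.labels[0]] - est[data.labels[1]])
        vals = np.asarray(vals)
        se = np.sqrt(ours.values.var() / B + vals.var() / B)
        assert abs(ours.values.mean() - vals.mean()) < 3 * se

    def test_single_approach_stratified_and_pooled(self, medium_dataset):
        for resampling in ("stratified", "pooled"):
            ds = gm.bootstrap_draws(
                medium_dataset, "difference", approach="single", B=200, seed=3,
                resampling=resampling,
            )
            assert ds.n_draws == 200
            assert np.all(np.isfinite(ds.values))
        with pytest.raises(ValueError):
            gm.bootstrap_draws(
                medium_dataset, "difference", approach="multi", B=200,
                resampling="pooled",
            )

    def test_single_approach_difference_equals_a3b_draws(self, medium_dataset):
        # the single-group difference draws are exactly (focal - reference)
        sets = gm.bootstrap_draw_sets(
            medium_dataset, ("G1", "G2", "difference"), approach="single",
            B=150, seed=11,
        )
        assert np.allclose(
            sets["difference"].values,
            sets["G2"].values - sets["G1"].values,
            atol=1e-12,
        )

    def test_small_B_rejected(self, medium_dataset):
        with pytest.raises(ValueError):
            gm.bootstrap_draws(medium_dataset, "difference", B=50)

    def test_drop_accounting(self):
        from groupmediate.inference import _finalize_draws

        vals = np.arange(1000, dtype=float)
        bad = np.zeros(1000, dtype=bool)
        bad[:30] = True  # 3% -> flagged
        with pytest.warns(UserWarning):
            ds = _finalize_draws(vals, bad, 1000, "bootstrap", 0.0, "t", "multi", None)
        assert ds.n_dropped == 30
        assert "high_drop_rate" in ds.flags
        bad[:150] = True  # 15% -> error
        with pytest.raises(EstimationError):
            _finalize_draws(vals, bad, 1000, "bootstrap", 0.0, "t", "multi", None)


class TestMonteCarlo:
    def test_zero_se_degenerates_to_point(self):
        fit = make_multi_fit(0.4, 0.5, 0.2, 0.3, se_a1=0, se_b1=0, se_a2=0, se_b2=0)
        draws = gm.monte_carlo_draws(fit, R=200, seed=1)
        assert np.all(draws["G1"].values == 0.4 * 0.5)
        ci = gm.percentile_ci(draws["G1"])
        assert ci.lower == ci.upper == pytest.approx(0.2)

    def test_same_seed_bit_identical(self):
        fit = make_multi_fit(0.4, 0.5, 0.2, 0.3)
        d1 = gm.monte_carlo_draws(fit, R=300, seed=9)["difference"]
        d2 = gm.monte_carlo_draws(fit, R=300, seed=9)["difference"]
        assert np.array_equal(d1.values, d2.values)

    def test_requires_unconstrained_fit(self, medium_dataset):
        c = gm.fit_multi_group(medium_dataset, {"b_equal"})
        with pytest.raises(EstimationError):
            gm.monte_carlo_draws(c, R=200, seed=0)

    def test_product_normal_quantile_matches_quadrature(self):
        # a-hat = b-hat = 0 with unit ses: a+ * b+ is a standard product
        # normal; compare the empirical 97.5% quantile with the value from
        # numerical integration of the product-normal CDF
        fit = make_multi_fit(0.0, 0.0, 0.0, 0.0, se_a1=1, se_b1=1)
        draws = gm.monte_carlo_draws(fit, R=200_000, seed=123)["G1"].values

        def cdf(t):
            def f(x):
                return stats.norm.pdf(x) * stats.norm.cdf(t / x)

            pos, _ = integrate.quad(f, 1e-12, 40, limit=200)
            def fneg(x):
                return stats.norm.pdf(x) * stats.norm.sf(t / x)

            neg, _ = integrate.quad(fneg, -40, -1e-12, limit=200)
            return pos + neg

        q_oracle = optimize.brentq(lambda t: cdf(t) - 0.975, 0.5, 10.0, xtol=1e-6)
        q_emp = np.quantile(draws, 0.975)
        assert abs(q_emp - q_oracle) < 0.04


class TestIntervals:
    def test_percentile_order_statistics(self):
        ds = gm.DrawSet(
            values=np.arange(1, 1001, dtype=float), provenance="bootstrap",
            point_estimate=500.0, target="difference", approach="multi",
            n_requested=1000,
        )
        ci = gm.percentile_ci(ds, 0.95)
        assert ci.lower == 25.0
        assert ci.upper == 976.0

    def test_constant_draws(self):
        ds = gm.DrawSet(
            values=np.full(500, 3.25), provenance="bootstrap",
            point_estimate=3.25, target="G1", approach="multi", n_requested=500,
        )
        for fn in (gm.percentile_ci, gm.bc_ci):
            ci = fn(ds, 0.95)
            assert ci.lower == ci.upper == 3.25

    def test_symmetric_draws_symmetric_endpoints(self, rng):
        half = np.sort(rng.normal(size=500))
        vals = np.r_[half, -half]
        ds = gm.DrawSet(
            values=vals, provenance="bootstrap", point_estimate=0.0,
            target="difference", approach="multi", n_requested=1000,
        )
        ci = gm.percentile_ci(ds, 0.95)
        assert ci.lower == pytest.approx(-ci.upper, abs=1e-12)

    def test_bc_equals_percentile_at_zero_median_bias(self):
        vals = np.arange(1, 1001, dtype=float)
        ds = gm.DrawSet(
            values=vals, provenance="bootstrap", point_estimate=500.5,
            target="G1", approach="multi", n_requested=1000,
        )
        pc, bc = gm.percentile_ci(ds, 0.95), gm.bc_ci(ds, 0.95)
        assert (bc.lower, bc.upper) == (pc.lower, pc.upper)

    def test_bc_adjusted_levels_oracle(self):
        # draws {1..1000}, point estimate 600.5: z0 = Phi^-1(0.6); the
        # adjusted levels and order-statistic indices computed from scratch
        vals = np.arange(1, 1001, dtype=float)
        ds = gm.DrawSet(
            values=vals, provenance="bootstrap", point_estimate=600.5,
            target="G1", approach="multi", n_requested=1000,
        )
        ci = gm.bc_ci(ds, 0.95)
        z0 = stats.norm.ppf(0.6)
        p_lo = stats.norm.cdf(2 * z0 - 1.959964)
        p_hi = stats.norm.cdf(2 * z0 + 1.959964)
        k_lo = int(np.floor(1001 * p_lo))
        k_hi = int(np.ceil(1001 * p_hi))
        assert ci.lower == float(vals[k_lo - 1])
        assert ci.upper == float(vals[min(k_hi, 1000) - 1])
        assert ci.flags == ()

    def test_bc_clamps_extreme_proportion(self):
        vals = np.arange(1, 1001, dtype=float)
        ds = gm.DrawSet(
            values=vals, provenance="bootstrap", point_estimate=0.5,  # below all
            target="G1", approach="multi", n_requested=1000,
        )
        ci = gm.bc_ci(ds, 0.95)
        assert "z0_clamped" in ci.flags
        assert ci.lower == 1.0

    @given(
        data=st.data(),
        level_pair=st.sampled_from([(0.90, 0.95), (0.90, 0.99), (0.95, 0.99)]),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_raising_level_never_narrows(self, data, level_pair):
        seed = data.draw(st.integers(0, 2**20))
        vals = np.random.default_rng(seed).normal(size=400)
        ds = gm.DrawSet(
            values=vals, provenance="bootstrap",
            point_estimate=float(np.median(vals)), target="G1",
            approach="multi", n_requested=400,
        )
        lo_level, hi_level = level_pair
        for fn in (gm.percentile_ci, gm.bc_ci):
            narrow, wide = fn(ds, lo_level), fn(ds, hi_level)
            assert wide.lower <= narrow.lower
            assert wide.upper >= narrow.upper

    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(-0.057, -0.001, True), (-0.01, 0.02, False), (0.0, 0.3, False),
         (0.001, 0.3, True), (-0.3, 0.0, False)],
    )
    def test_excludes_zero(self, lo, hi, expected):
        ci = gm.IntervalEstimate(
            method="PCdiffM", target="difference", lower=lo, upper=hi,
            level=0.95, n_draws=1000,
        )
        assert gm.ci_excludes_zero(ci) is expected
        assert ci.excludes_zero is expected
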