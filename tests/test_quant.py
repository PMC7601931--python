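"""Sn scale, ANOVA, planned contrasts, bootstrap null, Fisher LSD."""

import itertools
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cllassoc import (
    CohortError,
    ContrastSpec,
    QuantGroups,
    SnMode,
    anova_oneway,
    bootstrap_f_pvalue,
    fisher_lsd,
    homogeneous_group_notation,
    linear_contrast,
    sn_scale,
    trend_by_ordinal,
)
from cllassoc.quant import Transform, boxcox_transform, group_summary


def brute_sn_literal(x):
    """Pure-python double-median oracle (inner index includes i, midpoint medians)."""
    inner = [statistics.median(abs(xi - xj) for xj in x) for xi in x]
    return statistics.median(inner)


def brute_sn_rc(x):
    """Pure-python Rousseeuw-Croux oracle: high-median inner over j != i, low-median outer."""
    n = len(x)
    if n == 1:
        return 0.0
    # inner: high median (rank floor(m/2)+1) of the m = n-1 differences;
    # outer: low median (rank floor((n+1)/2)) of the n inner values
    inner = [
        sorted(abs(xi - xj) for j, xj in enumerate(x) if j != i)[(n - 1) // 2]
        for i, xi in enumerate(x)
    ]
    return 1.1926 * sorted(inner)[(n + 1) // 2 - 1]


class TestSn:
    def test_constant_vector_is_zero(self):
        assert sn_scale([4.2] * 9).sn == 0.0

    def test_hand_examples(self):
        assert sn_scale([1, 2, 3]).sn == 1.0
        assert sn_scale([0, 0, 10]).sn == 0.0

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(31)
        for mode in SnMode:
            assert sn_scale(-3.5 * x, mode).sn == pytest.approx(3.5 * sn_scale(x, mode).sn)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_literal_matches_bruteforce(self, x):
        assert sn_scale(x).sn == pytest.approx(brute_sn_literal(x), abs=1e-9)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_rousseeuw_croux_matches_bruteforce(self, x):
        assert sn_scale(x, SnMode.ROUSSEEUW_CROUX).sn == pytest.approx(brute_sn_rc(x), abs=1e-9)

    def test_rc_consistent_for_normal_sd(self, rng):
        x = rng.standard_normal(4000)
        assert sn_scale(x, SnMode.ROUSSEEUW_CROUX).sn == pytest.approx(1.0, abs=0.08)

    def test_empty_vector_rejected(self):
        with pytest.raises(CohortError):
            sn_scale([])


class TestAnova:
    def test_equal_means_give_zero_f(self):
        g = QuantGroups(["a", "b"], [np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert anova_oneway(g).f == pytest.approx(0.0)

    def test_matches_scipy_f_oneway(self, rng):
        values = [rng.standard_normal(n) + m for n, m in [(12, 0), (15, 0.5), (9, 1)]]
        g = QuantGroups(["a", "b", "c"], values)
        res = anova_oneway(g)
        ref = stats.f_oneway(*values)
        assert res.f == pytest.approx(ref.statistic)
        assert res.p_parametric == pytest.approx(ref.pvalue)
        assert res.df_between == 2 and res.df_within == 33

    def test_boxcox_recovers_log_for_lognormal(self, rng):
        values = [np.exp(rng.standard_normal(500) * 0.5 + m) for m in (0.0, 0.2, 0.1)]
        res = anova_oneway(QuantGroups(["a", "b", "c"], values), Transform.BOXCOX)
        assert res.boxcox_lambda == pytest.approx(0.0, abs=0.2)

    def test_boxcox_rejects_nonpositive(self):
        g = QuantGroups(["a", "b"], [np.array([-1.0, 2, 3]), np.array([1.0, 2, 3])])
        with pytest.raises(CohortError, match="positive"):
            anova_oneway(g, Transform.BOXCOX)

    def test_boxcox_lambda_one_is_affine_noop(self, rng):
        values = [rng.uniform(1, 5, 20) for _ in range(3)]
        g = QuantGroups(["a", "b", "c"], values)
        plain = anova_oneway(g)
        shifted = [np.array(stats.boxcox(v, lmbda=1.0)) for v in values]
        res = anova_oneway(QuantGroups(["a", "b", "c"], shifted))
        assert res.f == pytest.approx(plain.f)

    def test_degenerate_variance_is_error(self):
        g = QuantGroups(["a", "b"], [np.array([1.0, 1.0]), np.array([2.0, 2.0])])
        with pytest.raises(CohortError, match="F undefined"):
            anova_oneway(g)


class TestLinearContrast:
    def test_full_hand_computation(self):
        g = QuantGroups(
            ["a", "b", "c"],
            [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])],
        )
        res = linear_contrast(g, ContrastSpec((-1, 0, 1)))
        assert res.estimate == pytest.approx(2.0)
        assert res.f_contrast == pytest.approx(6.0)
        assert res.df_within == 6
        assert res.r_alerting == pytest.approx(1.0)
        assert res.r_effect_size == pytest.approx(np.sqrt(0.5))

    def test_equal_means_zero_contrast(self):
        g = QuantGroups(["a", "b"], [np.array([1.0, 2, 3]), np.array([2.0, 1, 3])])
        res = linear_contrast(g, ContrastSpec((-1, 1)))
        assert res.f_contrast == pytest.approx(0.0)
        assert res.r_effect_size == pytest.approx(0.0)

    def test_effect_size_formula_inversion(self):
        # |r| = sqrt(F/(F+df)) evaluated at F=4.2475, df=212
        assert np.sqrt(4.2475 / (4.2475 + 212)) == pytest.approx(0.140, abs=5e-4)

    def test_two_group_contrast_is_squared_pooled_t(self, rng):
        a, b = rng.standard_normal(14), rng.standard_normal(11) + 0.8
        res = linear_contrast(QuantGroups(["a", "b"], [a, b]), ContrastSpec((-1, 1)))
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_contrast == pytest.approx(t.statistic**2)
        assert res.p_parametric == pytest.approx(t.pvalue)

    def test_orthogonal_basis_sums_to_omnibus(self, rng):
        # balanced design: sum of contrast F over an orthogonal basis equals
        # df_between * omnibus F
        values = [rng.standard_normal(10) + m for m in (0.0, 1.0, 0.3)]
        g = QuantGroups(["a", "b", "c"], values)
        f1 = linear_contrast(g, ContrastSpec((-1, 0, 1))).f_contrast
        f2 = linear_contrast(g, ContrastSpec((1, -2, 1))).f_contrast
        omnibus = anova_oneway(g)
        assert f1 + f2 == pytest.approx(omnibus.df_between * omnibus.f)

    def test_weights_must_sum_to_zero(self):
        with pytest.raises(CohortError, match="sum to zero"):
            ContrastSpec((1.0, 1.0, -1.0))

    def test_sign_follows_contrast_estimate(self, rng):
        g = QuantGroups(
            ["lo", "mid", "hi"],
            [rng.standard_normal(20) + m for m in (3.0, 2.0, 1.0)],
        )
        res = linear_contrast(g, ContrastSpec((-1, 0, 1)))
        assert res.estimate < 0 and res.r_effect_size < 0 and res.r_alerting < 0


class TestTrend:
    def test_perfectly_linear_means(self):
        g = QuantGroups(
            ["0", "1", "2"],
            [np.array([0.9, 1.1]), np.array([1.9, 2.1]), np.array([2.9, 3.1])],
        )
        assert trend_by_ordinal(g).r_alerting == pytest.approx(1.0)

    def test_alerting_and_effect_size_decouple_under_noise(self, rng):
        # means exactly linear but a tiny slope against huge within-group
        # spread: near-perfect alerting correlation, negligible effect size
        means = np.array([0.0, 0.01, 0.02, 0.03, 0.04])
        values = [rng.standard_normal(40) * 50 - v.mean() + m
                  for m, v in zip(means, [rng.standard_normal(40)] * 5)]
        values = [v - v.mean() + m for m, v in zip(means, values)]
        g = QuantGroups([str(i) for i in range(5)], values)
        res = trend_by_ordinal(g)
        assert abs(res.r_alerting) == pytest.approx(1.0, abs=1e-9)
        assert abs(res.r_effect_size) < 0.05

    def test_needs_three_groups(self):
        g = QuantGroups(["0", "1"], [np.array([1.0, 2]), np.array([2.0, 3])])
        with pytest.raises(CohortError):
            trend_by_ordinal(g)


class TestBootstrap:
    def _groups(self, rng):
        return QuantGroups(["a", "b", "c"], [rng.standard_normal(15) + m for m in (0, 0.4, 0.9)])

    def test_seeded_determinism(self, rng):
        g = self._groups(rng)
        p1 = bootstrap_f_pvalue(g, "omnibus_F", B=400, seed=9)
        p2 = bootstrap_f_pvalue(g, "omnibus_F", B=400, seed=9)
        assert p1 == p2

    def test_invariant_to_group_relabeling(self, rng):
        g = self._groups(rng)
        perm = [2, 0, 1]
        gp = QuantGroups([g.labels[i] for i in perm], [g.values[i] for i in perm])
        assert bootstrap_f_pvalue(g, "omnibus_F", B=400, seed=9) == bootstrap_f_pvalue(
            gp, "omnibus_F", B=400, seed=9
        )

    def test_contrast_statistic_variant(self, rng):
        g = self._groups(rng)
        p = bootstrap_f_pvalue(g, "contrast_F", contrast=ContrastSpec((-1, 0, 1)), B=400, seed=2)
        assert 0 < p <= 1

    def test_degenerate_residuals_give_one(self):
        g = QuantGroups(["a", "b"], [np.array([1.0, 1.0]), np.array([5.0, 5.0])])
        assert bootstrap_f_pvalue(g, "omnibus_F", B=200, seed=0) == 1.0

    def test_b_floor_enforced(self, rng):
        with pytest.raises(CohortError):
            bootstrap_f_pvalue(self._groups(rng), "omnibus_F", B=50, seed=0)


def brute_lsd_notation(labels, values, alpha=0.05):
    """Independent clique construction: pairwise pooled-t p-values + subset scan."""
    k = len(labels)
    df_w = sum(len(v) - 1 for v in values)
    mse = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in values) / df_w
    homog = np.ones((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(mse * (1 / len(values[i]) + 1 / len(values[j])))
        t = (np.mean(values[i]) - np.mean(values[j])) / se
        p = 2 * stats.t.sf(abs(t), df_w)
        homog[i, j] = homog[j, i] = p >= alpha
    cliques = []
    for r in range(k, 0, -1):
        for combo in itertools.combinations(range(k), r):
            if all(homog[i, j] for i, j in itertools.combinations(combo, 2)) and not any(
                set(combo) <= set(c) for c in cliques
            ):
                cliques.append(combo)
    parts = []
    for c in sorted(cliques, key=lambda c: c[0]):
        names = [labels[i] for i in c]
        parts.append(names[0] if len(c) == 1 else "(" + ".".join(names) + ")")
    return " ".join(parts)


def exact_moment_groups(means, sds, sizes, rng):
    """Groups constructed to hit the requested means and SDs exactly."""
    values = []
    for m, s, n in zip(means, sds, sizes):
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std(ddof=1)
        values.append(m + s * z)
    return values


class TestFisherLsd:
    def test_identical_groups_single_clique(self):
        g = QuantGroups(
            ["A", "B", "C"],
            [np.array([1.0, 2, 3]), np.array([1.0, 2, 3]), np.array([1.0, 2, 3])],
        )
        assert fisher_lsd(g).notation == "(A.B.C)"

    def test_well_separated_groups_all_singletons(self):
        g = QuantGroups(
            ["A", "B", "C"],
            [np.array([0.0, 0.1, -0.1]), np.array([10.0, 10.1, 9.9]), np.array([20.0, 20.1, 19.9])],
        )
        assert fisher_lsd(g).notation == "A B C"

    def test_outlier_group_notation(self, rng):
        # means like the TACI-MFI pattern: one low homozygote group, the
        # other two indistinguishable
        values = exact_moment_groups([35, 43, 42], [6, 6, 6], [58, 65, 22], rng)
        g = QuantGroups(["AA", "AG", "GG"], values)
        res = fisher_lsd(g)
        assert res.notation == "AA (AG.GG)"
        assert res.notation == brute_lsd_notation(["AA", "AG", "GG"], values)

    def test_middle_group_differs_notation(self, rng):
        # het-distinct pattern: homozygotes match each other, het stands out
        values = exact_moment_groups([12.1, 7.1, 15.3], [8, 8, 8], [59, 65, 22], rng)
        g = QuantGroups(["AA", "AG", "GG"], values)
        assert fisher_lsd(g).notation == brute_lsd_notation(["AA", "AG", "GG"], values)

    def test_all_singleton_groups_error(self):
        g = QuantGroups(["A", "B"], [np.array([1.0]), np.array([2.0])])
        with pytest.raises(CohortError):
            fisher_lsd(g)


def test_group_summary_table(rng):
    g = QuantGroups(["x", "y"], [rng.standard_normal(30), rng.standard_normal(25)], units="g/L")
    df = group_summary(g)
    assert list(df["group"]) == ["x", "y"]
    assert list(df["n"]) == [30, 25]
    assert (df["q1"] <= df["median"]).all() and (df["median"] <= df["q3"]).all()


def test_boxcox_transform_bounds():
    x = np.exp(np.linspace(-1, 1, 50))
    _, lam = boxcox_transform(x)
    assert -5 <= lam <= 5
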