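"""Cohort statistics: rank tests against permutation oracles, chi-square on
a published-style contingency table, Bonferroni, Spearman and the OLS fit
against a normal-equations oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tilquant import (
    bonferroni_adjust,
    chi_square_test,
    fit_linear_model,
    kruskal_wallis,
    spearman,
    wilcoxon_rank_sum,
)
from tilquant.cohort_stats import CollinearityError, DegenerateDataError


def _kw_stat(groups):
    """Direct tie-corrected Kruskal–Wallis H for the permutation oracle."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx : idx + len(g)]
        idx += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    corr = 1.0 - (t**3 - t).sum() / (n**3 - n)
    return h / corr if corr > 0 else 0.0


def _kw_permutation_p(groups):
    """Enumerate every distinct assignment of the pooled values to groups."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    observed = _kw_stat(groups)
    count = total = 0

    def recurse(remaining, gi, chosen):
        nonlocal count, total
        if gi == len(sizes) - 1:
            arranged = chosen + [pooled[remaining]]
            total += 1
            count += _kw_stat(arranged) >= observed - 1e-12
            return
        for comb in itertools.combinations(remaining, sizes[gi]):
            rest = [r for r in remaining if r not in comb]
            recurse(rest, gi + 1, chosen + [pooled[list(comb)]])

    recurse(list(range(len(pooled))), 0, [])
    return count / total


class TestKruskalWallis:
    def test_identical_groups_h_zero_p_one(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [2, 1, 3]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_tiny_groups_agree_with_permutation_oracle(self):
        groups = [[1.2, 3.1, 0.5], [2.2, 4.0, 2.9], [5.1, 4.4, 6.0]]
        res = kruskal_wallis(groups)
        p_perm = _kw_permutation_p([np.asarray(g, float) for g in groups])
        assert abs(res.p - p_perm) <= 0.02

    def test_two_groups_match_rank_sum_approximation(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=25)
        res_kw = kruskal_wallis([a, b])
        res_w = wilcoxon_rank_sum(a, b)
        assert abs(res_kw.p - res_w.p) <= 0.01

    def test_all_tied_raises_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[2, 2], [2, 2]])

    def test_invariant_to_monotone_transform(self, rng):
        groups = [rng.exponential(size=12) for _ in range(3)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.log(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2)


class TestWilcoxonRankSum:
    def test_identical_multisets_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p >= 0.99

    def test_extreme_separation_exact_one_sided_p(self):
        """{1,2,3} entirely below {4,5,6}: one in 6!/(3!3!) = 20 orderings."""
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.p == pytest.approx(1 / 20)

    def test_two_sided_p_symmetric_in_arguments(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(loc=0.7, size=15)
        assert wilcoxon_rank_sum(a, b).p == pytest.approx(wilcoxon_rank_sum(b, a).p)

    def test_small_sample_agrees_with_permutation_oracle(self):
        a = [0.3, 1.7, 2.5, 0.9]
        b = [2.8, 3.5, 1.1]
        res = wilcoxon_rank_sum(a, b)
        pooled = np.array(a + b)
        obs = stats.mannwhitneyu(a, b).statistic
        n_a = len(a)
        count = total = 0
        mean_u = n_a * len(b) / 2
        for comb in itertools.combinations(range(7), n_a):
            aa = pooled[list(comb)]
            bb = pooled[[i for i in range(7) if i not in comb]]
            u = stats.mannwhitneyu(aa, bb).statistic
            total += 1
            count += abs(u - mean_u) >= abs(obs - mean_u) - 1e-12
        assert abs(res.p - count / total) <= 0.02


class TestChiSquare:
    def test_sex_by_cancer_type_table(self):
        """Three-cohort sex distribution (men 152/189/492 of 214/256/752)
        differs at p = 0.027."""
        res = chi_square_test([[152, 189, 492], [62, 67, 260]])
        assert res.df == 2
        assert round(res.p, 3) == 0.027

    def test_proportional_table_chi2_zero(self):
        res = chi_square_test([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_2x2_matches_hand_computation(self):
        """{{10,20},{20,10}}: expected 15 everywhere, X² = 4*(25/15)."""
        res = chi_square_test([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(4 * 25 / 15)
        assert res.df == 1

    def test_zero_marginal_raises(self):
        with pytest.raises(DegenerateDataError):
            chi_square_test([[0, 0], [5, 10]])


class TestBonferroni:
    def test_arithmetic_and_capping(self):
        out = bonferroni_adjust([0.02, 0.5, 0.012], m=3)
        assert out == pytest.approx([0.06, 1.0, 0.036])

    def test_single_comparison_unchanged(self):
        assert bonferroni_adjust([0.3]) == pytest.approx([0.3])

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=10)
        assert (bonferroni_adjust(p) >= p).all()


class TestSpearman:
    def test_monotone_sequences(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 9, 16, 30])[0] == pytest.approx(1.0)
        assert spearman(x, [5, 3, 2, 1, 0])[0] == pytest.approx(-1.0)

    def test_tied_data_match_rank_then_pearson(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [10.0, 12.0, 11.0, 11.0, 15.0]
        rho, _ = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rho_hand = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(rho_hand)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateDataError):
            spearman([1, 1, 1], [2, 3, 4])


class TestLinearModel:
    def test_exact_linear_relation_r2_one(self):
        design = pd.DataFrame({"x1": [1.0, 2, 3, 4, 5, 6], "x2": [0.0, 1, 0, 1, 0, 1]})
        y = 2.0 + 3.0 * design["x1"] - 1.5 * design["x2"]
        fit = fit_linear_model(design, y)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.B == pytest.approx([3.0, -1.5], abs=1e-9)

    def test_coefficients_match_normal_equations_oracle(self, rng):
        design = pd.DataFrame(rng.normal(size=(6, 2)), columns=["a", "b"])
        y = rng.normal(size=6)
        fit = fit_linear_model(design, y)
        X = np.column_stack([np.ones(6), design["a"], design["b"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.B == pytest.approx(beta[1:], abs=1e-8)

    def test_standardised_self_regression_beta_one(self, rng):
        x = rng.normal(size=50)
        design = pd.DataFrame({"x": x})
        fit = fit_linear_model(design, x.copy())
        assert fit.beta_std[0] == pytest.approx(1.0)

    def test_adjusted_r2_identity(self, rng):
        n, p = 40, 3
        design = pd.DataFrame(rng.normal(size=(n, p)), columns=list("abc"))
        y = design["a"] * 0.5 + rng.normal(size=n)
        fit = fit_linear_model(design, y)
        expect = 1 - (1 - fit.r2) * (n - 1) / (n - p - 1)
        assert fit.adj_r2 == pytest.approx(expect, abs=1e-12)

    def test_categorical_uses_stated_reference_level(self):
        rng = np.random.default_rng(0)
        ct = ["ESCC"] * 20 + ["GAC"] * 20 + ["AEGJ"] * 20
        offsets = {"ESCC": 0.0, "GAC": 1.0, "AEGJ": 2.0}
        y = np.array([offsets[c] for c in ct]) + rng.normal(0, 0.3, 60)
        fit = fit_linear_model(
            pd.DataFrame({"cancer_type": ct}), y, categorical={"cancer_type": "ESCC"}
        )
        assert set(fit.terms) == {"cancer_type[GAC]", "cancer_type[AEGJ]"}
        i_gac = fit.terms.index("cancer_type[GAC]")
        i_aegj = fit.terms.index("cancer_type[AEGJ]")
        assert fit.B[i_aegj] > fit.B[i_gac] > 0

    def test_collinear_design_raises_naming_terms(self, rng):
        a = rng.normal(size=20)
        design = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(CollinearityError, match="a"):
            fit_linear_model(design, rng.normal(size=20))

    def test_cancer_type_effect_recovery_on_synthetic_cohort(self):
        """TIL offsets ordered AEGJ > GAC > ESCC must come back as positive,
        ordered standardised effects (ESCC reference)."""
        rng = np.random.default_rng(42)
        n = 400
        ct = rng.choice(["ESCC", "GAC", "AEGJ"], size=n, p=[0.6, 0.2, 0.2])
        offset = {"ESCC": 0.0, "GAC": 1.8, "AEGJ": 4.7}
        age = rng.normal(65, 8, n)
        y = (
            np.array([offset[c] for c in ct])
            + 0.02 * (age - 65)
            + rng.lognormal(0.0, 1.0, n)
        )
        fit = fit_linear_model(
            pd.DataFrame({"cancer_type": ct, "age": age}),
            y,
            categorical={"cancer_type": "ESCC"},
        )
        b = {t: fit.beta_std[i] for i, t in enumerate(fit.terms)}
        assert b["cancer_type[AEGJ]"] > b["cancer_type[GAC]"] > 0
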