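"""Agreement statistics: Bland–Altman, Wilcoxon, Fisher, regression, trends."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from prrtdose import (adjusted_linear_association, bland_altman,
                      fisher_exact_2x2, out_of_bound_fraction,
                      percent_difference, summarize_percent_differences,
                      tiac_trend_test, wilcoxon_signed_rank)


def differences_with_moments(mu, sigma, n, seed=0):
    """n values with exactly the requested sample mean and SD (ddof=1)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mu + sigma * z


class TestBlandAltman:
    def test_degenerate_equal_differences(self):
        res = bland_altman([1.5, 1.5, 1.5])
        assert res.loa_low == res.loa_high == pytest.approx(1.5)
        assert res.ci_low == res.ci_high == pytest.approx(1.5)

    def test_reconstructed_kidney_limits(self):
        # mean -1.3 Gy and SD 2.347 Gy over 30 patients give the published
        # kidney limits of agreement (-5.9, 3.3) Gy
        d = differences_with_moments(-1.3, 2.347, 30)
        res = bland_altman(d)
        assert round(res.loa_low, 1) == -5.9
        assert round(res.loa_high, 1) == 3.3

    def test_ci_inside_loa_and_ordered(self):
        d = differences_with_moments(0.7, 2.0, 25, seed=3)
        res = bland_altman(d)
        assert res.loa_low < res.ci_low < res.mu_delta < res.ci_high < res.loa_high

    def test_gaussian_coverage_law(self):
        rng = np.random.default_rng(11)
        d = rng.standard_normal(100_000)
        res = bland_altman(d)
        inside = np.mean((d >= res.loa_low) & (d <= res.loa_high))
        assert inside == pytest.approx(0.95, abs=0.005)

    def test_too_few_differences_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0])


class TestOutOfBound:
    def test_all_inside_is_zero(self):
        assert out_of_bound_fraction([0.0, 0.1], (-1.0, 1.0)) == 0.0

    def test_published_rounding_two_of_thirty(self):
        d = np.zeros(30)
        d[:2] = 5.0
        assert out_of_bound_fraction(d, (-1.0, 1.0)) == 6.7

    def test_boundary_counts_as_inside(self):
        assert out_of_bound_fraction([-1.0, 1.0, 0.0], (-1.0, 1.0)) == 0.0


class TestWilcoxon:
    def test_antisymmetric_differences_show_no_shift(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        p = wilcoxon_signed_rank(a, np.zeros(6))
        assert p == pytest.approx(1.0, abs=0.05)

    def test_exact_p_matches_sign_enumeration_oracle(self):
        d = np.array([1.2, -0.4, 2.1, 0.9, -1.7, 0.3])
        p = wilcoxon_signed_rank(d, np.zeros(6))
        ranks = stats.rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = 0
        for signs in itertools.product([1, -1], repeat=6):
            w_plus = sum(r for s, r in zip(signs, ranks) if s > 0)
            w = min(w_plus, ranks.sum() - w_plus)
            if w <= w_obs:
                count += 1
        assert p == pytest.approx(count / 2**6, rel=1e-9)

    def test_identical_vectors_warn_and_return_one(self):
        x = np.arange(6.0)
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank(x, x) == 1.0

    def test_normal_approximation_close_to_exact_for_moderate_n(self):
        rng = np.random.default_rng(21)
        for n in (20, 22, 25):
            d = rng.standard_normal(n) + 0.3
            exact = stats.wilcoxon(d, method="exact").pvalue
            approx = stats.wilcoxon(d, method="approx", correction=True).pvalue
            assert abs(exact - approx) < 0.01
            # the module routes these n through the exact branch
            assert wilcoxon_signed_rank(d, np.zeros(n)) == pytest.approx(exact)

    def test_too_few_nonzero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0, 0.0, 0.0, 0.0],
                                 [0.0, 0.0, 0.0, 0.0, 0.0])


class TestPercentDifference:
    def test_identity_and_doubling(self):
        assert percent_difference(15.7, 15.7) == 0.0
        assert percent_difference(2 * 15.7, 15.7) == pytest.approx(100.0)

    def test_published_percent_of_means(self):
        # the percent difference of cohort means (-8.3%) is distinct from
        # the published mean of per-patient percentages (-9.7%)
        assert percent_difference(14.4, 15.7) == pytest.approx(-8.3, abs=0.05)

    def test_cohort_summary_uses_per_patient_ratios(self):
        m0 = np.array([10.0, 20.0])
        mx = np.array([5.0, 30.0])
        mean, sd = summarize_percent_differences(mx, m0)
        assert mean == pytest.approx(0.0)  # (-50% + 50%) / 2
        assert sd == pytest.approx(np.std([-50.0, 50.0], ddof=1))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


class TestFisherExact:
    def test_published_liver_burden_table(self):
        p = fisher_exact_2x2([[4, 10], [0, 16]])
        assert round(p, 2) == 0.04

    def test_diagonal_two_by_two_is_uninformative(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_transposition_invariance(self):
        t = [[3, 7], [5, 2]]
        assert fisher_exact_2x2(t) == pytest.approx(
            fisher_exact_2x2(np.array(t).T.tolist()), rel=1e-12)

    def test_matches_hypergeometric_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 9, size=4)
            table = np.array([[a, b], [c, d]])
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            r1, r2 = table.sum(axis=1)
            c1 = table[:, 0].sum()
            n = table.sum()
            lo, hi = max(0, c1 - r2), min(r1, c1)
            probs = {k: stats.hypergeom.pmf(k, n, r1, c1)
                     for k in range(lo, hi + 1)}
            p_obs = probs[a]
            p_oracle = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
            assert fisher_exact_2x2(table) == pytest.approx(p_oracle, rel=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -2], [3, 4]])


class TestAdjustedAssociation:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        slope, p = adjusted_linear_association(2.0 * x, x)
        assert slope == pytest.approx(2.0, rel=1e-10)
        assert p < 1e-10

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        n = 40
        x = rng.normal(size=n)
        g = rng.integers(0, 2, size=n).astype(float)
        w = rng.normal(75, 10, size=n)
        y = 1.0 - 0.06 * x + 0.3 * g + 0.01 * w + rng.normal(0, 0.5, n)
        slope, _ = adjusted_linear_association(y, x, {"gender": g, "weight": w})
        design = np.column_stack([np.ones(n), x, g, w])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert slope == pytest.approx(beta[1], abs=1e-10)

    def test_orthogonal_covariate_leaves_slope_unchanged(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0] * 4)
        z = np.tile([1.0, -1.0, 0.0, 1.0, -1.0], 4)
        z = z - z.mean()
        z = z - (z @ x) / (x @ x) * x  # orthogonalize against x
        rng = np.random.default_rng(9)
        y = 3.0 * x + rng.normal(0, 0.1, x.size)
        s0, _ = adjusted_linear_association(y, x)
        s1, _ = adjusted_linear_association(y, x, {"z": z})
        assert s1 == pytest.approx(s0, abs=1e-8)

    def test_collinear_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            adjusted_linear_association(x, x, {"x2": 2 * x})


class TestTiacTrend:
    def test_identical_cycles_show_no_trend(self):
        t = np.tile([1.8, 1.8, 1.8, 1.8], (8, 1))
        with pytest.warns(UserWarning):
            res = tiac_trend_test(t, region="kidney")
        assert res.mean_diff_h == 0.0
        assert res.p == 1.0

    def test_upward_drift_gives_negative_cycle1_minus_cycle4(self, small_cohort):
        _, truths, _ = small_cohort
        tiacs = np.array([[t.organ_tiac("kidney", c) for c in (1, 2, 3, 4)]
                          for t in truths])
        res = tiac_trend_test(tiacs, region="kidney")
        assert res.mean_diff_h < 0.0

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            tiac_trend_test([[1.0, 1.1, 1.2, 1.3]])
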