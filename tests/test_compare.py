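"""Method-comparison statistics against independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from reomsim.compare import (
    MethodComparison,
    adjusted_spearman,
    bland_altman,
    friedman_posthoc,
    sample_size_correlation,
    spearman_ci,
    svm_loo_confusion,
    wilcoxon_rank_sum_exact,
)


class TestSpearman:
    def test_monotone_transforms(self):
        x = np.array([0.3, 1.2, 2.0, 3.5, 4.1, 5.0])
        assert spearman_ci(x, np.exp(x), B=0).rho == pytest.approx(1.0)
        assert spearman_ci(x, -x**3, B=0).rho == pytest.approx(-1.0)

    def test_textbook_rank_example(self):
        # d^2 = (0,1,1,1,1): rho = 1 - 6*4/(5*24) = 0.8
        r = spearman_ci([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], B=500, seed=0)
        assert r.rho == pytest.approx(0.8)
        assert r.ci_lower <= r.rho <= r.ci_upper

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_ci([1, 1, 1, 1, 1], [1, 2, 3, 4, 5], B=0)

    def test_bootstrap_ci_brackets_rho_and_fisher_ci_close(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = x + 0.5 * rng.normal(size=40)
        r = spearman_ci(x, y, B=2000, seed=1)
        assert r.ci_lower <= r.rho <= r.ci_upper
        assert r.fisher_ci[0] == pytest.approx(r.ci_lower, abs=0.15)


class TestAdjustedSpearman:
    @staticmethod
    def covariates(n, rng):
        return pd.DataFrame({
            "age": rng.uniform(45, 85, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi": rng.uniform(18, 35, n),
            "pack_years": rng.uniform(10, 60, n),
            "severity": rng.integers(0, 2, n).astype(float),
        })

    def test_independent_covariates_leave_rho_unchanged(self):
        rng = np.random.default_rng(7)
        n = 60
        x = rng.normal(size=n)
        y = x + 0.4 * rng.normal(size=n)
        cov = self.covariates(n, rng)  # unrelated to x, y
        plain = spearman_ci(x, y, B=0).rho
        adj = adjusted_spearman(x, y, cov, B=0).rho
        assert adj == pytest.approx(plain, abs=0.08)

    def test_affine_covariate_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        n = 30
        x, y = rng.normal(size=n), rng.normal(size=n)
        cov = self.covariates(n, rng)
        base = adjusted_spearman(x, y, cov, B=0).rho
        cov2 = cov.copy()
        cov2["age"] = 3.7 * cov2["age"] - 120.0
        assert adjusted_spearman(x, y, cov2, B=0).rho == pytest.approx(base)

    def test_degenerate_outcome_flagged(self):
        rng = np.random.default_rng(9)
        n = 30
        cov = self.covariates(n, rng)
        sev = cov["severity"].to_numpy()
        r = adjusted_spearman(sev, sev, cov, B=0)
        assert r.degenerate

    def test_collinear_design_named(self):
        rng = np.random.default_rng(10)
        n = 25
        cov = self.covariates(n, rng)
        cov["bmi"] = 2.0 * cov["age"] + 1.0
        with pytest.raises(ValueError, match="collinear"):
            adjusted_spearman(rng.normal(size=n), rng.normal(size=n), cov, B=0)

    def test_adjustment_removes_confounded_association(self):
        # x and y correlate only through the severity indicator
        rng = np.random.default_rng(11)
        n = 80
        sev = rng.integers(0, 2, n).astype(float)
        x = sev + 0.3 * rng.normal(size=n)
        y = sev + 0.3 * rng.normal(size=n)
        cov = self.covariates(n, rng)
        cov["severity"] = sev
        assert spearman_ci(x, y, B=0).rho > 0.5
        assert abs(adjusted_spearman(x, y, cov, B=0).rho) < 0.35


class TestBlandAltman:
    def test_identical_measurements(self):
        md, lo, hi = bland_altman([0.3, 0.5, 0.7], [0.3, 0.5, 0.7])
        assert (md, lo, hi) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        md, lo, hi = bland_altman(np.array([0.4, 0.6]) + 0.1, [0.4, 0.6])
        assert md == pytest.approx(0.1)
        assert lo == pytest.approx(0.1) and hi == pytest.approx(0.1)

    def test_hand_computed_limits(self):
        # d = (-0.1, 0, 0.1): sd = 0.1, limits at +-1.96 sd
        md, lo, hi = bland_altman([0.9, 1.0, 1.1], [1.0, 1.0, 1.0])
        assert md == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(-0.196)
        assert hi == pytest.approx(0.196)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2, 3])


class TestWilcoxonRankSum:
    def test_complete_separation_9_vs_8(self):
        a = np.arange(1.0, 10.0)          # 9 values, all smaller
        b = np.arange(20.0, 28.0)         # 8 values
        p = wilcoxon_rank_sum_exact(a, b)
        assert p == pytest.approx(2 / 24310, rel=1e-9)
        assert p < 0.001

    def test_identical_groups_give_p_one(self):
        # ties present: tie-corrected normal path
        assert wilcoxon_rank_sum_exact([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_symmetry_in_group_order(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=7), rng.normal(1.0, 1, size=6)
        assert wilcoxon_rank_sum_exact(a, b) == \
            pytest.approx(wilcoxon_rank_sum_exact(b, a), rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=int(rng.integers(3, 9)))
        b = rng.normal(0.5, 1, size=int(rng.integers(3, 9)))
        ours = wilcoxon_rank_sum_exact(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=8)
        b = rng.normal(0.8, 1, size=7)
        p_exact = wilcoxon_rank_sum_exact(a, b)
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:8].sum()
        mu = 8 * (15 + 1) / 2
        n_mc = 100_000
        perm = rng.permuted(np.tile(ranks, (n_mc, 1)), axis=1)
        w = perm[:, :8].sum(axis=1)
        p_mc = np.mean(np.abs(w - mu) >= abs(w_obs - mu) - 1e-9)
        se = np.sqrt(p_exact * (1 - p_exact) / n_mc)
        assert abs(p_exact - p_mc) <= 3 * se + 1e-12

    def test_group_size_precondition(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum_exact([1.0], [2.0, 3.0])


def svm_1d_oracle(x, y, C=1.0):
    """Brute-force soft-margin objective search over (w, b) for 1-D inputs.

    Minimises 0.5 w^2 + C sum(hinge) — convex — by Nelder-Mead from a grid
    of starts; independent of scikit-learn.
    """
    x = np.asarray(x, dtype=float)
    ysign = np.where(y == np.unique(y)[1], 1.0, -1.0)

    def objective(wb):
        w, b = wb
        margins = ysign * (w * x + b)
        return 0.5 * w * w + C * np.sum(np.maximum(0.0, 1.0 - margins))

    best = None
    for w0 in (-5.0, -1.0, -0.2, 0.2, 1.0, 5.0, 20.0):
        for b0 in (-5.0, 0.0, 5.0):
            res = optimize.minimize(objective, [w0, b0], method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12,
                                             "maxiter": 5000})
            if best is None or res.fun < best.fun:
                best = res
    return best.x, best.fun, objective


class TestSvmLooConfusion:
    def test_separated_classes_classified_perfectly(self):
        values = np.array([0.2, 0.25, 0.3, 0.9, 1.0, 1.1])
        labels = np.array(["mild"] * 3 + ["severe"] * 3)
        cm = svm_loo_confusion(values, labels)
        assert cm.n_misclassified == 0
        assert cm.n == 6

    def test_single_overlapping_point_is_the_only_error(self):
        # one severe value sits inside the mild cluster; class gap is wide
        # relative to 1/C so the margin is cheap and only that point is lost
        values = np.array([2.0, 2.2, 2.4, 2.6, 2.3, 2.35, 8.5, 9.0, 8.0])
        labels = np.array(["g1"] * 5 + ["g4"] * 4)
        cm = svm_loo_confusion(values, labels)
        assert cm.n_misclassified == 1
        assert cm.counts[1, 0] == 1  # the displaced g4 participant

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_margin_objective(self, seed):
        """LOO predictions equal a from-scratch convex-objective search."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        x = np.where(y == "b", 1.0, 0.0) + rng.normal(0, 0.45, size=n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if np.unique(y[mask]).size < 2:
                continue
            (w, b), f_oracle, objective = svm_1d_oracle(x[mask], y[mask])
            clf = SVC(kernel="linear", C=1.0).fit(x[mask, None], y[mask])
            w_sk = float(clf.coef_[0][0])
            b_sk = float(clf.intercept_[0])
            # same objective value and same held-out prediction
            assert objective([w_sk, b_sk]) == pytest.approx(f_oracle, abs=1e-4)
            margin = w * x[i] + b
            if abs(margin) > 1e-6:
                oracle_label = np.unique(y)[1] if margin > 0 else np.unique(y)[0]
                assert clf.predict(x[i:i + 1, None])[0] == oracle_label

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            svm_loo_confusion([1.0, 2.0], ["a", "a"])


class TestFriedman:
    def test_identical_columns(self):
        r = friedman_posthoc(np.tile([[1.0], [2.0], [3.0], [4.0]], (1, 3)))
        assert r.statistic == 0.0
        assert r.p_value == 1.0
        assert not r.posthoc_performed

    def test_hand_computed_statistic(self):
        # 4 rows of (1,2,3): rank sums 4,8,12 -> chi2 = 8
        data = np.tile([1.0, 2.0, 3.0], (4, 1))
        r = friedman_posthoc(data)
        assert r.statistic == pytest.approx(8.0)
        assert r.p_value == pytest.approx(stats.chi2.sf(8.0, 2), rel=1e-9)

    def test_rank_formula_oracle_exhaustive_small(self):
        """Statistic equals the rank-sum formula on random untied blocks."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(3, 6))
            data = rng.normal(size=(n, 3))
            r = friedman_posthoc(data)
            ranks = stats.rankdata(data, axis=1)
            rj = ranks.sum(axis=0)
            expected = 12.0 / (n * 3 * 4) * np.sum((rj - n * 2) ** 2)
            assert r.statistic == pytest.approx(expected, rel=1e-9)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(13)
        data = rng.normal(size=(6, 3))
        a = friedman_posthoc(data)
        b = friedman_posthoc(data[:, [2, 0, 1]])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_posthoc_triggered_with_bonferroni(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=10)
        data = np.column_stack([base, base + 1.0, base + 2.0])
        r = friedman_posthoc(data)
        assert r.p_value < 0.05 and r.posthoc_performed
        assert set(r.posthoc_p) == {"0-1", "0-2", "1-2"}
        assert all(0 < p <= 1 for p in r.posthoc_p.values())

    def test_missing_cells_rejected(self):
        data = np.ones((4, 3))
        data[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman_posthoc(data)


class TestSampleSize:
    def test_planning_value(self):
        # r^2 = 0.45, power 0.8, alpha 0.05 -> 15 by the Fisher-z formula
        assert sample_size_correlation(0.45, power=0.8, alpha=0.05) == 15

    def test_perfect_correlation_floor(self):
        assert sample_size_correlation(0.999999) == 4

    def test_monotone_in_power(self):
        ns = [sample_size_correlation(0.45, power=p) for p in (0.5, 0.8, 0.9, 0.99)]
        assert ns == sorted(ns)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sample_size_correlation(0.0)
        with pytest.raises(ValueError):
            sample_size_correlation(1.0)


class TestMethodComparisonModel:
    @staticmethod
    def session_frame(n1=9, n4=8, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for group, n, level in (("GOLD1", n1, 0.3), ("GOLD4", n4, 0.7)):
            base = level * np.exp(rng.normal(0, 0.15, size=n))
            for i, b in enumerate(base):
                rows.append({
                    "participant_id": f"{group}-{i}", "group": group,
                    "age": rng.uniform(45, 85), "sex": rng.choice(["F", "M"]),
                    "bmi": rng.uniform(18, 32),
                    "pack_years": rng.uniform(10, 60),
                    "R5": b * 1.1, "R19": b * 0.9,
                    "Reo_s": b * 1.05 * np.exp(rng.normal(0, 0.03)),
                    "Reo_f": b * 0.95 * np.exp(rng.normal(0, 0.03)),
                })
        return pd.DataFrame(rows)

    def test_fit_produces_full_report(self):
        df = self.session_frame()
        res = MethodComparison.from_dataframe(df).fit(bootstrap=300, seed=5)
        assert res.n == 17
        assert set(res.agreement) == {"R5~Reo_s", "R19~Reo_f"}
        for key, rep in res.agreement.items():
            assert rep.loa_lower <= rep.mean_difference <= rep.loa_upper
        assert res.unadjusted["R5~Reo_s"].rho > 0.9
        assert set(res.group_table.index) == {"R5", "R19", "Reo_s", "Reo_f"}
        text = res.summary()
        assert "mean diff" in text and "misclassified" in text

    def test_group_table_matches_direct_medians(self):
        df = self.session_frame()
        res = MethodComparison(df).fit(bootstrap=0)
        direct = df.loc[df.group == "GOLD4", "R5"].median()
        assert res.group_table.loc["R5", "median_GOLD4"] == pytest.approx(direct)

    def test_incomplete_rows_counted_and_dropped(self):
        df = self.session_frame()
        df.loc[3, "Reo_s"] = np.nan
        model = MethodComparison(df)
        assert model.n_excluded == 1
        assert model.fit(bootstrap=0).n == 16

    def test_two_group_requirement(self):
        df = self.session_frame()
        with pytest.raises(ValueError, match="two group"):
            MethodComparison(df[df.group == "GOLD1"])
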