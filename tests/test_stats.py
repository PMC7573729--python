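"""Mantel tests, matrix regression, class summaries, weighted least squares."""

from itertools import permutations

import numpy as np
import pytest

from dupdiv import (
    DistanceMatrix,
    class_summary,
    mantel,
    matrix_regression,
    run_divergence_suite,
    weighted_lm,
)
from dupdiv.errors import (
    DegeneratePredictorError,
    IdError,
    InsufficientDataError,
)


def random_dm(n, seed, labels=None):
    rs = np.random.default_rng(seed)
    pts = rs.random((n, 3))
    v = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(labels or [f"g{i}" for i in range(n)], v)


def exhaustive_mantel_p(d1, d2, tail="upper"):
    """Independent enumeration over all label permutations of d2."""
    n = d1.n
    iu = np.triu_indices(n, 1)
    x = d1.values[iu]

    def corr(y):
        return np.corrcoef(x, y)[0, 1]

    r_obs = corr(d2.values[iu])
    hits = total = 0
    for perm in permutations(range(n)):
        p = np.array(perm)
        y = d2.values[np.ix_(p, p)][iu]
        r = corr(y)
        total += 1
        if tail == "upper":
            hits += r >= r_obs - 1e-12
        else:
            hits += abs(r) >= abs(r_obs) - 1e-12
    return hits / total


class TestMantel:
    def test_self_comparison_r_one(self):
        d = random_dm(8, 0)
        res = mantel(d, d, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value <= 0.05

    def test_exact_enumeration_for_small_label_sets(self):
        d1, d2 = random_dm(5, 1), random_dm(5, 2)
        res = mantel(d1, d2, n_perm=999, seed=0)
        assert res.method == "exact"
        assert res.n_permutations == 120
        assert res.p_value == pytest.approx(exhaustive_mantel_p(d1, d2), abs=1e-12)

    def test_exact_p_for_four_labels_both_tails(self):
        d1, d2 = random_dm(4, 3), random_dm(4, 4)
        for tail in ("upper", "two"):
            res = mantel(d1, d2, seed=0, tail=tail)
            assert res.p_value == pytest.approx(
                exhaustive_mantel_p(d1, d2, tail), abs=1e-12
            )

    def test_monte_carlo_close_to_exhaustive(self):
        # 8 labels forces Monte-Carlo; compare against full enumeration of
        # 8! permutations via a large sample
        d1, d2 = random_dm(8, 5), random_dm(8, 6)
        res = mantel(d1, d2, n_perm=4999, seed=3)
        assert res.method == "monte-carlo"
        ref = mantel(d1, d2, n_perm=4999, seed=17)
        assert res.p_value == pytest.approx(ref.p_value, abs=0.05)

    def test_relabeling_invariance(self):
        d1, d2 = random_dm(6, 7), random_dm(6, 8)
        r1 = mantel(d1, d2, seed=0).statistic
        new = [f"x{i}" for i in range(6)]
        r2 = mantel(
            DistanceMatrix(new, d1.values), DistanceMatrix(new, d2.values), seed=0
        ).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_mask_excluded_pairwise(self):
        d1 = random_dm(6, 9)
        v = random_dm(6, 10).values
        mask = np.zeros((6, 6), bool)
        mask[0, 1] = mask[1, 0] = True
        d2 = DistanceMatrix(d1.labels, v, mask)
        res = mantel(d1, d2, seed=0)
        assert res.n_pairs == 14  # 15 off-diagonal pairs minus the masked one

    def test_label_mismatch_is_error(self):
        with pytest.raises(IdError):
            mantel(random_dm(4, 0), random_dm(4, 0, labels=list("wxyz")))

    def test_too_few_pairs_is_error(self):
        d = random_dm(3, 0)
        mask = ~np.eye(3, dtype=bool)
        masked = DistanceMatrix(d.labels, d.values, mask)
        with pytest.raises(InsufficientDataError):
            mantel(d, masked)

    def test_type_one_error_calibrated_quick(self):
        # smaller version of the acceptance-scale calibration
        rej = 0
        n_rep = 100
        for rep in range(n_rep):
            d1 = random_dm(10, 2 * rep + 100)
            d2 = random_dm(10, 2 * rep + 101)
            if mantel(d1, d2, n_perm=199, seed=rep).p_value < 0.05:
                rej += 1
        assert 0.0 <= rej / n_rep <= 0.11


class TestMatrixRegression:
    def test_exact_linear_relationship(self):
        dx = random_dm(6, 11)
        dy = DistanceMatrix(dx.labels, 2.0 * dx.values)
        res = matrix_regression(dy, dx, seed=0)
        assert res.slope == pytest.approx(2.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_normal_equations_oracle(self):
        dx, dy = random_dm(7, 12), random_dm(7, 13)
        iu = np.triu_indices(7, 1)
        x, y = dx.values[iu], dy.values[iu]
        X = np.column_stack([np.ones_like(x), x])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        res = matrix_regression(dy, dx, seed=0)
        assert res.intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.slope == pytest.approx(coef[1], abs=1e-10)
        pred = X @ coef
        r2 = 1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_joint_relabeling_leaves_coefficients_unchanged(self):
        dx, dy = random_dm(6, 14), random_dm(6, 15)
        perm = np.random.default_rng(1).permutation(6)
        labels = [dx.labels[i] for i in perm]
        dx2 = DistanceMatrix(labels, dx.values[np.ix_(perm, perm)])
        dy2 = DistanceMatrix(labels, dy.values[np.ix_(perm, perm)])
        r1 = matrix_regression(dy, dx, seed=0)
        r2 = matrix_regression(dy2, dx2, seed=0)
        assert r1.slope == pytest.approx(r2.slope, abs=1e-12)
        assert r1.r_squared == pytest.approx(r2.r_squared, abs=1e-12)

    def test_constant_predictor_is_error(self):
        n = 4
        v = np.ones((n, n)) - np.eye(n)
        dx = DistanceMatrix([f"g{i}" for i in range(n)], v)
        with pytest.raises(DegeneratePredictorError):
            matrix_regression(random_dm(n, 16), dx, seed=0)


class TestClassSummary:
    def _dm(self, condensed, labels):
        return DistanceMatrix.from_condensed(labels, condensed)

    def test_mean_sd_n(self):
        dm = self._dm([0.1, 0.3, 0.2], list("abc"))
        summaries, warnings = class_summary({"c1": {"genetic": dm}})
        s = summaries[0]
        assert s.mean == pytest.approx(0.2)
        assert s.sd == pytest.approx(0.1, abs=1e-12)
        assert s.n == 3 and not warnings

    def test_single_pair_sd_missing(self):
        dm = self._dm([0.5], list("ab"))
        summaries, _ = class_summary({"c1": {"genetic": dm}})
        assert summaries[0].sd is None and summaries[0].n == 1

    def test_masked_pairs_excluded_from_n(self):
        dm = DistanceMatrix.from_condensed(
            list("abc"), [0.1, 0.3, 0.2], mask=[False, True, False]
        )
        summaries, _ = class_summary({"c1": {"omega": dm}})
        assert summaries[0].n == 2
        assert summaries[0].mean == pytest.approx(0.15)

    def test_empty_class_warned(self):
        dm = DistanceMatrix.from_condensed(list("ab"), [0.4], mask=[True])
        summaries, warnings = class_summary({"c1": {"omega": dm}})
        assert not summaries and warnings


class TestWeightedLm:
    def test_perfect_line_any_weights(self):
        res = weighted_lm([1, 2, 3], [1, 2, 3], [1, 5, 2])
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_equal_weights_reduce_to_ols(self):
        rs = np.random.default_rng(2)
        x, y = rs.random(6), rs.random(6)
        w_res = weighted_lm(x, y, np.full(6, 3.0))
        beta, alpha = np.polyfit(x, y, 1)
        assert w_res.slope == pytest.approx(beta, abs=1e-12)
        assert w_res.intercept == pytest.approx(alpha, abs=1e-12)

    def test_weighted_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.1, 1.9, 3.2])
        w = np.array([1.0, 1.0, 4.0])
        X = np.column_stack([np.ones(3), x])
        coef = np.linalg.solve(X.T @ np.diag(w) @ X, X.T @ (w * y))
        res = weighted_lm(x, y, w)
        assert res.intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.slope == pytest.approx(coef[1], abs=1e-10)

    def test_p_value_from_t_distribution(self):
        rs = np.random.default_rng(3)
        x = np.arange(8.0)
        y = 0.5 * x + rs.normal(0, 0.3, 8)
        w = np.full(8, 2.0)
        res = weighted_lm(x, y, w)
        # closed-form OLS t test (equal weights)
        import scipy.stats as st

        beta, alpha = np.polyfit(x, y, 1)
        resid = y - (alpha + beta * x)
        se = np.sqrt(resid @ resid / 6 / ((x - x.mean()) ** 2).sum())
        t = beta / se
        p = 2 * st.t.sf(abs(t), df=6)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_two_points_r2_one_no_p(self):
        res = weighted_lm([0, 1], [3, 5], [1, 1])
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.p_value is None

    def test_degenerate_x_is_error(self):
        with pytest.raises(DegeneratePredictorError):
            weighted_lm([2, 2, 2], [1, 2, 3], [1, 1, 1])


class TestDivergenceSuite:
    def test_single_class_structure(self):
        d = random_dm(6, 20)
        report = run_divergence_suite(
            {"only": {"genetic": d, "expression": d, "omega": d}},
            n_perm=99,
            seed=0,
        )
        entry = report.within["only"]
        assert entry["mantel_expression_genetic"].statistic == pytest.approx(1.0)
        assert all(isinstance(v, str) for v in report.between.values())

    def test_three_classes_between_regressions_present(self):
        classes = {}
        for k in range(3):
            g = random_dm(5, 30 + k)
            e = random_dm(5, 40 + k)
            o = random_dm(5, 50 + k)
            classes[f"c{k}"] = {"genetic": g, "expression": e, "omega": o}
        report = run_divergence_suite(classes, n_perm=99, seed=0)
        assert len(report.summaries) == 9
        for res in report.between.values():
            assert hasattr(res, "slope")

    def test_reproducible_given_seed(self):
        classes = {
            f"c{k}": {
                "genetic": random_dm(8, 60 + k),
                "expression": random_dm(8, 70 + k),
            }
            for k in range(2)
        }
        r1 = run_divergence_suite(classes, n_perm=199, seed=5)
        r2 = run_divergence_suite(classes, n_perm=199, seed=5)
        for name in classes:
            a = r1.within[name]["mantel_expression_genetic"]
            b = r2.within[name]["mantel_expression_genetic"]
            assert a.p_value == b.p_value
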