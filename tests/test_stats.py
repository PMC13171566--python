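"""Normality screening, CI, Friedman and Conover tests.

The Conover oracle below is an independent scalar-loop transcription of
the published Friedman post-hoc formulas (rank sums R_j, rank-squared
total A1, C1 = nk(k+1)^2/4, t on (n-1)(k-1) df), kept free of the
vectorized library code path.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ctveval import (
    ComparisonReport,
    MetricTable,
    ci95,
    compare,
    conover_posthoc,
    friedman_test,
    normality_check,
    significance_marks,
)


def oracle_conover_pmatrix(x: np.ndarray) -> np.ndarray:
    """Scalar-loop Conover Friedman post-hoc p-values."""
    n, k = x.shape
    ranks = np.empty((n, k))
    for i in range(n):
        for j in range(k):
            less = sum(1 for v in x[i] if v < x[i][j])
            eq = sum(1 for v in x[i] if v == x[i][j])
            ranks[i][j] = less + (eq + 1) / 2.0
    rank_sums = [sum(ranks[i][j] for i in range(n)) for j in range(k)]
    a1 = sum(ranks[i][j] ** 2 for i in range(n) for j in range(k))
    c1 = n * k * (k + 1) ** 2 / 4.0
    t1 = (k - 1) * sum((r - n * (k + 1) / 2.0) ** 2 for r in rank_sums) / (a1 - c1)
    df = (n - 1) * (k - 1)
    denom = math.sqrt(2.0 * n * (a1 - c1) / df * (1.0 - t1 / (n * (k - 1))))
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                t = abs(rank_sums[i] - rank_sums[j]) / denom
                pmat[i][j] = min(1.0, 2.0 * sps.t.sf(t, df))
    return pmat


def table(values, metric="dice"):
    values = np.asarray(values, dtype=float)
    names = [f"m{j}" for j in range(values.shape[1])]
    return MetricTable(values, names, metric)


class TestNormalityCheck:
    def test_gaussian_samples_usually_pass(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            normality_check(rng.standard_normal(200)).p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 < rejections / 400 < 0.09  # ~5% nominal

    def test_exponential_samples_usually_fail(self):
        rng = np.random.default_rng(12)
        rejections = sum(
            normality_check(rng.exponential(size=200)).p_value < 0.05
            for _ in range(100)
        )
        assert rejections >= 95

    def test_constant_vector_flagged_degenerate(self):
        res = normality_check([2.0] * 10)
        assert res.degenerate
        assert math.isnan(res.p_value)

    def test_qq_points_are_sorted_sample(self):
        rng = np.random.default_rng(13)
        vals = rng.standard_normal(50)
        res = normality_check(vals)
        np.testing.assert_allclose(res.qq_sample, np.sort(vals))
        assert res.qq_theoretical.shape == res.qq_sample.shape


class TestCI95:
    def test_constant_vector_collapses(self):
        assert ci95([3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_two_point_closed_form(self):
        lo, hi = ci95([0.0, 2.0])
        sd = math.sqrt(2.0)
        assert lo == pytest.approx(1 - 1.96 * sd)
        assert hi == pytest.approx(1 + 1.96 * sd)

    def test_large_standard_normal_sample(self):
        rng = np.random.default_rng(14)
        lo, hi = ci95(rng.standard_normal(200_000))
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)


class TestFriedman:
    def test_closed_form_consistent_rankings(self):
        # n=3 patients all ranking the models identically
        t = table([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        q, p = friedman_test(t)
        assert q == pytest.approx(6.0)
        assert p == pytest.approx(math.exp(-3.0), rel=1e-12)

    def test_identical_columns_give_null(self):
        t = table([[1, 1, 1], [2, 2, 2], [5, 5, 5]])
        q, p = friedman_test(t)
        assert q == 0.0 and p == 1.0

    def test_matches_scipy_on_tie_free_tables(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            vals = rng.standard_normal((12, 5))
            q, p = friedman_test(table(vals))
            q_ref, p_ref = sps.friedmanchisquare(*vals.T)
            assert q == pytest.approx(q_ref, rel=1e-12)
            assert p == pytest.approx(p_ref, rel=1e-12)

    def test_invariant_under_row_monotone_transforms(self):
        rng = np.random.default_rng(16)
        vals = rng.random((10, 4))
        transforms = [np.exp, lambda v: v**3 + v, lambda v: 10 * v - 3]
        warped = np.stack(
            [transforms[i % 3](vals[i]) for i in range(vals.shape[0])]
        )
        assert friedman_test(table(vals)) == friedman_test(table(warped))

    def test_needs_three_models(self):
        with pytest.raises(ValueError):
            friedman_test(table([[1, 2], [2, 1]]))


class TestConover:
    def test_identical_columns_no_significant_pairs(self):
        t = table([[1, 1, 1], [2, 2, 2], [3, 3, 3]])
        pmat = conover_posthoc(t)
        assert (pmat.to_numpy() == 1.0).all()

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(17)
        vals = rng.standard_normal((10, 4))
        got = conover_posthoc(table(vals)).to_numpy()
        want = oracle_conover_pmatrix(vals)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(18)
        pmat = conover_posthoc(table(rng.random((8, 5)))).to_numpy()
        np.testing.assert_allclose(pmat, pmat.T)
        np.testing.assert_allclose(np.diag(pmat), 1.0)
        assert ((pmat >= 0) & (pmat <= 1)).all()

    def test_column_permutation_permutes_matrix(self):
        rng = np.random.default_rng(19)
        vals = rng.random((9, 4))
        perm = [2, 0, 3, 1]
        a = conover_posthoc(table(vals)).to_numpy()
        b = conover_posthoc(table(vals[:, perm])).to_numpy()
        np.testing.assert_allclose(b, a[np.ix_(perm, perm)])

    def test_dominant_column_has_smallest_pvalues(self):
        rng = np.random.default_rng(20)
        vals = rng.random((15, 4))
        vals[:, 2] += 5.0  # stochastically dominates all others
        pmat = conover_posthoc(table(vals)).to_numpy()
        off = pmat[~np.eye(4, dtype=bool)]
        dominated = [pmat[2, j] for j in range(4) if j != 2]
        assert max(dominated) <= min(
            pmat[i, j]
            for i, j in itertools.combinations(range(4), 2)
            if 2 not in (i, j)
        )
        assert min(off) == min(dominated)


class TestSignificanceMarks:
    def _report(self, friedman_p, pairs):
        import pandas as pd

        names = ["a", "b", "c"]
        pmat = pd.DataFrame(np.ones((3, 3)), index=names, columns=names)
        for (x, y), p in pairs.items():
            pmat.loc[x, y] = pmat.loc[y, x] = p
        return ComparisonReport(10.0, friedman_p, pmat)

    def test_all_unit_pvalues_empty(self):
        assert significance_marks(self._report(0.001, {})) == set()

    def test_single_significant_pair(self):
        rep = self._report(0.001, {("a", "b"): 0.01, ("a", "c"): 0.5})
        assert significance_marks(rep) == {("a", "b")}

    def test_gated_on_omnibus(self):
        rep = self._report(0.2, {("a", "b"): 0.001})
        assert significance_marks(rep) == set()


class TestCompare:
    def test_holm_adjustment_never_decreases_pvalues(self):
        rng = np.random.default_rng(22)
        t = table(rng.random((10, 4)))
        raw = compare(t, adjust="none").conover_p.to_numpy()
        adj = compare(t, adjust="holm").conover_p.to_numpy()
        assert (adj + 1e-15 >= raw).all()

    def test_missing_rows_dropped_in_from_long(self):
        import pandas as pd

        rows = []
        for pid in range(4):
            for m in ("a", "b", "c"):
                rows.append({"patient_id": f"P{pid}", "model": m, "dice": pid + 0.1})
        df = pd.DataFrame(rows)
        df.loc[(df.patient_id == "P2") & (df.model == "b"), "dice"] = np.nan
        t = MetricTable.from_long(df, "dice")
        assert t.n_patients == 3
        assert "P2" not in t.patient_ids
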