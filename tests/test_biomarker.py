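import math

import numpy as np
import pytest
from scipy import stats

from salivapred.biomarker import (
    EnrichmentQuery,
    ExpressionMatrix,
    fold_change,
    hypergeom_pmf,
    hypergeom_tail,
    intersect_candidates,
    paired_ttest,
    select_deg,
)


def paired_t_oracle(case_row, ctrl_row):
    """Textbook paired t: mean difference over its standard error, df = m-1."""
    d = np.asarray(case_row) - np.asarray(ctrl_row)
    m = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(m))
    return 2 * stats.t.sf(abs(t), df=m - 1)


def make_expr(case, control):
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    return ExpressionMatrix([f"g{i}" for i in range(case.shape[0])], case, control)


class TestFoldChange:
    def test_constant_matrices(self):
        expr = make_expr([[3.0] * 4], [[2.0] * 4])
        assert fold_change(expr)[0] == pytest.approx(1.5)

    def test_identity(self):
        expr = make_expr([[2.0, 5.0]], [[2.0, 5.0]])
        assert fold_change(expr)[0] == pytest.approx(1.0)

    def test_hand_evaluation(self):
        expr = make_expr([[2.0, 4.0]], [[1.0, 1.0]])
        assert fold_change(expr)[0] == pytest.approx(3.0)

    def test_swap_inverts_under_ratio_of_sums(self, rng):
        case = rng.lognormal(size=(10, 6))
        control = rng.lognormal(size=(10, 6))
        fwd = fold_change(make_expr(case, control))
        back = fold_change(make_expr(control, case))
        assert fwd == pytest.approx(1.0 / back)

    def test_mean_of_ratios_variant(self):
        expr = make_expr([[2.0, 4.0]], [[1.0, 1.0]])
        assert fold_change(expr, method="mean_of_ratios")[0] == pytest.approx(3.0)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            make_expr([[1.0, -1.0]], [[1.0, 1.0]])


class TestPairedTtest:
    def test_matches_textbook_oracle(self, rng):
        case = rng.lognormal(mean=2, size=(50, 8))
        control = rng.lognormal(mean=2, size=(50, 8))
        p = paired_ttest(make_expr(case, control))
        expected = [paired_t_oracle(c, n) for c, n in zip(case, control)]
        assert p == pytest.approx(expected, abs=1e-10)

    def test_null_pvalues_approximately_uniform(self, rng):
        # symmetric (normal) noise, no effect: p-values are exactly uniform
        case = rng.normal(100.0, 5.0, size=(1000, 10))
        control = rng.normal(100.0, 5.0, size=(1000, 10))
        p = paired_ttest(make_expr(case, control))
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_degenerate_rows(self):
        expr = make_expr(
            [[2.0, 2.0, 2.0], [3.0, 3.0, 3.0]],
            [[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]],
        )
        p = paired_ttest(expr)
        assert p[0] == 1.0  # all differences zero
        assert 0 < p[1] <= np.finfo(float).tiny  # constant nonzero shift

    def test_single_pair_errors(self):
        with pytest.raises(ValueError):
            paired_ttest(make_expr([[1.0]], [[2.0]]))


class TestSelectDeg:
    def test_threshold_boundary_inclusive(self):
        kept = select_deg(np.array([1.5]), np.array([0.01]), ["g"])
        assert kept == ["g"]

    def test_mild_downregulation_dropped(self):
        kept = select_deg(np.array([0.8]), np.array([0.001]), ["g"])
        assert kept == []

    def test_toy_table(self):
        fc = np.array([2.0, 1.2, 0.5, 1.5, 0.7])
        p = np.array([0.01, 0.01, 0.01, 0.2, 0.01])
        ids = [f"gene{i+1}" for i in range(5)]
        assert select_deg(fc, p, ids) == ["gene1", "gene3"]


class TestHypergeometric:
    @pytest.mark.parametrize(
        "n,s,expected",
        [(500, 1, 0.367), (1000, 3, 0.211), (1500, 6, 0.076),
         (5500, 19, 0.017), (6000, 20, 0.020)],
    )
    def test_point_mass_reproduces_survey_table(self, n, s, expected):
        p = hypergeom_pmf(EnrichmentQuery(N=20209, S=47, n=n, s=s))
        assert p == pytest.approx(expected, abs=1.5e-3)

    @pytest.mark.parametrize(
        "n,s,expected",
        [(2000, 8, 0.088), (2500, 11, 0.026), (3000, 12, 0.038),
         (4000, 13, 0.123), (5000, 16, 0.098)],
    )
    def test_upper_tail_reproduces_survey_table(self, n, s, expected):
        p = hypergeom_tail(EnrichmentQuery(N=20209, S=47, n=n, s=s))
        assert p == pytest.approx(expected, abs=1.5e-3)

    def test_breast_cancer_overlap_tail(self):
        p = hypergeom_tail(EnrichmentQuery(N=20209, S=37, n=31, s=4))
        assert p == pytest.approx(2.89e-7, rel=5e-3)

    def test_forced_draw(self):
        assert hypergeom_pmf(EnrichmentQuery(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_pmf_normalizes(self):
        N, S, n = 50, 10, 20
        total = sum(
            hypergeom_pmf(EnrichmentQuery(N, S, n, s))
            for s in range(max(0, n - (N - S)), min(S, n) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_role_symmetry_of_S_and_n(self, rng):
        for _ in range(30):
            N = int(rng.integers(10, 2000))
            S = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo = max(0, n - (N - S))
            s = int(rng.integers(lo, min(S, n) + 1))
            a = hypergeom_pmf(EnrichmentQuery(N, S, n, s))
            b = hypergeom_pmf(EnrichmentQuery(N, n, S, s))
            assert a == pytest.approx(b, rel=1e-12)

    def test_matches_exact_bigint_oracle(self, rng):
        from math import comb

        for _ in range(40):
            N = int(rng.integers(5, 2000))
            S = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo = max(0, n - (N - S))
            s = int(rng.integers(lo, min(S, n) + 1))
            mine = hypergeom_pmf(EnrichmentQuery(N, S, n, s))
            from fractions import Fraction

            exact = Fraction(comb(S, s) * comb(N - S, n - s), comb(N, n))
            assert mine == pytest.approx(float(exact), rel=1e-10, abs=1e-300)

    def test_matches_scipy_oracle_large_N(self, rng):
        for _ in range(50):
            N = int(rng.integers(1000, 1000000))
            S = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo = max(0, n - (N - S))
            s = int(rng.integers(lo, min(S, n) + 1))
            mine = hypergeom_pmf(EnrichmentQuery(N, S, n, s))
            ref = stats.hypergeom.pmf(s, N, S, n)
            assert mine == pytest.approx(ref, rel=1e-8, abs=1e-300)

    def test_tail_equals_pmf_sum(self, rng):
        for _ in range(20):
            N = int(rng.integers(5, 500))
            S = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo = max(0, n - (N - S))
            s = int(rng.integers(lo, min(S, n) + 1))
            tail = hypergeom_tail(EnrichmentQuery(N, S, n, s))
            brute = sum(
                stats.hypergeom.pmf(k, N, S, n) for k in range(s, min(S, n) + 1)
            )
            assert tail == pytest.approx(brute, abs=1e-12)

    def test_invalid_query_errors(self):
        with pytest.raises(ValueError):
            EnrichmentQuery(10, 3, 4, 5)  # s > min(S, n)
        with pytest.raises(ValueError):
            EnrichmentQuery(10, 11, 4, 2)  # S > N


class TestIntersectCandidates:
    def test_disjoint_and_nested(self):
        assert intersect_candidates(["a"], ["b"], ["c"]) == []
        assert intersect_candidates(["a", "b", "c"], ["a", "b", "c"], ["b"]) == ["b"]

    def test_toy_sets(self):
        assert intersect_candidates(["a", "b", "c"], ["b", "c", "d"], ["c"]) == ["c"]

    def test_ordering_by_rank_then_id(self):
        out = intersect_candidates(
            ["x", "y", "z"], ["x", "y", "z"], ["x", "y", "z"],
            ranking={"x": 30, "y": 10},
        )
        assert out == ["y", "x", "z"]


class TestDegRecovery:
    def test_planted_fold_changes_recovered(self):
        from salivapred.synth import SynthSpec, generate_expression

        expr, truth = generate_expression(SynthSpec(seed=11))
        fc = fold_change(expr)
        pv = paired_ttest(expr)
        called = set(select_deg(fc, pv, expr.gene_ids))
        true_set = set(truth.loc[truth["is_de"] == 1, "gene"])
        tp = len(called & true_set)
        prec = tp / len(called)
        rec = tp / len(true_set)
        f1 = 2 * prec * rec / (prec + rec)
        assert f1 >= 0.9
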