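"""Gene-centric and term-centric metric implementations vs independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from covote.evaluation import (
    DEFAULT_GRID,
    average_pr_curve,
    avg_auroc,
    evaluate_gene_centric,
    gene_pr_curve,
    roc_auc,
    ru_mi_curve,
)
from covote.expression import ValidationError
from oracles import (
    oracle_auroc,
    oracle_average_pr,
    oracle_gene_pr,
    oracle_ru_mi,
    random_instance,
)


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------

class TestGenePR:
    def test_counting_example(self):
        # P = {a, b}, T = {a, c} -> pr = 1/2, rc = 1/2
        scores = np.array([0.9, 0.8, 0.1])  # terms a, b, c
        truth = np.array([True, False, True])
        df, _ = gene_pr_curve(scores, truth)
        row = df[df.threshold == 0.5].iloc[0]
        assert row.precision == pytest.approx(0.5)
        assert row.recall == pytest.approx(0.5)

    def test_perfect_scores(self):
        scores = np.array([1.0, 1.0, 0.0])
        truth = np.array([True, True, False])
        df, auprc = gene_pr_curve(scores, truth)
        assert np.allclose(df.precision.dropna(), 1.0)
        assert np.allclose(df.recall, 1.0)

    def test_empty_truth_errors(self):
        with pytest.raises(ValidationError):
            gene_pr_curve(np.array([0.5]), np.array([False]))


class TestAveragePR:
    def test_harmonic_mean_value(self):
        # pr = 0.6 and rc = 0.7 give F = 0.6462
        f = 2 * 0.6 * 0.7 / (0.6 + 0.7)
        assert f == pytest.approx(0.6462, abs=5e-5)

    def test_m_t_denominator(self):
        # gene 0 predicted perfectly; gene 1 has no predictions at t=0.5
        scores = np.array([[1.0, 0.0], [0.2, 0.2]])
        truth = np.array([[True, False], [True, True]])
        curve, *_ = average_pr_curve(scores, truth)
        row = curve[curve.threshold == 0.5].iloc[0]
        assert row.m == 1
        assert row.precision == pytest.approx(1.0)  # from gene 0 only
        assert row.recall == pytest.approx(0.5)  # (1 + 0) / 2

    def test_fmax_tie_breaks_to_smaller_threshold(self):
        # constant scores -> identical F at every covered threshold
        scores = np.array([[0.6, 0.6]])
        truth = np.array([[True, False]])
        curve, _, fmax, fmax_t = average_pr_curve(scores, truth)
        assert fmax_t == pytest.approx(0.01)


class TestRuMi:
    def test_perfect_prediction_zero_error(self):
        scores = np.array([[1.0, 1.0, 0.0]])
        truth = np.array([[True, True, False]])
        ru, mi, smin, _ = ru_mi_curve(scores, truth, np.array([1.0, 2.0, 3.0]))
        assert smin == pytest.approx(0.0)

    def test_empty_prediction_components(self):
        # P = empty set: ru component 1, mi component 0
        scores = np.array([[0.0, 0.0]])
        truth = np.array([[True, True]])
        ru, mi, smin, _ = ru_mi_curve(scores, truth, np.array([1.0, 2.0]))
        assert ru[-1] == pytest.approx(1.0)
        assert mi[-1] == pytest.approx(0.0)

    def test_three_term_worked_case(self):
        # T = {a, b}, P = {b, c}; IC = (3, 1, 2) -> ru = 3/6, mi = 2/6
        scores = np.array([[0.1, 0.9, 0.9]])
        truth = np.array([[True, True, False]])
        ic = np.array([3.0, 1.0, 2.0])
        ru, mi, *_ = ru_mi_curve(scores, truth, ic, grid=np.array([0.5]))
        assert ru[0] == pytest.approx(0.5)
        assert mi[0] == pytest.approx(2 / 6)


class TestAUROC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_brute_force(self, rng):
        for _ in range(20):
            scores = np.round(rng.random(30), 2)  # rounding forces ties
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                oracle_auroc(scores, labels), abs=1e-12
            )

    @given(st.integers(0, 10 ** 6))
    def test_monotone_transform_invariance(self, seed):
        r = np.random.default_rng(seed)
        scores = r.random(20)
        labels = np.arange(20) < 7
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores) - 0.5, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_avg_auroc(self):
        assert avg_auroc([1.0, 0.5]) == pytest.approx(0.75)
        assert avg_auroc([0.9]) == pytest.approx(0.9)
        assert avg_auroc([0.3, 0.6, 0.9]) == avg_auroc([0.9, 0.3, 0.6])


# ---------------------------------------------------------------------------
# Oracle equivalence on random instances
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    def test_gene_auprc_matches_oracle(self, rng):
        for _ in range(20):
            scores, truth = random_instance(rng, n_genes=1)
            _, auprc = gene_pr_curve(scores[0], truth[0])
            assert auprc == pytest.approx(
                oracle_gene_pr(scores[0], truth[0], DEFAULT_GRID), abs=1e-12
            )

    def test_average_pr_matches_oracle(self, rng):
        for _ in range(20):
            scores, truth = random_instance(rng)
            curve, auprc, fmax, _ = average_pr_curve(scores, truth)
            o_curve, o_area, o_fmax = oracle_average_pr(scores, truth, DEFAULT_GRID)
            assert auprc == pytest.approx(o_area, abs=1e-12)
            assert fmax == pytest.approx(o_fmax, abs=1e-12)
            for (t, o_pr, o_rc, o_m), (_, row) in zip(o_curve, curve.iterrows()):
                assert row.m == o_m
                assert row.recall == pytest.approx(o_rc, abs=1e-12)
                if o_m:
                    assert row.precision == pytest.approx(o_pr, abs=1e-12)

    def test_ru_mi_matches_oracle(self, rng):
        for _ in range(20):
            scores, truth = random_instance(rng)
            ic = rng.uniform(0.1, 5, size=scores.shape[1])
            ru, mi, smin, _ = ru_mi_curve(scores, truth, ic)
            o_curve, o_smin = oracle_ru_mi(scores, truth, ic, DEFAULT_GRID)
            assert np.allclose(ru, [r for r, _ in o_curve], atol=1e-12)
            assert np.allclose(mi, [m for _, m in o_curve], atol=1e-12)
            assert smin == pytest.approx(o_smin, abs=1e-12)


# ---------------------------------------------------------------------------
# Metric invariants
# ---------------------------------------------------------------------------

class TestInvariants:
    @given(st.integers(0, 10 ** 6))
    def test_curve_monotonicity_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        scores, truth = random_instance(rng)
        ic = rng.uniform(0.1, 4, size=scores.shape[1])
        res = evaluate_gene_centric(scores, truth, ic=ic)
        c = res.curve
        assert (np.diff(c.recall) <= 1e-12).all()  # rc non-increasing in t
        assert (np.diff(c.m) <= 0).all()  # m non-increasing in t
        assert (np.diff(c.ru) >= -1e-12).all()  # ru non-decreasing
        assert (np.diff(c.mi) <= 1e-12).all()  # mi non-increasing
        assert ((c.ru + c.mi) <= 1 + 1e-12).all()
        assert 0 <= res.smin <= 1
        assert 0 <= res.fmax <= 1
        f = c.F.dropna()
        assert (f <= res.fmax + 1e-12).all()

    def test_constant_ic_reduces_to_set_error(self, rng):
        """With IC constant, 1 - (ru + mi) at a threshold equals the mean
        Jaccard index between predicted and true sets."""
        scores, truth = random_instance(rng, n_genes=6, n_terms=5)
        ic = np.full(5, 2.7)
        ru, mi, *_ = ru_mi_curve(scores, truth, ic, grid=np.array([0.5]))
        jaccards = []
        for i in range(6):
            p = {j for j in range(5) if scores[i, j] >= 0.5}
            t = {j for j in range(5) if truth[i, j]}
            jaccards.append(len(p & t) / len(p | t))
        assert 1 - (ru[0] + mi[0]) == pytest.approx(np.mean(jaccards), abs=1e-12)
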