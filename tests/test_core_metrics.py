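"""Agreement statistics on the 3x3 true-vs-imputed table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imputeqc import (
    ConfusionTable,
    GenotypeVector,
    PosteriorMatrix,
    accuracy,
    build_confusion,
    chance_agreement,
    cross_platform_confusion,
    efficiency,
    estimated_maf,
    iqs,
    observed_agreement,
)
from imputeqc.core import MISSING, confusion_batch, iqs_from_tables

from conftest import brute_force_kappa, hwe_onehot

EXAMPLE = ConfusionTable(np.array([[45.0, 5, 0], [5, 25, 0], [0, 0, 20]]))


class TestBuildConfusion:
    def test_certain_posteriors_give_diagonal_counts(self):
        truth = GenotypeVector("s", [0, 0, 1])
        post = PosteriorMatrix("s", hwe_onehot([0, 0, 1]))
        table = build_confusion(truth, post)
        np.testing.assert_allclose(table.n, np.diag([2.0, 1.0, 0.0]))
        assert table.total == 3

    def test_probability_mass_lands_in_true_genotype_row(self):
        truth = GenotypeVector("s", [0, 1])
        post = PosteriorMatrix("s", [[0.8, 0.2, 0.0], [0.1, 0.6, 0.3]])
        table = build_confusion(truth, post)
        expected = np.array([[0.8, 0.2, 0.0], [0.1, 0.6, 0.3], [0.0, 0.0, 0.0]])
        np.testing.assert_allclose(table.n, expected)
        assert table.total == pytest.approx(2.0)

    def test_missing_truth_is_excluded(self):
        truth = GenotypeVector("s", [0, MISSING])
        post = PosteriorMatrix("s", [[1.0, 0, 0], [0.5, 0.5, 0]])
        table = build_confusion(truth, post)
        assert table.total == pytest.approx(1.0)
        assert table.n[0, 0] == pytest.approx(1.0)
        assert table.n.sum() - table.n[0, 0] == pytest.approx(0.0)

    def test_length_mismatch_and_all_missing_raise(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_confusion(GenotypeVector("s", [0]), PosteriorMatrix("s", hwe_onehot([0, 1])))
        with pytest.raises(ValueError, match="missing"):
            build_confusion(GenotypeVector("s", [MISSING, MISSING]),
                            PosteriorMatrix("s", hwe_onehot([0, 1])))


class TestAgreementScores:
    @pytest.mark.parametrize(
        "table, po, pc",
        [
            (np.diag([50.0, 30, 20]), 1.0, 0.38),
            (EXAMPLE.n, 0.90, 0.38),
            (np.full((3, 3), 10.0), 1 / 3, 1 / 3),
        ],
    )
    def test_observed_and_chance_agreement(self, table, po, pc):
        assert observed_agreement(table) == pytest.approx(po)
        assert chance_agreement(table) == pytest.approx(pc)

    def test_iqs_worked_example(self):
        assert iqs(EXAMPLE) == pytest.approx((0.90 - 0.38) / 0.62, abs=1e-12)
        assert iqs(EXAMPLE) == pytest.approx(brute_force_kappa(EXAMPLE.n.tolist()), abs=1e-12)

    def test_perfect_diagonal_scores_one(self):
        assert iqs(np.diag([7.0, 2.5, 1.0])) == pytest.approx(1.0)

    def test_independence_table_scores_zero(self, rng):
        pi = rng.dirichlet([2.0, 2.0, 2.0])
        table = 500.0 * np.outer(pi, pi)
        assert iqs(table) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_table_is_undefined(self):
        table = np.zeros((3, 3))
        table[0, 0] = 100.0
        assert chance_agreement(table) == pytest.approx(1.0)
        assert np.isnan(iqs(table))

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            observed_agreement(np.zeros((3, 3)))


class TestCrossPlatform:
    def test_identical_certain_calls_give_iqs_one(self):
        probs = hwe_onehot([0, 1, 2, 1])
        table = cross_platform_confusion(probs, probs)
        np.testing.assert_allclose(table.n, np.diag([1.0, 2.0, 1.0]))
        assert iqs(table) == pytest.approx(1.0)

    def test_uniform_second_platform_gives_iqs_zero(self, rng):
        a = rng.dirichlet([1, 1, 1], size=20)
        b = np.full((20, 3), 1 / 3)
        table = cross_platform_confusion(a, b)
        assert observed_agreement(table) == pytest.approx(1 / 3)
        assert iqs(table) == pytest.approx(0.0, abs=1e-12)

    def test_outer_product_tabulation(self):
        a = np.array([[0.9, 0.1, 0.0], [0.2, 0.7, 0.1]])
        b = np.array([[0.8, 0.2, 0.0], [0.1, 0.8, 0.1]])
        expected = np.outer(a[0], b[0]) + np.outer(a[1], b[1])
        table = cross_platform_confusion(a, b)
        np.testing.assert_allclose(table.n, expected, atol=1e-15)
        assert table.total == pytest.approx(2.0)

    def test_disjoint_cohorts_use_marginal_product(self):
        a = hwe_onehot([0, 0, 1, 2])
        b = hwe_onehot([0, 1])
        table = cross_platform_confusion(a, b, disjoint=True)
        np.testing.assert_allclose(
            table.n, 3.0 * np.outer(a.mean(axis=0), b.mean(axis=0)))
        with pytest.raises(ValueError, match="disjoint"):
            cross_platform_confusion(a, b)


class TestHardCallMetrics:
    def test_accuracy_counts_argmax_matches(self):
        truth = GenotypeVector("s", [0, 1, 2])
        post = PosteriorMatrix("s", [[0.9, 0.1, 0], [0.2, 0.6, 0.2], [0.8, 0.1, 0.1]])
        assert accuracy(truth, post) == pytest.approx(2 / 3)

    def test_accuracy_tie_breaks_toward_lowest_genotype(self):
        truth = GenotypeVector("s", [0, 1])
        post = PosteriorMatrix("s", [[0.5, 0.5, 0.0], [0.5, 0.5, 0.0]])
        assert accuracy(truth, post) == pytest.approx(0.5)

    def test_all_major_calls_at_rare_snp_score_high_accuracy(self, rng):
        # accuracy inflates as MAF -> 0 even with zero information
        maf = 0.05
        truth = rng.binomial(2, maf, size=200_000).astype(np.int8)
        post = np.tile([1.0, 0.0, 0.0], (truth.shape[0], 1))
        assert accuracy(truth, post) == pytest.approx((1 - maf) ** 2, abs=0.01)
        # ... while IQS sees straight through it: no better than chance
        assert iqs(build_confusion(truth, post)) == pytest.approx(0.0, abs=1e-12)

    def test_efficiency_counts_confident_rows(self):
        post = PosteriorMatrix("s", [[0.95, 0.05, 0], [0.85, 0.15, 0], [0.04, 0.05, 0.91]])
        assert efficiency(post) == pytest.approx(2 / 3)
        assert efficiency(hwe_onehot([0, 1, 2])) == 1.0
        assert efficiency(np.full((5, 3), 1 / 3)) == 0.0

    def test_estimated_maf_folds_to_minor(self):
        assert estimated_maf(hwe_onehot([0, 0, 0])) == 0.0
        assert estimated_maf(hwe_onehot([1, 1])) == pytest.approx(0.5)
        assert estimated_maf(hwe_onehot([0, 1, 2])) == pytest.approx(0.5)
        assert estimated_maf(hwe_onehot([2, 2, 2, 1])) == pytest.approx(1 / 8)


@st.composite
def truth_and_posteriors(draw):
    n = draw(st.integers(min_value=2, max_value=30))
    calls = draw(st.lists(st.integers(min_value=0, max_value=2),
                          min_size=n, max_size=n))
    raw = draw(st.lists(st.tuples(*[st.floats(0.01, 1.0) for _ in range(3)]),
                        min_size=n, max_size=n))
    probs = np.asarray(raw)
    probs /= probs.sum(axis=1, keepdims=True)
    return np.asarray(calls, dtype=np.int8), probs


class TestInvariants:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(truth_and_posteriors())
    def test_mass_conservation(self, data):
        calls, probs = data
        table = build_confusion(calls, probs)
        assert table.total == pytest.approx(calls.shape[0], rel=1e-9)
        np.testing.assert_allclose(table.row_marginals.sum(), table.total)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(truth_and_posteriors(), st.permutations([0, 1, 2]))
    def test_label_permutation_symmetry(self, data, perm):
        calls, probs = data
        perm = np.asarray(perm)
        t1 = build_confusion(calls, probs)
        t2 = build_confusion(perm[calls], probs[:, np.argsort(perm)])
        assert observed_agreement(t1) == pytest.approx(observed_agreement(t2), abs=1e-12)
        assert chance_agreement(t1) == pytest.approx(chance_agreement(t2), abs=1e-12)
        v1, v2 = iqs(t1), iqs(t2)
        assert (np.isnan(v1) and np.isnan(v2)) or v1 == pytest.approx(v2, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(truth_and_posteriors())
    def test_defined_iqs_never_exceeds_one(self, data):
        calls, probs = data
        table = build_confusion(calls, probs)
        score = iqs(table)
        if not np.isnan(score):
            assert score <= 1.0 + 1e-12
            off_diag = table.n.sum() - np.trace(table.n)
            assert (score == pytest.approx(1.0, abs=1e-12)) == (off_diag < 1e-12)

    def test_batch_tables_match_per_snp_path(self, rng):
        truth = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        probs = rng.dirichlet([1, 1, 1], size=(6, 40))
        tables = confusion_batch(truth, probs)
        scores = iqs_from_tables(tables)
        for k in range(6):
            single = build_confusion(truth[k], probs[k])
            np.testing.assert_allclose(tables[k], single.n, atol=1e-12)
            assert scores[k] == pytest.approx(iqs(single), abs=1e-12)

    def test_random_hardcalls_from_marginals_score_near_zero(self, rng):
        # stochastic null: imputation by random calling has expected IQS 0
        n_snps, n = 1000, 1000
        mafs = rng.uniform(0.05, 0.5, size=n_snps)
        truth = rng.binomial(2, mafs[:, None], size=(n_snps, n)).astype(np.int8)
        scores = np.empty(n_snps)
        for k in range(n_snps):
            counts = np.bincount(truth[k], minlength=3)
            calls = rng.choice(3, size=n, p=counts / n)
            scores[k] = iqs(build_confusion(truth[k], hwe_onehot(calls)))
        assert abs(np.nanmean(scores)) < 0.02
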