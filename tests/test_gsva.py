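import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from clockpe.gsva import (
    GsvaParams,
    expression_statistic,
    gsva_scores,
    random_walk_es,
    rank_statistic,
)
from clockpe.io import ExpressionMatrix, GeneSetCollection, ValidationError


def _expr(values: np.ndarray, label="toy") -> ExpressionMatrix:
    genes = [f"G{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), cohort_label=label
    )


def gsva_reference(values, sets, tau=1.0, divisor=4.0):
    """Straight-line reimplementation with explicit loops, used as oracle."""
    n_genes, n_samples = values.shape
    z = np.zeros_like(values, dtype=float)
    for i in range(n_genes):
        h = np.std(values[i], ddof=1) / divisor
        for j in range(n_samples):
            acc = 0.0
            for k in range(n_samples):
                acc += norm.cdf((values[i, j] - values[i, k]) / h)
            z[i, j] = acc / n_samples
    scores = {}
    for name, members in sets.items():
        col = []
        for j in range(n_samples):
            order = np.argsort(-z[:, j], kind="stable")
            in_set = np.array([g in members for g in order])
            weights = np.abs(n_genes / 2.0 - np.arange(1, n_genes + 1)) ** tau
            gain = np.where(in_set, weights, 0.0)
            v = np.cumsum(gain) / gain.sum() - np.cumsum(~in_set) / (n_genes - in_set.sum())
            col.append(max(v.max(), 0.0) + min(v.min(), 0.0))
        scores[name] = col
    return z, scores


class TestExpressionStatistic:
    def test_constant_gene_gets_equal_statistic_with_warning(self):
        values = np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            z = expression_statistic(_expr(values))
        assert len(set(z.iloc[0])) == 1

    def test_centered_point_symmetry(self):
        z = expression_statistic(_expr(np.array([[0.0, 1.0, 2.0], [9.0, 1.0, 5.0]])))
        row = z.iloc[0]
        assert row["s1"] == pytest.approx(0.5)
        assert row["s0"] < row["s1"] < row["s2"]

    def test_matches_brute_force_kernel_sum(self):
        rng = np.random.default_rng(2)
        values = rng.normal(8, 1, size=(3, 4))
        z = expression_statistic(_expr(values))
        z_ref, _ = gsva_reference(values, {})
        np.testing.assert_allclose(z.to_numpy(), z_ref, atol=1e-9)

    def test_strictly_increasing_in_expression(self):
        values = np.array([[1.0, 3.0, 2.0, 5.0]])
        z = expression_statistic(_expr(np.vstack([values, values[::-1] * 2])))
        assert list(np.argsort(z.iloc[0].to_numpy())) == list(np.argsort(values[0]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            expression_statistic(_expr(np.ones((2, 2))))


class TestRankStatistic:
    def test_symmetric_weights_for_four_genes(self):
        _, weights = rank_statistic(np.array([0.9, 0.7, 0.5, 0.1]))
        np.testing.assert_allclose(weights, [1.0, 0.0, 1.0, 2.0])

    def test_reversed_input_reverses_order(self):
        z = np.array([0.1, 0.4, 0.8])
        fwd, _ = rank_statistic(z)
        rev, _ = rank_statistic(z[::-1])
        np.testing.assert_array_equal(fwd, len(z) - 1 - rev)

    def test_single_gene_degenerate_weight(self):
        _, weights = rank_statistic(np.array([0.3]))
        assert weights[0] == pytest.approx(0.5)


class TestRandomWalk:
    def test_top_ranked_singleton_attains_plus_one(self):
        in_set = np.array([True, False, False, False])
        es = random_walk_es(in_set, np.ones(4), GsvaParams(min_set_size=1))
        assert es == pytest.approx(1.0)

    def test_bottom_ranked_singleton_attains_minus_one(self):
        in_set = np.array([False, False, False, True])
        es = random_walk_es(in_set, np.ones(4), GsvaParams(min_set_size=1))
        assert es == pytest.approx(-1.0)

    def test_evenly_interleaved_half_set_is_balanced(self):
        in_set = np.tile([True, False], 10)
        es = random_walk_es(in_set, np.ones(20), GsvaParams(tau=0.0, min_set_size=1))
        assert abs(es) <= 0.15

    def test_empty_intersection_and_full_universe_rejected(self):
        with pytest.raises(ValidationError):
            random_walk_es(np.zeros(4, dtype=bool), np.ones(4))
        with pytest.raises(ValidationError):
            random_walk_es(np.ones(4, dtype=bool), np.ones(4))

    def test_maxdev_mode_returns_signed_largest_deviation(self):
        in_set = np.array([False, False, False, True])
        es = random_walk_es(in_set, np.ones(4), GsvaParams(es_mode="maxdev", min_set_size=1))
        assert es == pytest.approx(-1.0)


class TestGsvaScores:
    def _toy(self):
        rng = np.random.default_rng(9)
        values = rng.normal(7, 1, size=(6, 3))
        sets = GeneSetCollection(
            {"S1": ("d", ("G0", "G2", "G4")), "S2": ("d", ("G1", "G5"))}
        )
        return values, sets

    def test_matches_straight_line_reference(self):
        values, sets = self._toy()
        params = GsvaParams(min_set_size=1)
        scores = gsva_scores(_expr(values), sets, params)
        # the reference tracks genes by row position: G0 -> 0, etc.
        _, ref_scores = gsva_reference(values, {"S1": {0, 2, 4}, "S2": {1, 5}})
        np.testing.assert_allclose(scores.loc["S1"], ref_scores["S1"], atol=1e-9)
        np.testing.assert_allclose(scores.loc["S2"], ref_scores["S2"], atol=1e-9)

    def test_scores_bounded_on_random_input(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, size=(40, 8))
        sets = GeneSetCollection(
            {f"S{k}": ("d", tuple(f"G{i}" for i in rng.choice(40, 8, replace=False)))
             for k in range(5)}
        )
        scores = gsva_scores(_expr(values), sets, GsvaParams(min_set_size=1))
        assert (scores.to_numpy() >= -1 - 1e-12).all()
        assert (scores.to_numpy() <= 1 + 1e-12).all()

    def test_duplicated_sample_column_gives_identical_scores(self):
        values, sets = self._toy()
        dup = np.column_stack([values, values[:, 0]])
        scores = gsva_scores(_expr(dup), sets, GsvaParams(min_set_size=1))
        np.testing.assert_allclose(scores.iloc[:, 0], scores.iloc[:, 3], atol=1e-12)

    def test_sample_permutation_equivariance(self):
        values, sets = self._toy()
        params = GsvaParams(min_set_size=1)
        scores = gsva_scores(_expr(values), sets, params)
        perm = [2, 0, 1]
        permuted = gsva_scores(_expr(values[:, perm]), sets, params)
        np.testing.assert_allclose(
            permuted.to_numpy(), scores.to_numpy()[:, perm], atol=1e-12
        )

    def test_affine_transform_of_one_gene_row_is_invariant(self):
        # bandwidth scales with the SD, so shifting/scaling a gene's row
        # leaves its kernel-CDF statistic and all downstream scores unchanged
        values, sets = self._toy()
        params = GsvaParams(min_set_size=1)
        base = gsva_scores(_expr(values), sets, params)
        values2 = values.copy()
        values2[2] = 3.0 * values2[2] + 1.0
        np.testing.assert_allclose(
            gsva_scores(_expr(values2), sets, params).to_numpy(),
            base.to_numpy(),
            atol=1e-9,
        )

    def test_monotone_transform_preserves_within_gene_ordering(self):
        values, _ = self._toy()
        z1 = expression_statistic(_expr(values))
        values2 = values.copy()
        values2[1] = np.exp(values2[1] / 2)
        z2 = expression_statistic(_expr(values2))
        assert list(np.argsort(z1.iloc[1].to_numpy())) == list(
            np.argsort(z2.iloc[1].to_numpy())
        )

    def test_top_block_set_attains_maximal_walk_peak(self):
        values, _ = self._toy()
        z = expression_statistic(_expr(values), GsvaParams(min_set_size=1))
        order, weights = rank_statistic(z.iloc[:, 0].to_numpy())
        in_set = np.zeros(6, dtype=bool)
        in_set[:3] = True  # the top-3 ranked genes of this sample
        es = random_walk_es(in_set, weights, GsvaParams(min_set_size=1))
        assert es == pytest.approx(1.0)

    def test_no_surviving_sets_is_error(self):
        values, sets = self._toy()
        with pytest.raises(ValidationError):
            gsva_scores(_expr(values), sets, GsvaParams(min_set_size=10))
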