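import math

import numpy as np
import pandas as pd
import pytest

from clockpe.diffexpr import SignificanceThresholds
from clockpe.io import PhenotypeTable, ValidationError
from clockpe.pathways import (
    estimate_variance_prior,
    moderated_t,
    overlap_pathways,
    pearson_with_ci,
    score_pathway_table,
    trigamma_inverse,
)


def _pheno(n_ctrl, n_case):
    ids = [f"s{i}" for i in range(n_ctrl + n_case)]
    return PhenotypeTable(
        pd.DataFrame(
            {"condition": ["non-PE"] * n_ctrl + ["PE"] * n_case},
            index=pd.Index(ids, name="sample_id"),
        )
    )


def _scores(n_sets, n_ctrl, n_case, seed=0, shift_first=0.0):
    rng = np.random.default_rng(seed)
    data = rng.normal(0, 0.3, size=(n_sets, n_ctrl + n_case))
    data[0, n_ctrl:] += shift_first
    return pd.DataFrame(
        data,
        index=[f"P{k}" for k in range(n_sets)],
        columns=[f"s{i}" for i in range(n_ctrl + n_case)],
    )


class TestModeratedT:
    def test_zero_prior_df_recovers_ordinary_t(self):
        scores = _scores(6, 5, 5, seed=1, shift_first=0.8)
        pheno = _pheno(5, 5)
        out = moderated_t(scores, pheno, prior_df=0.0)
        from clockpe.diffexpr import two_sample_t

        for name in scores.index:
            a = scores.loc[name].iloc[:5].to_numpy()
            b = scores.loc[name].iloc[5:].to_numpy()
            t, _, p = two_sample_t(b, a)  # case minus control
            assert out.loc[name, "t"] == pytest.approx(t, rel=1e-9)
            assert out.loc[name, "p"] == pytest.approx(p, rel=1e-9)

    def test_fixed_hyperparameters_hand_arithmetic(self):
        # one pathway, groups of 4 and 4 (d = 6), s2 = 2, mean diff 1,
        # prior d0 = 4, s0^2 = 1: shrunken variance (4*1 + 6*2)/10 = 1.6,
        # t = 1/sqrt(1.6 * (1/4 + 1/4)) = 1.118, df = 10
        a = np.array([0.0, 1.0, -1.0, 0.0])
        sd_target = math.sqrt(2.0)
        a = a / a.std(ddof=1) * sd_target  # control: mean 0, s = sqrt(2)
        b = a + 1.0  # case: mean 1, same spread
        scores = pd.DataFrame(
            [np.concatenate([a, b])], index=["P0"],
            columns=[f"s{i}" for i in range(8)],
        )
        out = moderated_t(scores, _pheno(4, 4), prior_df=4.0, prior_var=1.0)
        assert out.loc["P0", "t"] == pytest.approx(1 / math.sqrt(1.6 * 0.5), rel=1e-9)
        assert out.loc["P0", "df"] == pytest.approx(10.0)

    def test_equal_group_means_give_null(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        scores = pd.DataFrame(
            [vals, vals * 2], index=["P0", "P1"], columns=[f"s{i}" for i in range(6)]
        )
        out = moderated_t(scores, _pheno(3, 3))
        assert out.loc["P0", "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["P0", "p"] == pytest.approx(1.0)

    def test_infinite_prior_df_uses_common_variance(self):
        scores = _scores(8, 6, 6, seed=3)
        out = moderated_t(scores, _pheno(6, 6), prior_df=math.inf, prior_var=0.09)
        # every set's t must use the same pooled variance
        diffs = scores.iloc[:, 6:].mean(axis=1) - scores.iloc[:, :6].mean(axis=1)
        expected = diffs / math.sqrt(0.09 * (2 / 6))
        np.testing.assert_allclose(out["t"], expected, rtol=1e-9)

    def test_identical_residual_variances_hit_infinite_prior_branch(self):
        base = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        scores = pd.DataFrame(
            [base + k for k in range(4)],
            index=[f"P{k}" for k in range(4)],
            columns=[f"s{i}" for i in range(6)],
        )
        out = moderated_t(scores, _pheno(3, 3))
        assert math.isinf(out.attrs["prior_df"])

    def test_prior_estimation_recovers_large_d0_for_homogeneous_variances(self):
        rng = np.random.default_rng(8)
        s2 = rng.chisquare(50, size=200) / 50  # tight spread around 1
        d0, s0 = estimate_variance_prior(s2, df=10.0)
        assert d0 > 10 and s0 == pytest.approx(1.0, abs=0.15)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (0.05, 0.5, 2.0, 20.0):
            x = trigamma_inverse(y)
            assert float(polygamma(1, x)) == pytest.approx(y, rel=1e-6)


class TestPearsonWithCi:
    def test_perfect_linear_relation_degenerates_cleanly(self):
        x = np.arange(10.0)
        rec = pearson_with_ci(x, 2 * x + 1)
        assert rec.r == pytest.approx(1.0)
        assert rec.p == 0.0
        assert rec.ci_low == rec.ci_high == rec.r

    def test_hand_computed_r_of_small_vectors(self):
        rec = pearson_with_ci(
            np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]),
            np.array([1.0, 3.0, 2.0, 1.0, 3.0, 2.0]),
        )
        assert rec.r == pytest.approx(0.5, rel=1e-12)

    def test_published_fisher_z_interval(self):
        # r = -0.57 at n = 157 must give the published CI (-0.67, -0.45)
        zr = math.atanh(-0.57)
        half = 1.96 / math.sqrt(157 - 3)
        assert round(math.tanh(zr - half), 2) == -0.67
        assert round(math.tanh(zr + half), 2) == -0.45
        # and the implementation agrees with its own closed form on data
        rng = np.random.default_rng(0)
        x = rng.normal(size=157)
        y = -0.6 * x + rng.normal(size=157)
        rec = pearson_with_ci(x, y)
        assert rec.ci_low == pytest.approx(math.tanh(math.atanh(rec.r) - half), rel=1e-9)

    def test_matches_brute_force_sums_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            x, y = rng.normal(size=n), rng.normal(size=n)
            rec = pearson_with_ci(x, y)
            sx, sy = x.sum(), y.sum()
            sxy = (x * y).sum()
            sxx, syy = (x * x).sum(), (y * y).sum()
            r_brute = (n * sxy - sx * sy) / math.sqrt(
                (n * sxx - sx * sx) * (n * syy - sy * sy)
            )
            assert rec.r == pytest.approx(r_brute, abs=1e-12)
            assert rec.ci_low < rec.r < rec.ci_high

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            pearson_with_ci(np.ones(10), np.arange(10.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci(np.arange(3.0), np.arange(3.0))


class TestScorePathwayTable:
    def test_correlated_pathway_detected_with_sign(self):
        rng = np.random.default_rng(5)
        n = 60
        risk = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        scores = pd.DataFrame(
            {f"s{i}": 0.0 for i in range(n)}, index=["NEG", "NULL"]
        ).astype(float)
        scores.loc["NEG"] = -0.8 * risk.to_numpy() + rng.normal(0, 0.4, n)
        scores.loc["NULL"] = rng.normal(0, 1, n)
        out = score_pathway_table(scores, risk)
        assert bool(out.loc["NEG", "significant"])
        assert out.loc["NEG", "r"] < 0

    def test_misaligned_samples_rejected(self):
        scores = pd.DataFrame([[0.1, 0.2]], index=["P"], columns=["a", "b"])
        risk = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(ValidationError):
            score_pathway_table(scores, risk)

    def test_empty_matrix_gives_empty_table(self):
        scores = pd.DataFrame(columns=["a", "b", "c", "d"]).astype(float)
        risk = pd.Series([1.0, 2.0, 3.0, 4.0], index=["a", "b", "c", "d"])
        assert score_pathway_table(scores, risk).empty

    def test_null_retention_near_nominal_rate(self):
        # with permuted (independent) risk scores, the raw p < 0.05 rate
        # stays near 5%; the dual filter can only reduce it
        rng = np.random.default_rng(17)
        n, n_sets = 50, 400
        risk = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        scores = pd.DataFrame(
            rng.normal(size=(n_sets, n)),
            index=[f"P{k}" for k in range(n_sets)],
            columns=risk.index,
        )
        out = score_pathway_table(scores, risk)
        assert (out["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.035)
        assert out["significant"].mean() <= 0.05 + 0.035


class TestOverlapPathways:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            rows, columns=["pathway", "r", "significant"]
        ).set_index("pathway")

    def test_concordant_sets_partitioned_by_sign(self):
        a = self._table(
            [("P1", -0.5, True), ("P2", 0.4, True), ("P3", -0.3, True)]
        )
        b = self._table(
            [("P1", -0.4, True), ("P2", 0.3, True), ("P3", -0.2, True)]
        )
        res = overlap_pathways(a, b)
        assert res.n_common == 3
        assert list(res.decreased.index) == ["P1", "P3"]
        assert list(res.increased.index) == ["P2"]

    def test_discordant_sign_excluded_and_reported(self):
        a = self._table([("P1", -0.5, True)])
        b = self._table([("P1", 0.5, True)])
        res = overlap_pathways(a, b)
        assert res.n_common == 0 and res.discordant == ["P1"]

    def test_disjoint_tables_empty(self):
        res = overlap_pathways(
            self._table([("P1", -0.5, True)]), self._table([("P2", 0.5, True)])
        )
        assert res.n_common == 0 and res.discordant == []
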