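import itertools

import numpy as np
import pandas as pd
import pytest

from oracles import bray_curtis_oracle, chao1_oracle, ols_oracle, ranksum_exact_oracle
from raretaxa.io import EnvTable, OtuTable, SampleMetadata
from raretaxa.soilfun import (
    SoilFunctionMatrix,
    alpha_by_class,
    alpha_function_regression,
    beta_function_regression,
    beta_pcoa_axis,
    bray_curtis,
    chao1,
    compare_alpha_by_health,
    zscore_functions,
)


def _table(counts):
    counts = np.asarray(counts)
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"S{i}" for i in range(counts.shape[0])],
            columns=[f"O{i}" for i in range(counts.shape[1])],
        )
    )


class TestChao1:
    def test_no_singletons_equals_observed_richness(self):
        assert chao1([5, 2, 3, 7]) == 4.0

    def test_hand_computed_example(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 4*3/6 = 12
        counts = [1, 1, 1, 1, 2, 2, 5, 5, 9, 4]
        assert chao1(counts) == pytest.approx(12.0)

    def test_never_below_observed_richness_and_matches_oracle(self):
        rng = np.random.default_rng(28)
        for _ in range(20):
            c = rng.poisson(1.2, size=50)
            got = chao1(c)
            assert got >= (c > 0).sum()
            assert got == pytest.approx(chao1_oracle(c), abs=1e-10)

    def test_empty_sample(self):
        assert chao1([]) == 0.0
        assert chao1([0, 0]) == 0.0


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = _table([[3, 4, 5], [3, 4, 5]])
        assert bray_curtis(t).iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        t = _table([[5, 0, 2, 0], [0, 3, 0, 9]])
        assert bray_curtis(t).iloc[0, 1] == pytest.approx(1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(29)
        t = _table(rng.integers(0, 30, size=(6, 15)) + 1)
        d = bray_curtis(t)
        rel = t.relative_abundance().to_numpy()
        for i, j in itertools.combinations(range(6), 2):
            assert d.iloc[i, j] == pytest.approx(
                bray_curtis_oracle(rel[i], rel[j]), abs=1e-12
            )

    def test_all_zero_sample_flagged(self):
        with pytest.raises(ValueError, match="S1"):
            bray_curtis(_table([[1, 2], [0, 0]]))


class TestZscore:
    def test_hand_computed_column(self):
        env = EnvTable(pd.DataFrame({"pH": [1.0, 2.0, 3.0]}, index=list("abc")))
        z = zscore_functions(env)
        np.testing.assert_allclose(z.z["pH"], [-1, 0, 1])
        assert z.sd["pH"] == pytest.approx(1.0)

    def test_columns_standardized(self):
        rng = np.random.default_rng(30)
        env = EnvTable(
            pd.DataFrame(rng.normal(5, 3, size=(20, 4)),
                         index=[f"S{i}" for i in range(20)],
                         columns=list("WXYZ"))
        )
        z = zscore_functions(env).z
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(31)
        env = EnvTable(
            pd.DataFrame(rng.normal(size=(10, 2)),
                         index=[f"S{i}" for i in range(10)], columns=["a", "b"])
        )
        z1 = zscore_functions(env).z
        z2 = zscore_functions(EnvTable(z1)).z
        pd.testing.assert_frame_equal(z1, z2, atol=1e-12, rtol=0)

    def test_constant_column_named_in_error(self):
        env = EnvTable(pd.DataFrame({"pH": [1.0, 2.0], "flat": [3.0, 3.0]},
                                    index=["a", "b"]))
        with pytest.raises(ValueError, match="flat"):
            zscore_functions(env)


def _functions(values, names=None):
    names = names or [f"F{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=[f"S{i}" for i in range(values.shape[0])],
                      columns=names)
    return zscore_functions(EnvTable(df))


class TestAlphaRegression:
    def test_alpha_equal_to_function_gives_r2_one(self):
        rng = np.random.default_rng(32)
        vals = rng.normal(size=(20, 1))
        fn = _functions(vals)
        alpha = pd.DataFrame({"AT": fn.z["F0"]})
        fits = alpha_function_regression(alpha, fn)
        assert fits["r2"].iloc[0] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(33)
        vals = rng.normal(size=(20, 3))
        fn = _functions(vals)
        alpha = pd.DataFrame(
            {"AT": rng.normal(50, 5, 20)}, index=fn.z.index
        )
        fits = alpha_function_regression(alpha, fn)
        for _, row in fits.iterrows():
            o = ols_oracle(fn.z[row["indicator"]], alpha["AT"])
            assert row["slope"] == pytest.approx(o["slope"], abs=1e-10)
            assert row["r2"] == pytest.approx(o["r2"], abs=1e-10)
            assert row["p"] == pytest.approx(o["p"], abs=1e-10)

    def test_zero_variance_alpha_flagged(self):
        rng = np.random.default_rng(34)
        fn = _functions(rng.normal(size=(10, 1)))
        alpha = pd.DataFrame({"AT": np.full(10, 5.0)}, index=fn.z.index)
        fits = alpha_function_regression(alpha, fn)
        assert not fits["defined"].iloc[0]

    def test_type_one_error_calibrated_under_null(self):
        """Independent alpha and functions: ~5% of fits flagged at p<0.05."""
        rng = np.random.default_rng(35)
        hits = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            from scipy.stats import linregress

            hits += linregress(x, y).pvalue < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 2 * se

    def test_affine_rescaling_invariance(self):
        """Z-scoring absorbs units: fits identical under affine transforms."""
        rng = np.random.default_rng(36)
        raw = rng.normal(10, 2, size=(15, 2))
        fn1 = _functions(raw)
        fn2 = _functions(raw * 37.0 + 5.0)
        alpha = pd.DataFrame({"AT": rng.normal(size=15)},
                             index=fn1.z.index)
        f1 = alpha_function_regression(alpha, fn1)
        f2 = alpha_function_regression(alpha, fn2)
        pd.testing.assert_frame_equal(f1, f2, atol=1e-10, rtol=0)


class TestBetaRegression:
    def test_distance_equal_to_delta_z_gives_r2_one(self):
        rng = np.random.default_rng(37)
        fn = _functions(rng.normal(size=(8, 1)))
        z = fn.z["F0"].to_numpy()
        n = len(z)
        d = np.abs(z[:, None] - z[None, :])
        beta = pd.DataFrame(d, index=fn.z.index, columns=fn.z.index)
        fits = beta_function_regression(beta, fn)
        assert fits["r2"].iloc[0] == pytest.approx(1.0)
        assert fits["n"].iloc[0] == n * (n - 1) // 2

    def test_consistent_relabeling_invariance(self):
        rng = np.random.default_rng(38)
        t = _table(rng.integers(1, 40, size=(8, 20)))
        fn = _functions(rng.normal(size=(8, 2)))
        beta = bray_curtis(t)
        f1 = beta_function_regression(beta, fn)
        perm = rng.permutation(8)
        order = [f"S{i}" for i in perm]
        beta2 = beta.loc[order, order]
        fn2 = SoilFunctionMatrix(fn.z.loc[order], fn.mean, fn.sd)
        f2 = beta_function_regression(beta2, fn2)
        for col in ("slope", "r2", "p"):
            np.testing.assert_allclose(f1[col], f2[col], atol=1e-12)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(39)
        t = _table(rng.integers(1, 40, size=(7, 25)))
        fn = _functions(rng.normal(size=(7, 1)))
        beta = bray_curtis(t)
        fits = beta_function_regression(beta, fn)
        z = fn.z["F0"].to_numpy()
        pairs = list(itertools.combinations(range(7), 2))
        x = [abs(z[i] - z[j]) for i, j in pairs]
        y = [beta.iloc[i, j] for i, j in pairs]
        o = ols_oracle(x, y)
        assert fits["slope"].iloc[0] == pytest.approx(o["slope"], abs=1e-10)
        assert fits["p"].iloc[0] == pytest.approx(o["p"], abs=1e-10)

    def test_pcoa_axis_orders_a_gradient(self):
        # three samples on a line in composition space
        t = _table([[10, 0, 0], [5, 5, 0], [0, 10, 0]])
        axis = beta_pcoa_axis(bray_curtis(t))
        assert (axis.iloc[0] < axis.iloc[1] < axis.iloc[2]) or (
            axis.iloc[0] > axis.iloc[1] > axis.iloc[2]
        )


class TestAlphaHealthComparison:
    def _meta(self, n):
        half = n // 2
        return SampleMetadata(
            pd.DataFrame({"site": ["QS"] * n, "health": ["H"] * half + ["M"] * half},
                         index=[f"S{i}" for i in range(n)])
        )

    def test_identical_groups_not_significant(self):
        alpha = pd.Series([5.0, 6, 7, 5, 6, 7], index=[f"S{i}" for i in range(6)])
        res = compare_alpha_by_health(alpha, self._meta(6))
        assert res["p"] > 0.9

    def test_separated_groups_significant(self):
        alpha = pd.Series(
            [10.0, 11, 12, 13, 14, 50, 51, 52, 53, 54],
            index=[f"S{i}" for i in range(10)],
        )
        res = compare_alpha_by_health(alpha, self._meta(10))
        assert res["p"] < 0.05

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(40)
        vals = rng.normal(size=12)
        alpha = pd.Series(vals, index=[f"S{i}" for i in range(12)])
        res = compare_alpha_by_health(alpha, self._meta(12))
        u_obs, p_exact = ranksum_exact_oracle(vals[:6], vals[6:])
        assert res["p"] == pytest.approx(p_exact, abs=1e-12)

    def test_alpha_by_class_splits_columns(self, processed):
        table, part, *_ = processed
        df = alpha_by_class(table, part)
        assert set(df.columns) == {"Whole", "AT", "IT", "RT"}
        assert (df["Whole"] >= df["AT"]).all()
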