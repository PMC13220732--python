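import numpy as np
import pandas as pd
import pytest

from volprior.stats import (
    bonferroni,
    cluster_permutation_paired,
    paired_t,
    pearson_r,
    power_paired_t,
    rm_anova,
)


def long_frame(Y, factors):
    """Subject x cell array -> long table; factors = dict name -> levels."""
    names = list(factors)
    grids = np.meshgrid(*[np.arange(len(factors[f])) for f in names], indexing="ij")
    rows = []
    for s in range(Y.shape[0]):
        flat = Y[s].reshape(-1)
        for c, y in enumerate(flat):
            row = {"participant": s, "y": y}
            for g, f in zip(grids, names):
                row[f] = factors[f][g.reshape(-1)[c]]
            rows.append(row)
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_f_equals_squared_paired_t(self, rng):
        x = rng.normal(0, 1, 12)
        y = x + rng.normal(0.5, 1, 12)
        df = long_frame(np.column_stack([x, y])[:, None, :].reshape(12, 2),
                        {"cond": ["a", "b"]})
        res = rm_anova(df, dv="y", within=["cond"])
        t, _, p_t, _ = paired_t(x, y)
        assert res["F"].iloc[0] == pytest.approx(t**2, rel=1e-10)
        assert res["p"].iloc[0] == pytest.approx(p_t, rel=1e-10)

    def test_two_level_factors_uncorrectable(self, rng):
        Y = rng.normal(size=(8, 2, 2))
        df = long_frame(Y, {"a": ["x", "y"], "b": ["u", "v"]})
        res = rm_anova(df, dv="y", within=["a", "b"])
        assert (res["gg_epsilon"] == 1.0).all()
        assert not res["corrected"].any()

    def test_one_way_matches_brute_force_ss(self, rng):
        """3-level toy design against the classical sums-of-squares formulas."""
        n, k = 10, 3
        Y = rng.normal(0, 1, (n, k)) + np.array([0.0, 0.4, 0.9])
        df = long_frame(Y, {"cond": ["c1", "c2", "c3"]})
        res = rm_anova(df, dv="y", within=["cond"], correction="never")
        grand = Y.mean()
        ss_f = n * np.sum((Y.mean(axis=0) - grand) ** 2)
        ss_s = k * np.sum((Y.mean(axis=1) - grand) ** 2)
        ss_t = np.sum((Y - grand) ** 2)
        ss_e = ss_t - ss_f - ss_s
        F = (ss_f / (k - 1)) / (ss_e / ((k - 1) * (n - 1)))
        assert res["F"].iloc[0] == pytest.approx(F, abs=1e-8)
        assert res["partial_eta_sq"].iloc[0] == pytest.approx(
            ss_f / (ss_f + ss_e), abs=1e-8
        )

    def test_matches_pingouin_two_way(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(12, 3, 2)) + rng.normal(0, 0.5, (1, 3, 2))
        df = long_frame(Y, {"a": ["a1", "a2", "a3"], "b": ["b1", "b2"]})
        ours = rm_anova(df, dv="y", within=["a", "b"], correction="never")
        theirs = pg.rm_anova(data=df, dv="y", within=["a", "b"],
                             subject="participant", detailed=True)
        for effect, name in [("a", "a"), ("b", "b"), ("a * b", "a * b")]:
            f_ours = ours.loc[ours["effect"] == effect, "F"].iloc[0]
            f_pg = theirs.loc[theirs["Source"] == name, "F"].iloc[0]
            assert f_ours == pytest.approx(f_pg, rel=1e-6)

    def test_invariant_to_subject_constant_shift(self, rng):
        Y = rng.normal(size=(9, 3, 2))
        shifted = Y + rng.normal(0, 5, size=(9, 1, 1))
        f1 = rm_anova(long_frame(Y, {"a": list("abc"), "b": list("uv")}),
                      dv="y", within=["a", "b"], correction="never")
        f2 = rm_anova(long_frame(shifted, {"a": list("abc"), "b": list("uv")}),
                      dv="y", within=["a", "b"], correction="never")
        np.testing.assert_allclose(f1["F"], f2["F"], rtol=1e-8)

    def test_gg_correction_reduces_df(self, rng):
        # strongly non-spherical data: one condition much noisier
        n = 20
        base = rng.normal(size=(n, 1))
        Y = np.hstack([base + rng.normal(0, 0.1, (n, 1)),
                       base + rng.normal(0, 0.1, (n, 1)),
                       rng.normal(0, 5, (n, 1))])
        df = long_frame(Y, {"cond": list("abc")})
        res = rm_anova(df, dv="y", within=["cond"], correction="always")
        assert res["df_num"].iloc[0] < 2.0
        assert res["gg_epsilon"].iloc[0] < 1.0

    def test_missing_cell_rejected(self, rng):
        Y = rng.normal(size=(6, 3))
        df = long_frame(Y, {"cond": list("abc")})
        df = df[~((df["participant"] == 0) & (df["cond"] == "a"))]
        with pytest.raises(ValueError):
            rm_anova(df, dv="y", within=["cond"])

    def test_unbalanced_rejected(self, rng):
        Y = rng.normal(size=(6, 2))
        df = long_frame(Y, {"cond": list("ab")})
        extra = df.iloc[[0]].copy()
        with pytest.raises(ValueError):
            rm_anova(pd.concat([df, extra]), dv="y", within=["cond"])


class TestPairedT:
    def test_matches_textbook_formula(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.3, 1, 20)
        t, df, p, dz = paired_t(x, y)
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(20))
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert df == 19
        assert dz == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])  # constant +1 difference


class TestBonferroni:
    def test_scaling_and_cap(self):
        np.testing.assert_allclose(bonferroni([0.02, 0.5], m=4), [0.08, 1.0])

    def test_identity_at_m_one(self):
        np.testing.assert_allclose(bonferroni([0.3], m=1), [0.3])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=50)
        y = 0.4 * x + rng.normal(size=50)
        r, _ = pearson_r(x, y)
        oracle = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestClusterPermutation:
    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cluster_permutation_paired(np.ones((5, 10)), np.ones((5, 9)))

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        n, T = 10, 15
        a = rng.normal(0, 1, (n, T))
        a[:, 5:9] += 1.2
        b = rng.normal(0, 1, (n, T))
        mc = cluster_permutation_paired(a, b, n_perm=10_000, seed=3)
        ex = cluster_permutation_paired(a, b, exhaustive=True)
        assert [c[:2] for c in mc.clusters] == [c[:2] for c in ex.clusters]
        np.testing.assert_allclose(mc.p_values, ex.p_values, atol=0.02)

    def test_planted_effect_detected(self, rng):
        n, T = 16, 60
        a = rng.normal(0, 1, (n, T))
        b = rng.normal(0, 1, (n, T))
        a[:, 29:40] += 2.5  # large shift at positions 30-40 (1-based)
        res = cluster_permutation_paired(a, b, n_perm=2000, seed=0)
        sig = res.significant(0.05)
        assert len(sig) == 1
        start, end, stat = sig[0]
        assert start >= 27 and end <= 41 and stat > 0
        assert set(range(29, 40)).issubset(range(start, end + 1))

    def test_p_floor_is_one_over_nperm(self, rng):
        n, T = 12, 20
        a = rng.normal(0, 0.2, (n, T)) + 5.0
        b = rng.normal(0, 0.2, (n, T))
        res = cluster_permutation_paired(a, b, n_perm=500, seed=1)
        assert res.p_values.min() >= 1.0 / 500


class TestPower:
    def test_printed_sample_sizes(self):
        assert power_paired_t(1.5, alpha=0.05, power=0.9) == 7
        assert power_paired_t(0.65, alpha=0.05, power=0.9) == 27

    def test_minimality(self):
        from volprior.stats import _paired_t_power

        n = power_paired_t(0.8)
        assert _paired_t_power(n, 0.8, 0.05, 2) >= 0.9
        assert _paired_t_power(n - 1, 0.8, 0.05, 2) < 0.9

    def test_monotone_in_effect_and_power(self):
        assert power_paired_t(0.5) >= power_paired_t(1.0)
        assert power_paired_t(0.5, power=0.95) >= power_paired_t(0.5, power=0.8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_paired_t(0.0)
        with pytest.raises(ValueError):
            power_paired_t(0.5, alpha=0.5, power=0.4)
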