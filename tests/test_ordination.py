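"""Bray-Curtis, collinearity screen, and dbRDA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from streamdisturb.ordination import (
    DistanceRDA,
    bray_curtis,
    select_variables,
)
from conftest import random_abundance


def classical_rda_eigenvalues(Z, X):
    """Independent oracle: RDA of raw data Z on X (SS convention)."""
    Zc = Z - Z.mean(axis=0)
    Xc = X - X.mean(axis=0)
    Xs = Xc / Xc.std(axis=0, ddof=1)
    Q, _ = np.linalg.qr(Xs)
    fitted = Q @ Q.T @ Zc
    sv = np.linalg.svd(fitted, compute_uv=False)
    return sv[sv > 1e-9] ** 2


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == 0.0

    def test_disjoint_rows_one(self):
        m = pd.DataFrame([[4, 0], [0, 9]], index=["a", "b"])
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_example_no_transform(self):
        m = pd.DataFrame([[1, 2], [2, 2]], index=["a", "b"])
        d = bray_curtis(m, transform="none")
        assert d.loc["a", "b"] == pytest.approx(1 / 7)

    def test_sqrt_transform_applied(self):
        m = pd.DataFrame([[1, 4], [4, 4]], index=["a", "b"])
        d = bray_curtis(m, transform="sqrt")
        assert d.loc["a", "b"] == pytest.approx(1 / 7)  # sqrt -> (1,2),(2,2)

    def test_matches_brute_force(self, rng):
        m = random_abundance(rng, 8, 12)
        d = bray_curtis(m, transform="none").to_numpy()
        X = m.to_numpy(dtype=float)
        for i in range(8):
            for j in range(8):
                expected = np.abs(X[i] - X[j]).sum() / (X[i] + X[j]).sum()
                assert d[i, j] == pytest.approx(expected)

    def test_metric_properties(self, rng):
        m = random_abundance(rng, 9, 10)
        d = bray_curtis(m)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert (arr >= 0).all() and (arr <= 1).all()

    def test_all_zero_row_rejected(self):
        m = pd.DataFrame([[1, 2], [0, 0]], index=["a", "dead"])
        with pytest.raises(ValueError, match="dead"):
            bray_curtis(m)


class TestSelectVariables:
    def test_duplicated_column_drops_exactly_one(self, rng):
        x = rng.normal(size=30)
        env = pd.DataFrame({"a": x, "a_copy": x, "b": rng.normal(size=30)})
        kept, log = select_variables(env)
        assert kept.shape[1] == 2
        assert len([e for e in log if e["stage"] == "spearman"]) == 1
        assert {"a", "a_copy"} & set(kept.columns)

    def test_orthogonal_variables_all_kept(self, rng):
        env = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        kept, log = select_variables(env)
        assert list(kept.columns) == list("abcd")
        assert log == []

    def test_linear_combination_dropped_by_vif(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        env = pd.DataFrame(
            {"a": a, "b": b, "c": a + b + rng.normal(0, 0.02, 40)}
        )
        # VIF oracle 1/(1-R^2) for the near-collinear variable
        resid = np.linalg.lstsq(
            np.column_stack([np.ones(40), a, b]), env["c"], rcond=None
        )[1][0]
        r2 = 1 - resid / ((env["c"] - env["c"].mean()) ** 2).sum()
        assert 1 / (1 - r2) > 10
        kept, log = select_variables(env)
        assert kept.shape[1] == 2
        assert log[0]["stage"] in ("spearman", "vif")

    def test_fully_collinear_set_keeps_single_survivor(self, rng):
        x = rng.normal(size=25)
        env = pd.DataFrame({"a": x, "b": x, "c": x * 2})
        kept, log = select_variables(env)
        assert kept.shape[1] == 1
        assert len(log) == 2

    def test_too_few_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            select_variables(pd.DataFrame({"a": rng.normal(size=10)}))


class TestDistanceRDA:
    def test_euclidean_equivalence_with_classical_rda(self, rng):
        """Under Euclidean distances dbRDA reduces to RDA on coordinates."""
        for _ in range(5):
            Z = rng.normal(size=(10, 6))
            X = rng.normal(size=(10, 3))
            D = pd.DataFrame(squareform(pdist(Z)))
            env = pd.DataFrame(X, columns=list("abc"), index=D.index)
            res = DistanceRDA(D, env).fit()
            oracle = classical_rda_eigenvalues(Z, X)
            assert res.eig_constrained == pytest.approx(
                oracle[: len(res.eig_constrained)], rel=1e-8
            )

    def test_total_inertia_conserved(self, rng):
        m = random_abundance(rng, 12, 20)
        env = pd.DataFrame(rng.normal(size=(12, 3)), index=m.index,
                           columns=list("abc"))
        res = DistanceRDA.from_abundance(m, env).fit()
        decomposed = res.constrained_inertia + res.eig_unconstrained.sum()
        assert decomposed == pytest.approx(res.total_inertia, rel=1e-8)

    def test_invariant_to_site_ordering(self, rng):
        m = random_abundance(rng, 10, 14)
        env = pd.DataFrame(rng.normal(size=(10, 2)), index=m.index,
                           columns=["u", "v"])
        res1 = DistanceRDA.from_abundance(m, env).fit()
        order = rng.permutation(10)
        res2 = DistanceRDA.from_abundance(m.iloc[order], env.iloc[order]).fit()
        assert res1.eig_constrained == pytest.approx(res2.eig_constrained,
                                                     rel=1e-8)
        assert res1.total_inertia == pytest.approx(res2.total_inertia)

    def test_axis_scores_orthogonal(self, rng):
        m = random_abundance(rng, 12, 16)
        env = pd.DataFrame(rng.normal(size=(12, 3)), index=m.index,
                           columns=list("abc"))
        S = DistanceRDA.from_abundance(m, env).fit().site_scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(gram).max()

    def test_binary_split_variable_separates_clusters(self, rng):
        # two community clusters differing in composition
        a = rng.poisson([10, 10, 1, 1], size=(5, 4))
        b = rng.poisson([1, 1, 10, 10], size=(5, 4))
        m = pd.DataFrame(np.vstack([a, b]) + 1,
                         index=[f"s{i}" for i in range(10)])
        env = pd.DataFrame({"split": [0.0] * 5 + [1.0] * 5}, index=m.index)
        res = DistanceRDA.from_abundance(m, env).fit()
        s1 = res.site_scores["dbRDA1"]
        assert (s1.iloc[:5].max() < s1.iloc[5:].min()) or (
            s1.iloc[:5].min() > s1.iloc[5:].max()
        )
        unconstrained_1 = res.eig_unconstrained[0] / res.total_inertia
        assert res.proportion_explained.iloc[0] > unconstrained_1

    def test_sqrt_correction_removes_negative_inertia(self, rng):
        m = random_abundance(rng, 12, 8)
        env = pd.DataFrame(rng.normal(size=(12, 2)), index=m.index,
                           columns=["u", "v"])
        res = DistanceRDA.from_abundance(m, env, sqrt_correction=True).fit()
        assert res.negative_inertia == pytest.approx(0.0, abs=1e-8)

    def test_structuring_variable_attains_min_p(self, rng):
        a = rng.poisson([20, 1], size=(8, 2))
        b = rng.poisson([1, 20], size=(8, 2))
        m = pd.DataFrame(np.vstack([a, b]) + 1,
                         index=[f"s{i}" for i in range(16)])
        env = pd.DataFrame({"grad": np.r_[np.zeros(8), np.ones(8)]},
                           index=m.index)
        res = DistanceRDA.from_abundance(m, env).fit()
        tests = res.permutation_test(by="axis", n_perm=999, seed=0)
        assert tests.loc[tests["term"] == "model", "p"].iloc[0] == pytest.approx(
            0.001
        )

    def test_margin_single_variable_matches_global(self, rng):
        m = random_abundance(rng, 10, 12)
        env = pd.DataFrame({"only": rng.normal(size=10)}, index=m.index)
        res = DistanceRDA.from_abundance(m, env).fit()
        ax = res.permutation_test(by="axis", n_perm=199, seed=7)
        mg = res.permutation_test(by="margin", n_perm=199, seed=7)
        f_global = ax.loc[ax["term"] == "model", "pseudo_F"].iloc[0]
        assert mg.loc[0, "pseudo_F"] == pytest.approx(f_global, rel=1e-10)
        assert mg.loc[0, "p"] == ax.loc[ax["term"] == "model", "p"].iloc[0]

    def test_shape_and_validation_errors(self, rng):
        m = random_abundance(rng, 6, 8)
        env = pd.DataFrame(rng.normal(size=(6, 5)), index=m.index)
        with pytest.raises(ValueError, match="n_sites > n_variables"):
            DistanceRDA.from_abundance(m, env)
        env2 = pd.DataFrame({"a": rng.normal(size=6)}, index=m.index)
        env2["b"] = env2["a"] * 2  # rank deficient
        with pytest.raises(ValueError, match="rank-deficient"):
            DistanceRDA.from_abundance(m, env2).fit()

    def test_summary_renders(self, rng):
        m = random_abundance(rng, 10, 10)
        env = pd.DataFrame(rng.normal(size=(10, 2)), index=m.index,
                           columns=["u", "v"])
        text = DistanceRDA.from_abundance(m, env).fit().summary()
        assert "constrained inertia" in text
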