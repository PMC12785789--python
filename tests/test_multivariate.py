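"""Standardization, small-n PCA, Spearman rank correlation and one-way ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecikin import reference as ref
from ecikin.multivariate import (
    one_way_anova,
    run_pca,
    spearman_matrix,
    spearman_rho,
    standardize,
)
from ecikin.synthetic import assemble_feature_matrix


def rank_corr_oracle(x, y):
    """Pearson correlation of average ranks, written out longhand."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(v.size)
        for i, val in enumerate(v):
            less = np.sum(v < val)
            equal = np.sum(v == val)
            r[i] = less + (equal + 1) / 2.0
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean(); ry -= ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


class TestStandardize:
    def test_symmetric_triple(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        assert np.allclose(standardize(df)["x"], [-1, 0, 1])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        z = standardize(df)
        assert np.allclose(standardize(z), z, atol=1e-12)

    def test_zero_spread_column_named(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(df)

    def test_amplitude_column_largest_score_for_light(self):
        fm = assemble_feature_matrix()
        z = standardize(fm)
        assert z["a1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["a1"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        assert z["a1"].idxmax() == "light"


class TestRunPCA:
    def test_three_observations_two_components_explain_all(self):
        z = standardize(assemble_feature_matrix())
        res = run_pca(z)
        assert res.loadings.shape[1] == 2
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_perfectly_correlated_pair_collapses_to_one_component(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0]})
        res = run_pca(standardize(df))
        assert res.explained_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_loadings_orthonormal_and_reconstruction(self):
        rng = np.random.default_rng(5)
        z = standardize(pd.DataFrame(rng.normal(size=(3, 11)),
                                     columns=[f"v{i}" for i in range(11)]))
        res = run_pca(z)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
        assert np.allclose(res.scores.to_numpy() @ L.T, z.to_numpy(), atol=1e-9)

    def test_agrees_with_sklearn_reference(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(8)
        z = standardize(pd.DataFrame(rng.normal(size=(5, 4)), columns=list("wxyz")))
        res = run_pca(z)
        skl = sklearn_pca.PCA(n_components=4).fit(z.to_numpy())
        # sklearn re-centers (no-op here) and computes variance ratios the same way
        assert np.allclose(res.explained_pct / 100.0,
                           skl.explained_variance_ratio_, atol=1e-9)
        assert np.allclose(np.abs(res.loadings.to_numpy().T),
                           np.abs(skl.components_), atol=1e-9)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError, match="2 observations"):
            run_pca(pd.DataFrame({"x": [1.0]}))


class TestSpearman:
    def test_amplitudes_perfectly_concordant(self):
        rho = spearman_rho([20.848, 16.810, 8.187], [20.651, 16.591, 7.980])
        assert rho == 1.0

    def test_self_correlation(self):
        assert spearman_rho([3.0, 1.0, 2.0], [3.0, 1.0, 2.0]) == 1.0

    def test_amplitude_vs_rate_discordant(self):
        rho = spearman_rho([20.848, 16.810, 8.187], [0.350, 0.356, 0.383])
        assert rho == -1.0

    def test_constant_input_undefined(self):
        with pytest.warns(RuntimeWarning, match="zero rank variance"):
            assert math.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            rho = spearman_rho(x, y)
            assert spearman_rho(np.exp(x), y) == pytest.approx(rho, abs=1e-12)
            assert spearman_rho(x, y**3) == pytest.approx(rho, abs=1e-12)

    def test_reference_kinetic_columns_match_longhand_ranks(self):
        """Every pair of kinetic parameter columns agrees with a naive
        rank-correlation computation (ties by average rank)."""
        cols = {
            k: [ref.KINETIC_REFERENCE[l][k] for l in ref.TOAST_LEVELS]
            for k in ("eci_eq", "a1_mag", "k1", "a2_mag", "k2", "r2")
        }
        names = list(cols)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                x, y = cols[names[i]], cols[names[j]]
                assert spearman_rho(x, y) == pytest.approx(
                    rank_corr_oracle(x, y), abs=1e-12), (names[i], names[j])

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        fm = assemble_feature_matrix()
        m = spearman_matrix(fm)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_zero_within_variance_degenerate(self):
        res = one_way_anova([[0.0, 0.0], [1.0, 1.0]])
        assert math.isinf(res.f_stat)
        assert res.degenerate
        assert res.p_value == 0.0

    def test_textbook_decomposition_by_hand(self):
        # SS_between = 4, SS_within = 1.5 → F = (4/2)/(1.5/3) = 4.0
        res = one_way_anova([[1, 2], [2, 3], [3, 4]])
        assert res.f_stat == pytest.approx(4.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 3)
        assert res.p_value == pytest.approx(float(stats.f.sf(4.0, 2, 3)), abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            one_way_anova([[1, 2], [3]])

    def test_permutation_null_matches_f_distribution_mean(self):
        """F on label-permuted null data averages to df_w/(df_w−2)."""
        rng = np.random.default_rng(12)
        data = rng.normal(size=30)
        fs = []
        for _ in range(500):
            perm = rng.permutation(data)
            fs.append(one_way_anova([perm[:10], perm[10:20], perm[20:]]).f_stat)
        expected = 27 / 25  # E[F] for df_within = 27
        assert np.mean(fs) == pytest.approx(expected, rel=0.15)
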