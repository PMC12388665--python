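import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from microassembly.env_stats import (
    anova_lsd_cld,
    env_distance,
    mantel,
    mantel_exhaustive,
    partial_mantel,
    pearson_matrix,
    significance_band,
)
from microassembly.errors import InsufficientDataError, ValidationError


def random_distance(rng, n, dim=3):
    return squareform(pdist(rng.standard_normal((n, dim))))


class TestMantel:
    def test_self_correlation(self):
        rng = np.random.default_rng(0)
        D = random_distance(rng, 10)
        res = mantel(D, D, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_matches_skbio_oracle(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(2)
        Dx, Dy = random_distance(rng, 12), random_distance(rng, 12)
        ours = mantel(Dx, Dy, n_perm=999, seed=0)
        r_ref, p_ref, _ = skbio_mantel(Dx, Dy, permutations=999,
                                       alternative="greater", seed=0)
        assert ours.r == pytest.approx(r_ref, abs=1e-12)
        # permutation p-values agree within Monte-Carlo error
        assert abs(ours.p_value - p_ref) < 0.08

    def test_spearman_equals_pearson_on_ranked_matrices(self):
        rng = np.random.default_rng(3)
        Dx, Dy = random_distance(rng, 9), random_distance(rng, 9)
        rs = mantel(Dx, Dy, n_perm=9, seed=0, method="spearman").r
        iu = np.triu_indices(9, 1)
        ref = stats.spearmanr(Dx[iu], Dy[iu]).statistic
        assert rs == pytest.approx(ref, abs=1e-12)

    def test_sampled_p_approaches_exhaustive(self):
        rng = np.random.default_rng(4)
        Dx, Dy = random_distance(rng, 6), random_distance(rng, 6)
        exact = mantel_exhaustive(Dx, Dy)
        sampled = mantel(Dx, Dy, n_perm=4999, seed=5)
        assert abs(sampled.p_value - exact.p_value) < 0.03

    def test_exhaustive_covers_all_permutations(self):
        rng = np.random.default_rng(5)
        Dx, Dy = random_distance(rng, 5), random_distance(rng, 5)
        res = mantel_exhaustive(Dx, Dy)
        assert res.n_permutations == 120
        assert res.p_value >= 1 / 120

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(6)
        Dx, Dy = random_distance(rng, 10), random_distance(rng, 10)
        assert mantel(Dx, Dy, seed=7) == mantel(Dx, Dy, seed=7)

    def test_mismatched_ids_rejected(self):
        from skbio import DistanceMatrix

        D1 = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
                            ids=["a", "b", "c"])
        D2 = DistanceMatrix(D1.data, ids=["a", "b", "z"])
        with pytest.raises(ValidationError):
            mantel(D1, D2)


class TestPartialMantel:
    def test_perfect_control_gives_zero(self):
        rng = np.random.default_rng(8)
        Dx, Dy = random_distance(rng, 8), random_distance(rng, 8)
        res = partial_mantel(Dx, Dy, Dy, n_perm=9, seed=0)
        assert abs(res.r) < 1e-12

    def test_uncorrelated_control_leaves_r(self):
        rng = np.random.default_rng(9)
        Dx = random_distance(rng, 30, dim=5)
        Dy = Dx + 0.1 * random_distance(rng, 30, dim=5)
        Dz = random_distance(rng, 30, dim=5)
        plain = mantel(Dx, Dy, n_perm=9, seed=0).r
        partial = partial_mantel(Dx, Dy, Dz, n_perm=9, seed=0).r
        assert abs(plain - partial) < 0.05

    def test_formula_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(10)
        Dx, Dy, Dz = (random_distance(rng, 12) for _ in range(3))
        res = partial_mantel(Dx, Dy, Dz, n_perm=9, seed=0)
        iu = np.triu_indices(12, 1)
        vx, vy, vz = Dx[iu], Dy[iu], Dz[iu]
        # regress x and y on z, correlate residuals
        def residual(v, z):
            beta = np.polyfit(z, v, 1)
            return v - np.polyval(beta, z)

        oracle = stats.pearsonr(residual(vx, vz), residual(vy, vz))[0]
        assert res.r == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_control_rejected(self):
        rng = np.random.default_rng(11)
        Dx, Dy = random_distance(rng, 6), random_distance(rng, 6)
        with pytest.raises(ValidationError):
            partial_mantel(Dx, Dy, Dx)


class TestEnvDistance:
    def test_single_variable_hand_value(self):
        frame = pd.DataFrame({"pH": [7.0, 10.0]}, index=["a", "b"])
        D = env_distance(frame, ["pH"])
        # sd with n-1 of (0,3) is 3/sqrt(2); distance = 3 / (3/sqrt(2)) = sqrt(2)
        assert D.data[0, 1] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_identical_samples_zero(self):
        frame = pd.DataFrame({"x": [1.0, 1.0, 2.0], "y": [4.0, 4.0, 5.0]},
                             index=list("abc"))
        assert env_distance(frame, ["x", "y"]).data[0, 1] == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame(rng.standard_normal((6, 2)), columns=["u", "v"],
                             index=list("abcdef"))
        shifted = frame + 100.0
        assert np.allclose(env_distance(frame, ["u", "v"]).data,
                           env_distance(shifted, ["u", "v"]).data, atol=1e-10)

    def test_zero_variance_variable_dropped(self):
        frame = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 4.0]},
                             index=list("abc"))
        with pytest.warns(UserWarning, match="flat"):
            D = env_distance(frame, ["flat", "x"])
        assert D.data[0, 1] > 0


class TestPearsonMatrix:
    def test_diagonal_and_anticorrelation(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [-1.0, -2.0, -3.0]})
        corr = pearson_matrix(frame)
        assert corr.loc["x", "x"] == pytest.approx(1.0)
        assert corr.loc["x", "y"] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(13)
        frame = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        corr = pearson_matrix(frame).to_numpy()
        X = frame.to_numpy()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        sd = np.sqrt(np.diag(cov))
        oracle = cov / np.outer(sd, sd)
        assert np.max(np.abs(corr - oracle)) < 1e-12


class TestAnovaLsdCld:
    def test_two_groups_F_equals_t_squared(self):
        rng = np.random.default_rng(14)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(1, 1, 6)])
        groups = np.array(["a"] * 8 + ["b"] * 6)
        res, _ = anova_lsd_cld(values, groups)
        t, _ = stats.ttest_ind(values[:8], values[8:], equal_var=True)
        assert res.F == pytest.approx(t**2, abs=1e-10)

    def test_well_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(15)
        values = np.concatenate([rng.normal(mu, 0.1, 3) for mu in (0, 10, 20)])
        groups = np.repeat(["g0", "g10", "g20"], 3)
        _, letters = anova_lsd_cld(values, groups)
        assert len({letters[g] for g in ("g0", "g10", "g20")}) == 3
        assert all(len(v) == 1 for v in letters.values())

    def test_letters_encode_significance_matrix(self):
        # reconstruction property: share a letter <=> non-significant pair
        rng = np.random.default_rng(16)
        for trial in range(10):
            k = rng.integers(3, 6)
            values, groups = [], []
            for g in range(k):
                mu = rng.uniform(0, 3)
                values.extend(rng.normal(mu, 1.0, 5))
                groups.extend([f"g{g}"] * 5)
            values, groups = np.array(values), np.array(groups)
            res, letters = anova_lsd_cld(values, groups)
            df_w = res.df_within
            for g1, g2 in itertools.combinations(sorted(set(groups)), 2):
                v1, v2 = values[groups == g1], values[groups == g2]
                se = np.sqrt(res.mse * (1 / len(v1) + 1 / len(v2)))
                p = 2 * stats.t.sf(abs(v1.mean() - v2.mean()) / se, df_w)
                shares = bool(set(letters[g1]) & set(letters[g2]))
                assert shares == (p >= 0.05), (trial, g1, g2)

    def test_single_observation_group_named_in_error(self):
        with pytest.raises(InsufficientDataError, match="lonely"):
            anova_lsd_cld([1.0, 2.0, 3.0], ["a", "a", "lonely"])


def test_significance_bands():
    assert significance_band(0.001) == "p<0.01"
    assert significance_band(0.03) == "0.01<=p<0.05"
    assert significance_band(0.5) == "p>=0.05"
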