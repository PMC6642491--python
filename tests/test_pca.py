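import numpy as np
import pytest

import healtheff as h
from oracles import kmo_3x3_oracle, pearson_pair_oracle


def corr(entries, labels=None):
    entries = np.asarray(entries, float)
    labels = labels or [f"V{i + 1}" for i in range(entries.shape[0])]
    return h.CorrelationMatrix(tuple(labels), entries)


class TestZStandardize:
    def test_mean_zero_sd_one(self):
        Z = h.zstandardize(np.array([[1.], [2.], [3.]]))
        assert Z.mean() == pytest.approx(0.0, abs=1e-12)
        assert Z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        Z = h.zstandardize(rng.normal(size=(40, 3)))
        np.testing.assert_allclose(h.zstandardize(Z), Z, atol=1e-12)

    def test_two_point_sample_sd(self):
        Z = h.zstandardize(np.array([[2.], [4.]]))
        np.testing.assert_allclose(Z[:, 0], [-0.7071, 0.7071], atol=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="column"):
            h.zstandardize(np.array([[1., 5.], [2., 5.], [3., 5.]]))


class TestPearson:
    def test_self_and_sign_flip(self):
        x = np.array([1., 2., 4., 8.])
        R = h.pearson_correlation(np.column_stack([x, x, -x]))
        assert R.entries[0, 1] == pytest.approx(1.0)
        assert R.entries[0, 2] == pytest.approx(-1.0)

    def test_matches_hand_formula(self):
        x, y = [1., 2., 3.], [2., 4., 7.]
        R = h.pearson_correlation(np.column_stack([x, y]))
        assert R.entries[0, 1] == pytest.approx(pearson_pair_oracle(x, y), abs=1e-12)


class TestKMO:
    @pytest.mark.parametrize("r", [0.3, -0.6, 0.9])
    def test_two_variable_closed_form(self, r):
        assert h.kmo(corr([[1, r], [r, 1]])) == pytest.approx(0.5, abs=1e-12)

    def test_three_by_three_matches_cofactor_oracle(self):
        R = [[1.0, 0.4, 0.2], [0.4, 1.0, -0.3], [0.2, -0.3, 1.0]]
        assert h.kmo(corr(R)) == pytest.approx(kmo_3x3_oracle(R), abs=1e-12)

    def test_bounds(self, rng):
        A = rng.normal(size=(60, 5))
        R = h.pearson_correlation(A)
        assert 0.0 < h.kmo(R) <= 1.0

    def test_identity_off_diagonals_undefined(self):
        with pytest.raises(ZeroDivisionError):
            h.kmo(corr(np.eye(4)))


class TestBartlett:
    def test_identity_gives_zero(self):
        stats = h.bartlett_sphericity(corr(np.eye(5)), n_obs=100)
        assert stats.chi2 == pytest.approx(0.0, abs=1e-12)
        assert stats.df == 10

    def test_two_by_two_closed_form(self):
        # det = 1 - r^2 = 0.75; chi2 = -(10 - 1 - 9/6) ln 0.75
        stats = h.bartlett_sphericity(corr([[1, .5], [.5, 1]]), n_obs=10)
        assert stats.chi2 == pytest.approx(-7.5 * np.log(0.75), abs=1e-12)
        assert stats.df == 1

    def test_permutation_invariance(self, output_corr):
        rng = np.random.default_rng(1)
        perm = rng.permutation(output_corr.p)
        P = output_corr.entries[np.ix_(perm, perm)]
        a = h.bartlett_sphericity(output_corr, 310).chi2
        b = h.bartlett_sphericity(corr(P), 310).chi2
        assert a == pytest.approx(b, rel=1e-12)

    def test_n_not_larger_than_p_rejected(self, output_corr):
        with pytest.raises(ValueError):
            h.bartlett_sphericity(output_corr, n_obs=11)


class TestEigendecompose:
    def test_identity_spectrum(self):
        p = h.eigendecompose(corr(np.eye(3)))
        np.testing.assert_allclose(p.eigenvalues, [1, 1, 1])

    @pytest.mark.parametrize("r", [0.25, 0.8])
    def test_two_by_two_closed_form(self, r):
        p = h.eigendecompose(corr([[1, r], [r, 1]]))
        np.testing.assert_allclose(p.eigenvalues, [1 + r, 1 - r], atol=1e-12)

    def test_trace_and_reconstruction(self, output_corr):
        p = h.eigendecompose(output_corr)
        assert p.eigenvalues.sum() == pytest.approx(output_corr.p, abs=1e-9)
        recon = (p.eigenvectors * p.eigenvalues) @ p.eigenvectors.T
        np.testing.assert_allclose(recon, output_corr.entries, atol=1e-9)
        # unit-norm eigenvectors
        np.testing.assert_allclose(np.linalg.norm(p.eigenvectors, axis=0), 1.0,
                                   atol=1e-9)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            corr([[1.0, 0.5], [0.2, 1.0]])


class TestKaiser:
    @pytest.mark.parametrize("ev,expect", [
        ([2.5, 0.5], 1),
        ([1.0, 1.0, 1.0], 0),  # strict inequality at the boundary
        ([3.066, 2.619, 2.164, 1.476, 0.569], 4),
    ])
    def test_counts(self, ev, expect):
        assert h.kaiser_select(ev) == expect

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            h.kaiser_select([])


class TestComponentScores:
    def test_identity_coefficients_return_data(self, rng):
        Z = h.zstandardize(rng.normal(size=(50, 3)))
        pca = h.eigendecompose(corr(np.eye(3)))
        np.testing.assert_allclose(h.component_scores(Z, pca, k=3), Z, atol=1e-12)

    def test_hand_matrix_product(self):
        pca = h.eigendecompose(corr([[1, .5], [.5, 1]]))
        Z = np.array([[1., -1.], [0., 2.]])
        expected = Z @ pca.eigenvectors
        np.testing.assert_allclose(h.component_scores(Z, pca, k=2), expected,
                                   atol=1e-12)

    def test_score_variance_equals_eigenvalue(self, rng):
        X = rng.normal(size=(4000, 4)) @ rng.normal(size=(4, 4))
        Z = h.zstandardize(X, ddof=0)
        R = h.pearson_correlation(Z)
        pca = h.eigendecompose(R)
        S = h.component_scores(Z, pca, k=4)
        assert np.abs(S.mean(axis=0)).max() < 1e-9
        np.testing.assert_allclose(S.var(axis=0, ddof=0), pca.eigenvalues,
                                   atol=1e-6)

    def test_k_out_of_bounds(self, rng):
        pca = h.eigendecompose(corr(np.eye(3)))
        with pytest.raises(IndexError):
            h.component_scores(np.zeros((5, 3)), pca, k=4)

    def test_coefficients_are_loadings_over_sqrt_eigenvalue(self, output_corr):
        p = h.eigendecompose(output_corr)
        np.testing.assert_allclose(
            p.score_coefficients[:, :4],
            p.loadings[:, :4] / np.sqrt(p.eigenvalues[:4]), atol=1e-12)
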