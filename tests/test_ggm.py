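import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import sqrtm

from pnnet import ggm
from pnnet.ggm import (
    precision_to_pcor,
    ridge_precision,
    sample_covariance,
    scaled_identity_target,
    select_penalty,
    sparsify_threshold,
)


def random_symmetric(rng, p, scale=1.0):
    A = rng.normal(size=(p, p)) * scale
    return 0.5 * (A + A.T)


class TestSampleCovariance:
    def test_hand_computed_small_panel(self):
        # 3x2 worked example with the ML divisor n
        panel = pd.DataFrame({"a": [1.0, 2.0, 6.0], "b": [2.0, 2.0, 5.0]})
        S = sample_covariance(panel).matrix
        xa, xb = np.array([1.0, 2.0, 6.0]), np.array([2.0, 2.0, 5.0])
        expected = np.array(
            [
                [((xa - 3) ** 2).sum() / 3, ((xa - 3) * (xb - 3)).sum() / 3],
                [((xa - 3) * (xb - 3)).sum() / 3, ((xb - 3) ** 2).sum() / 3],
            ]
        )
        np.testing.assert_allclose(S, expected)

    def test_unbiased_divisor_toggle(self):
        panel = pd.DataFrame({"a": [1.0, 2.0, 6.0]})
        ml = sample_covariance(panel, ml=True).matrix[0, 0]
        ub = sample_covariance(panel, ml=False).matrix[0, 0]
        assert ub == pytest.approx(ml * 3 / 2)

    def test_standardized_column_has_unit_variance(self, cohort_2000):
        from pnnet.preprocess import npn_transform

        z = npn_transform(cohort_2000.panel)
        S = sample_covariance(z, ml=False).matrix
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-12)

    def test_duplicated_column_gives_rank_deficiency(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        panel = pd.DataFrame({"a": x, "b": x})
        S = sample_covariance(panel).matrix
        assert np.linalg.eigvalsh(S).min() == pytest.approx(0.0, abs=1e-10)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            sample_covariance(pd.DataFrame({"a": [1.0, np.nan]}))


class TestRidgePrecision:
    @pytest.mark.parametrize("lam", [1e-4, 0.01, 0.5, 1.0, 10.0, 100.0])
    def test_identity_fixed_point(self, lam):
        est = ridge_precision(np.eye(4), lam, target="identity")
        np.testing.assert_allclose(est.matrix, np.eye(4), atol=1e-10)

    def test_small_penalty_limit_is_inverse_covariance(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(4, 4))
        S = A @ A.T + 4 * np.eye(4)  # well-conditioned
        est = ridge_precision(S, 1e-8, target="identity")
        assert np.abs(est.matrix - np.linalg.inv(S)).max() < 1e-6

    def test_matches_matrix_square_root_oracle(self):
        # brute-force evaluation of the closed form via scipy's sqrtm
        rng = np.random.default_rng(7)
        S = random_symmetric(rng, 4)
        lam, T = 0.5, np.eye(4)
        M = S - lam * T
        oracle = np.linalg.inv(sqrtm(lam * np.eye(4) + 0.25 * M @ M).real + 0.5 * M)
        est = ridge_precision(S, lam, target=T)
        np.testing.assert_allclose(est.matrix, oracle, atol=1e-10)

    @given(st.integers(0, 1000))
    @settings(max_examples=60, deadline=None)
    def test_positive_definite_for_any_symmetric_input(self, seed):
        # S may be indefinite (negative eigenvalues allowed) -- the
        # estimator must still return a positive definite matrix
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 7))
        S = random_symmetric(rng, p, scale=rng.uniform(0.1, 5.0))
        lam = 10.0 ** rng.uniform(-4, 2)
        est = ridge_precision(S, lam, target="scaled-identity" if np.trace(S) > 0 else "identity")
        assert np.linalg.eigvalsh(est.matrix).min() > 0

    def test_non_positive_penalty_rejected(self):
        with pytest.raises(ValueError, match="penalty"):
            ridge_precision(np.eye(3), 0.0)

    def test_asymmetric_covariance_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ridge_precision(np.array([[1.0, 0.5], [0.2, 1.0]]), 0.1)

    def test_scaled_identity_target(self):
        S = np.diag([1.0, 2.0, 3.0])
        T = scaled_identity_target(S)
        np.testing.assert_allclose(T, np.eye(3) * 3 / 6)

    def test_scale_consistency_of_partial_correlations(self):
        # rescaling all variables by a common factor c (S -> cS), with the
        # precision-scale target rescaled accordingly (T -> T/c) and the
        # penalty rescaled by c^2, rescales the precision by 1/c and
        # leaves the partial-correlation matrix unchanged.  (The
        # estimator is rotation- but not diagonal-scale-equivariant,
        # which is why the pipeline standardizes to unit variance before
        # estimation.)
        rng = np.random.default_rng(11)
        A = rng.normal(size=(30, 4))
        S = A.T @ A / 30
        c = 4.0
        lam = 0.3
        T = np.diag(1.0 / np.diag(S))
        est1 = ridge_precision(S, lam, target=T)
        est2 = ridge_precision(c * S, lam * c**2, target=T / c)
        np.testing.assert_allclose(est2.matrix, est1.matrix / c, atol=1e-10)
        np.testing.assert_allclose(
            precision_to_pcor(est2), precision_to_pcor(est1), atol=1e-10
        )


class TestPrecisionToPcor:
    def test_two_by_two_direct_formula(self):
        P = precision_to_pcor(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert P[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(P), 1.0)

    def test_diagonal_precision_gives_identity(self):
        P = precision_to_pcor(np.diag([2.0, 5.0, 0.3]))
        np.testing.assert_allclose(P, np.eye(3))

    def test_matches_residual_regression_oracle(self):
        # pcor(i, j | rest) == correlation of OLS residuals after
        # regressing i and j on the remaining variable
        rng = np.random.default_rng(19)
        X = rng.normal(size=(5000, 3))
        X[:, 1] += 0.6 * X[:, 0]
        X[:, 2] += 0.4 * X[:, 0] - 0.3 * X[:, 1]
        S = np.cov(X.T)
        P = precision_to_pcor(np.linalg.inv(S))
        z = X[:, 2:3]
        beta_i = np.linalg.lstsq(np.c_[np.ones(len(X)), z], X[:, 0], rcond=None)[0]
        beta_j = np.linalg.lstsq(np.c_[np.ones(len(X)), z], X[:, 1], rcond=None)[0]
        ri = X[:, 0] - np.c_[np.ones(len(X)), z] @ beta_i
        rj = X[:, 1] - np.c_[np.ones(len(X)), z] @ beta_j
        assert P[0, 1] == pytest.approx(np.corrcoef(ri, rj)[0, 1], abs=1e-10)

    def test_non_positive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            precision_to_pcor(np.array([[0.0, 0.1], [0.1, 1.0]]))


class TestSelectPenalty:
    def test_single_element_grid_returned(self, cohort_2000):
        from pnnet.preprocess import npn_transform

        z = npn_transform(cohort_2000.panel.head(100))
        assert select_penalty(z, grid=[0.7], seed=0) == 0.7

    def test_independent_data_recovers_empty_network(self):
        rng = np.random.default_rng(23)
        panel = pd.DataFrame(rng.normal(size=(800, 6)), columns=list("abcdef"))
        lam = select_penalty(panel, seed=1)
        P = precision_to_pcor(ridge_precision(sample_covariance(panel).matrix, lam))
        off = P[np.triu_indices(6, k=1)]
        assert np.abs(off).max() < 0.1

    def test_selected_penalty_beats_grid_endpoints(self):
        rng = np.random.default_rng(29)
        sigma = np.linalg.inv(synthetic_precision())
        X = rng.multivariate_normal(np.zeros(12), sigma, size=500)
        panel = pd.DataFrame(X, columns=[f"v{i}" for i in range(12)])
        lam, scores = select_penalty(panel, seed=4, return_scores=True)
        grid = ggm.default_penalty_grid()
        best = scores.max()
        assert best >= scores[0] and best >= scores[-1]
        assert lam == pytest.approx(grid[int(np.argmax(scores))])

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(31)
        panel = pd.DataFrame(rng.normal(size=(120, 5)))
        assert select_penalty(panel, seed=9) == select_penalty(panel, seed=9)

    def test_degenerate_folds_rejected(self):
        panel = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="fold count"):
            select_penalty(panel, k=10)


def synthetic_precision():
    from pnnet.synthetic import default_network

    return default_network().precision()


class TestSparsifyThreshold:
    def test_cutoff_is_inclusive(self):
        P = np.eye(3)
        P[0, 1] = P[1, 0] = 0.10
        P[0, 2] = P[2, 0] = 0.0999
        G = sparsify_threshold(P, cutoff=0.1, names=("a", "b", "c"))
        assert G.has_edge("a", "b")
        assert not G.has_edge("a", "c")

    def test_single_negative_edge_reported(self):
        P = np.eye(3)
        P[0, 1] = P[1, 0] = -0.3
        P[1, 2] = P[2, 1] = 0.5
        G = sparsify_threshold(P, names=("a", "b", "c"))
        signs = [d["sign"] for _, _, d in G.edges(data=True)]
        assert sorted(signs) == [-1, 1]
        assert G["a"]["b"]["weight"] == pytest.approx(-0.3)

    def test_no_self_loops_and_threshold_recorded(self):
        G = sparsify_threshold(np.eye(4), cutoff=0.2)
        assert G.number_of_edges() == 0
        assert G.graph["threshold"] == 0.2
        assert G.number_of_nodes() == 4

    @pytest.mark.parametrize("cutoff", [0.0, 1.0, -0.1])
    def test_invalid_cutoff_rejected(self, cutoff):
        with pytest.raises(ValueError, match="cutoff"):
            sparsify_threshold(np.eye(3), cutoff=cutoff)
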