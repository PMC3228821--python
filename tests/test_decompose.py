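import numpy as np
import pytest

from icaqtl import (
    annotate_components,
    choose_num_components,
    compute_kurtosis,
    filter_components,
    flag_individual_specific,
    run_ica,
    standardize_genes,
)
from icaqtl.containers import Decomposition, ExpressionMatrix


def std_matrix(vals):
    g, n = vals.shape
    x = ExpressionMatrix(
        vals,
        gene_ids=[f"g{i}" for i in range(g)],
        sample_ids=[f"s{j}" for j in range(n)],
        transform_state="arcsinh",
    )
    return standardize_genes(x)


def planted_rank3(seed, G=1000, N=200, share=0.10):
    """Three dense factors, each ~`share` of total variance, plus iid noise."""
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((G, 3))
    F = rng.standard_normal((3, N))
    X = L @ F * np.sqrt(share)  # each factor's variance ~ share per gene
    X += rng.standard_normal((G, N)) * np.sqrt(1 - 3 * share)
    return std_matrix(X)


class TestChooseK:
    def test_planted_rank3_recovered(self):
        for seed in range(3):
            assert choose_num_components(planted_rank3(seed), seed=seed) == 3

    def test_pure_noise_yields_zero(self):
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            x = std_matrix(rng.standard_normal((500, 120)))
            assert choose_num_components(x, seed=seed) == 0

    def test_exact_rank_one(self):
        rng = np.random.default_rng(8)
        x = std_matrix(np.outer(rng.standard_normal(300), rng.standard_normal(50)))
        assert choose_num_components(x, seed=0) == 1

    def test_requires_standardized(self, expr_factory):
        with pytest.raises(ValueError, match="standardized"):
            choose_num_components(expr_factory(np.ones((10, 10))))


class TestRunICA:
    def laplace_mix(self, seed=0, G=2000, N=150):
        # row-centred but not row-scaled: per-gene rescaling would distort
        # the planted Laplace source distribution this oracle relies on
        rng = np.random.default_rng(seed)
        S = rng.laplace(size=(G, 2))
        A = rng.standard_normal((2, N)) + np.array([[2.0], [-1.0]])
        X = S @ A + 0.05 * rng.standard_normal((G, N))
        X = X - X.mean(axis=1, keepdims=True)
        x = ExpressionMatrix(
            X,
            gene_ids=[f"g{i}" for i in range(G)],
            sample_ids=[f"s{j}" for j in range(N)],
            transform_state="standardized",
        )
        return S, x

    def test_separates_laplace_sources(self):
        S_true, x = self.laplace_mix()
        d = run_ica(x, K=2, seed=0)
        for j in range(2):
            best = max(
                abs(np.corrcoef(S_true[:, j], d.S[:, k])[0, 1]) for k in range(2)
            )
            assert best > 0.99

    def test_reconstruction_matches_rank_k_svd(self, standardized_default):
        x = standardized_default
        d = run_ica(x, K=3, seed=1)
        U, s, Vt = np.linalg.svd(x.values, full_matrices=False)
        err_svd = np.linalg.norm(x.values - (U[:, :3] * s[:3]) @ Vt[:3])
        err_ica = np.linalg.norm(x.values - d.S @ d.A)
        assert abs(err_ica - err_svd) / err_svd < 1e-6

    def test_deterministic_for_fixed_seed(self):
        _, x = self.laplace_mix(seed=3, G=500, N=60)
        d1 = run_ica(x, K=2, seed=5)
        d2 = run_ica(x, K=2, seed=5)
        assert (d1.S == d2.S).all() and (d1.A == d2.A).all()

    def test_signature_scale_and_sign_conventions(self, standardized_default):
        d = run_ica(standardized_default, K=3, seed=2)
        np.testing.assert_allclose(d.S.var(axis=0, ddof=1), 1.0, atol=1e-6)
        from scipy.stats import skew

        assert (skew(d.S, axis=0) >= -1e-10).all()

    def test_pattern_duality_regression_recovers_A(self, standardized_default):
        x = standardized_default
        d = run_ica(x, K=3, seed=1)
        A_hat, *_ = np.linalg.lstsq(d.S, x.values, rcond=None)
        np.testing.assert_allclose(A_hat, d.A, atol=1e-6)

    def test_k_bounds_checked(self, standardized_default):
        with pytest.raises(ValueError, match="K="):
            run_ica(standardized_default, K=10_000, seed=0)


class TestKurtosis:
    def test_two_point_exact(self):
        assert compute_kurtosis(np.array([1.0, -1.0] * 50)) == pytest.approx(-2.0)

    def test_gaussian_near_zero(self):
        rng = np.random.default_rng(10)
        assert abs(compute_kurtosis(rng.standard_normal(100_000))) < 0.1

    def test_laplace_near_three(self):
        rng = np.random.default_rng(11)
        assert compute_kurtosis(rng.laplace(size=100_000)) == pytest.approx(3.0, abs=0.2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            compute_kurtosis(np.ones(10))


class TestIndividualSpecific:
    def test_single_dominant_individual_flagged(self):
        a = np.zeros(100)
        a[0] = 10.0
        flag, share = flag_individual_specific(a)
        assert flag and share == pytest.approx(98.01 / 99.0)

    def test_iid_pattern_not_flagged(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            assert not flag_individual_specific(rng.standard_normal(1490))[0]

    def test_share_exactly_at_threshold_not_flagged(self):
        a = np.array([1.0] * 5 + [-1.0] * 5)  # every share exactly 0.10
        flag, share = flag_individual_specific(a)
        assert share == pytest.approx(0.10) and not flag


class TestFilterComponents:
    def make_decomp(self, S, A):
        g, k = S.shape
        return Decomposition(
            S=S,
            A=A,
            gene_ids=[f"g{i}" for i in range(g)],
            sample_ids=[f"s{j}" for j in range(A.shape[1])],
            component_ids=[f"IC{j + 1}" for j in range(k)],
        )

    def test_gaussian_components_all_dropped(self):
        rng = np.random.default_rng(12)
        d = self.make_decomp(rng.standard_normal((5000, 2)), rng.standard_normal((2, 50)))
        with pytest.warns(UserWarning, match="all components removed"):
            out = filter_components(d)
        assert out.K == 0

    def test_sparse_signature_retained(self):
        rng = np.random.default_rng(13)
        S = rng.standard_normal((5000, 1)) * 0.1
        S[:50, 0] = 8.0
        d = self.make_decomp(S, rng.standard_normal((1, 500)))
        assert filter_components(d).K == 1

    def test_individual_specific_flag_takes_precedence(self):
        rng = np.random.default_rng(14)
        S = rng.standard_normal((5000, 1)) * 0.1
        S[:50, 0] = 8.0  # high kurtosis
        A = np.zeros((1, 50))
        A[0, 0] = 5.0
        A[0, 1:] = 0.01 * rng.standard_normal(49)
        d = self.make_decomp(S, A)
        d = annotate_components(d)
        assert d.kurtosis[0] > 3 and d.individual_specific[0]
        assert filter_components(d).K == 0

    def test_raw_kurtosis_scale_option(self):
        rng = np.random.default_rng(15)
        S = rng.standard_t(df=10, size=(20000, 1))  # excess ~1, raw ~4
        A = rng.standard_normal((1, 500))
        assert filter_components(self.make_decomp(S, A), kurtosis_scale="raw").K == 1
        with pytest.warns(UserWarning, match="all components removed"):
            out = filter_components(self.make_decomp(S, A), kurtosis_scale="excess")
        assert out.K == 0
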