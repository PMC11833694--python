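import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import minimize_scalar

from elongrate.core_io import TranscriptionUnit
from elongrate.features import FeatureMatrix, standardize
from elongrate import glm
from elongrate.glm import FitConfig, SeqBias


def one_gene(counts, Y, name="g0"):
    counts = np.asarray(counts, dtype=float)
    tu = TranscriptionUnit(name, "c", "+", 0, counts.size, counts=counts)
    fm = FeatureMatrix(
        names=[f"f{i}" for i in range(Y.shape[1])], raw=[np.asarray(Y, float)]
    )
    return [tu], fm


class TestLogLikelihood:
    def test_hand_evaluated_value(self):
        # X=[1,0], kappa=0 (zeta=1), chi=1: 1*log1 - 0 - 1*2 = -2
        tus, fm = one_gene([1, 0], np.zeros((2, 1)))
        assert glm.log_likelihood(tus, fm, np.zeros(1), np.array([1.0])) == -2.0

    def test_kappa_zero_optimum_is_s_over_N(self, rng):
        # with zeta = 1 the objective s log(chi) - chi*N peaks at chi = s/N
        x = rng.poisson(2.0, size=100).astype(float)
        x[0] = max(x[0], 1)
        tus, fm = one_gene(x, np.zeros((100, 1)))
        s, N = x.sum(), 100.0
        grid = np.linspace(0.2, 5, 2001) * s / N
        vals = [
            glm.log_likelihood(tus, fm, np.zeros(1), np.array([c])) for c in grid
        ]
        assert grid[int(np.argmax(vals))] == pytest.approx(s / N, rel=2e-3)

    def test_doubling_counts_shifts_optimum_chi(self, rng):
        x = rng.poisson(2.0, size=50).astype(float)
        x[0] = max(x[0], 1)

        def argmax_chi(counts):
            tus, fm = one_gene(counts, np.zeros((counts.size, 1)))
            res = minimize_scalar(
                lambda c: -glm.log_likelihood(
                    tus, fm, np.zeros(1), np.array([c])
                ),
                bounds=(1e-6, 50),
                method="bounded",
            )
            return res.x

        assert argmax_chi(2 * x) == pytest.approx(2 * argmax_chi(x), rel=1e-4)

    def test_nonpositive_chi_rejected(self):
        tus, fm = one_gene([1, 0], np.zeros((2, 1)))
        with pytest.raises(ValueError, match="chi"):
            glm.log_likelihood(tus, fm, np.zeros(1), np.array([0.0]))

    def test_masked_sites_excluded(self, rng):
        x = np.array([5.0, 1.0, 1.0, 9.0])
        Y = rng.normal(size=(4, 2))
        tus, fm = one_gene(x, Y)
        tus[0].mask = np.array([True, True, True, False])
        tus2, fm2 = one_gene(x[:3], Y[:3])
        k = np.array([0.3, -0.2])
        assert glm.log_likelihood(tus, fm, k, np.array([1.3])) == pytest.approx(
            glm.log_likelihood(tus2, fm2, k, np.array([1.3]))
        )


class TestGradient:
    @pytest.mark.parametrize("nu", [0.0, 3.0])
    def test_matches_central_finite_differences(self, rng, nu):
        M, N, F = 3, 60, 4
        tus, blocks = [], []
        for j in range(M):
            Y = rng.normal(size=(N, F))
            x = rng.poisson(1.5, size=N).astype(float)
            x[0] = max(x[0], 1)
            tus.append(
                TranscriptionUnit(f"g{j}", "c", "+", j * N, (j + 1) * N, counts=x)
            )
            blocks.append(Y)
        fm = FeatureMatrix(names=[f"f{i}" for i in range(F)], raw=blocks)
        for _ in range(5):
            kappa = rng.normal(scale=0.2, size=F)  # off the |k|=0 kinks
            chi = rng.uniform(0.5, 2.0, size=M)
            g = glm.gradient_kappa(tus, fm, kappa, chi, nu=nu)
            eps = 1e-6
            for n in range(F):
                kp, km = kappa.copy(), kappa.copy()
                kp[n] += eps
                km[n] -= eps
                fd = (
                    glm.log_likelihood(tus, fm, kp, chi, nu=nu)
                    - glm.log_likelihood(tus, fm, km, chi, nu=nu)
                ) / (2 * eps)
                assert abs(g[n] - fd) <= 1e-5 * max(abs(fd), 1.0)

    def test_l1_shrinks_gradient_by_nu_for_positive_kappa(self, rng):
        tus, fm = one_gene(
            rng.poisson(1.0, 50).astype(float) + 1, rng.normal(size=(50, 2))
        )
        kappa = np.array([0.4, 0.2])
        chi = np.array([1.0])
        g0 = glm.gradient_kappa(tus, fm, kappa, chi, nu=0.0)
        g5 = glm.gradient_kappa(tus, fm, kappa, chi, nu=5.0)
        np.testing.assert_allclose(g0 - g5, 5.0)


class TestUpdateChi:
    def test_direct_value(self):
        assert glm.update_chi(100.0, 1.0, 50.0) == 2.0

    def test_zero_counts_give_zero_chi(self):
        assert glm.update_chi(0.0, 1.0, 10.0) == 0.0

    def test_matches_golden_section_maximization(self):
        s, lam, U = 150.0, 0.8, 12_000.0
        res = minimize_scalar(
            lambda c: -(s * np.log(c) - lam * c * U),
            bracket=(1e-4, 0.01, 10.0),
            method="golden",
            options={"xtol": 1e-12},
        )
        assert glm.update_chi(s, lam, U) == pytest.approx(res.x, abs=1e-8)

    def test_nonpositive_U_rejected(self):
        with pytest.raises(ValueError, match="U_j"):
            glm.update_chi(1.0, 1.0, 0.0)


class TestSparseSufficientStats:
    def test_matches_dense_oracle(self, rng):
        blocks = [
            sp.random(1000, 10, density=0.03, format="csr", rng=rng)
            for _ in range(4)
        ]
        means = rng.uniform(0.005, 0.05, 10)
        sds = rng.uniform(0.05, 0.3, 10)
        kappa = rng.normal(scale=0.2, size=10)
        U, V = glm.sufficient_stats_sparse(blocks, means, sds, kappa)
        for j, b in enumerate(blocks):
            Y = (b.toarray() - means) / sds
            w = np.exp(-(Y @ kappa))
            assert abs(U[j] - w.sum()) < 1e-10 * w.sum()
            np.testing.assert_allclose(V[j], w @ Y, atol=1e-9)

    def test_all_zero_column_closed_form(self):
        # a feature absent from a gene contributes Y = -mean/sd everywhere
        block = sp.csr_matrix((100, 1))
        means, sds = np.array([0.1]), np.array([0.3])
        kappa = np.array([0.5])
        U, V = glm.sufficient_stats_sparse([block], means, sds, kappa)
        y = -means[0] / sds[0]
        w = np.exp(-kappa[0] * y)
        assert U[0] == pytest.approx(100 * w)
        assert V[0, 0] == pytest.approx(100 * w * y)

    def test_kappa_zero_gives_U_equal_N(self, rng):
        block = sp.random(500, 5, density=0.02, format="csr", rng=rng)
        U, _ = glm.sufficient_stats_sparse(
            [block], np.full(5, 0.02), np.full(5, 0.1), np.zeros(5)
        )
        assert U[0] == pytest.approx(500.0)


class TestFit:
    def test_recovers_kappa_on_model_data(self, small_glm_data):
        tus, fm, kappa_true = small_glm_data
        res = glm.fit(tus, fm, FitConfig(tol=1e-7, max_iter=20000))
        assert res.converged
        np.testing.assert_allclose(res.kappa, kappa_true, atol=0.08)

    def test_objective_trace_monotone_and_improves_on_init(self, small_glm_data):
        tus, fm, _ = small_glm_data
        res = glm.fit(tus, fm, FitConfig(tol=1e-7, max_iter=20000))
        trace = res.objective_trace
        assert np.all(np.diff(trace) >= -1e-9)
        assert trace[-1] >= trace[0]

    def test_zero_feature_model_recovers_mean_depth_chi(self, rng):
        # with no features zeta = 1, so chi_j = s_j / (lam * N_j)
        x = rng.poisson(2.0, size=200).astype(float)
        x[0] = max(x[0], 1)
        tu = TranscriptionUnit("g", "c", "+", 0, 200, counts=x)
        fm = FeatureMatrix(names=[], raw=[np.zeros((200, 0))])
        res = glm.fit([tu], fm, FitConfig(max_iter=5))
        assert res.chi[0] == pytest.approx(x.sum() / (res.lam * 200))

    def test_chi_coordinatewise_optimal_after_fit(self, small_glm_data):
        tus, fm, _ = small_glm_data
        res = glm.fit(tus, fm, FitConfig(tol=1e-7, max_iter=20000))
        base = glm.log_likelihood(tus, fm, res.kappa, res.chi, lam=res.lam)
        for j in range(len(res.chi)):
            for factor in (0.99, 1.01):
                chi = res.chi.copy()
                chi[j] *= factor
                assert glm.log_likelihood(tus, fm, res.kappa, chi, lam=res.lam) < base

    def test_first_order_conditions_at_convergence(self, small_glm_data):
        tus, fm, _ = small_glm_data
        res = glm.fit(tus, fm, FitConfig(tol=1e-9, max_iter=50000))
        g = glm.gradient_kappa(tus, fm, res.kappa, res.chi, lam=res.lam)
        # gradient scaled by the data size should be near zero at optimum
        total = sum(t.counts.sum() for t in tus)
        assert np.max(np.abs(g)) / total < 1e-4

    def test_constant_feature_shift_absorbed_by_standardization(self, rng):
        M, N = 3, 300
        kappa_true = np.array([-0.1])
        tus, blocks, shifted = [], [], []
        for j in range(M):
            Y = rng.normal(size=(N, 1))
            x = rng.poisson(np.exp(-Y[:, 0] * kappa_true[0]) * 1.5).astype(float)
            x[0] = max(x[0], 1)
            tus.append(
                TranscriptionUnit(f"g{j}", "c", "+", j * N, (j + 1) * N, counts=x)
            )
            blocks.append(Y)
            shifted.append(Y + 7.3)
        fit_a = glm.fit(
            tus, standardize(FeatureMatrix(names=["f"], raw=blocks)),
            FitConfig(tol=1e-8),
        )
        fit_b = glm.fit(
            tus, standardize(FeatureMatrix(names=["f"], raw=shifted)),
            FitConfig(tol=1e-8),
        )
        np.testing.assert_allclose(fit_a.kappa, fit_b.kappa, atol=1e-6)

    def test_fixed_lr_divergence_raises(self, small_glm_data):
        tus, fm, _ = small_glm_data
        with pytest.raises(RuntimeError, match="learning rate"):
            glm.fit(tus, fm, FitConfig(learning_rate=10.0, adapt_lr=False))


class TestSelectNu:
    def _kmer_like_data(self, rng, M=12, N=800, F=30, n_true=5):
        kappa_raw = np.zeros(F)
        true = rng.choice(F, n_true, replace=False)
        kappa_raw[true] = rng.uniform(0.2, 0.4, n_true) * rng.choice([-1, 1], n_true)
        tus, blocks = [], []
        for j in range(M):
            raw = np.zeros((N, F))
            raw[np.arange(N), rng.integers(0, F, N)] = 1.0
            zeta = np.exp(raw @ kappa_raw)
            x = rng.poisson(2.0 / zeta).astype(float)
            x[0] = max(x[0], 1)
            tus.append(
                TranscriptionUnit(f"g{j}", "c", "+", j * N, (j + 1) * N, counts=x)
            )
            blocks.append(sp.csr_matrix(raw))
        fm = standardize(
            FeatureMatrix(names=[f"m{i}" for i in range(F)], raw=blocks)
        )
        return tus, fm, set(f"m{i}" for i in true)

    def test_huge_nu_gives_empty_model(self, rng):
        tus, fm, _ = self._kmer_like_data(rng)
        nu, f = glm.select_nu(
            tus, fm, [1e9], FitConfig(penalty="l1", max_iter=200), seed=0
        )
        assert f.nonzero_count() == 0

    def test_seeded_split_is_reproducible(self, rng):
        tus, fm, _ = self._kmer_like_data(rng)
        grid = glm.default_nu_grid(tus, 3)
        nu1, f1 = glm.select_nu(
            tus, fm, grid, FitConfig(penalty="l1", max_iter=500), seed=7
        )
        nu2, f2 = glm.select_nu(
            tus, fm, grid, FitConfig(penalty="l1", max_iter=500), seed=7
        )
        assert nu1 == nu2
        np.testing.assert_array_equal(f1.kappa, f2.kappa)

    def test_recovers_true_support_on_easy_data(self, rng):
        tus, fm, true_names = self._kmer_like_data(rng)
        grid = glm.default_nu_grid(tus, 5)
        _, f = glm.select_nu(
            tus, fm, grid, FitConfig(penalty="l1", max_iter=2000, tol=1e-7), seed=0
        )
        picked = set(f.nonzero_features())
        assert len(picked & true_names) >= len(true_names) - 1

    def test_empty_grid_rejected(self, rng):
        tus, fm, _ = self._kmer_like_data(rng, M=6)
        with pytest.raises(ValueError, match="empty"):
            glm.select_nu(tus, fm, [])


class TestSequenceBias:
    def test_uniform_pi_collapses_to_unbiased_bit_for_bit(self, rng):
        x = rng.poisson(1.0, 40).astype(float)
        x[0] = max(x[0], 1)
        Y = rng.normal(size=(40, 2))
        tus, fm = one_gene(x, Y)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
        kappa = np.array([0.1, -0.2])
        chi = np.array([1.2])
        plain = glm.log_likelihood(tus, fm, kappa, chi)
        biased = glm.log_likelihood_biased(
            tus, fm, kappa, chi, SeqBias(np.full(4, 0.25)), [seq]
        )
        assert biased == plain  # exact equality

    def test_rho_is_four_pi_with_offsets(self):
        sb = SeqBias(np.array([0.2, 0.4, 0.2, 0.2]))
        np.testing.assert_allclose(sb.rho, [0.8, 1.6, 0.8, 0.8])
        track = sb.log_rho_track("CAN")
        assert track[0] == pytest.approx(np.log(1.6))
        assert track[1] == pytest.approx(np.log(0.8))
        assert track[2] == 0.0

    def test_estimate_rho_weights_by_read_counts(self):
        tu = TranscriptionUnit(
            "g", "c", "+", 0, 4, counts=np.array([2.0, 1.0, 0.0, 1.0])
        )
        sb = glm.estimate_rho([tu], ["ACGT"])
        np.testing.assert_allclose(sb.pi, [0.5, 0.25, 0.0, 0.25])

    def test_nonuniform_bias_changes_objective(self, rng):
        x = rng.poisson(1.0, 40).astype(float)
        x[0] = max(x[0], 1)
        tus, fm = one_gene(x, rng.normal(size=(40, 2)))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 40)])
        kappa = np.array([0.1, -0.2])
        chi = np.array([1.2])
        plain = glm.log_likelihood(tus, fm, kappa, chi)
        biased = glm.log_likelihood_biased(
            tus, fm, kappa, chi, SeqBias(np.array([0.1, 0.4, 0.1, 0.4])), [seq]
        )
        assert biased != plain


class TestFitBatches:
    def test_single_batch_has_no_se(self, small_glm_data):
        tus, fm, _ = small_glm_data
        res = glm.fit_batches(
            tus, fm, FitConfig(max_iter=2000), n_batches=1, batch_size=3, seed=0
        )
        assert res.se is None

    def test_identical_batches_give_zero_se(self, small_glm_data):
        tus, fm, _ = small_glm_data
        res = glm.fit_batches(
            tus, fm, FitConfig(max_iter=2000, tol=1e-7),
            n_batches=3, batch_size=len(tus), seed=0,
        )
        np.testing.assert_allclose(res.se, 0.0, atol=1e-12)

    def test_oversized_batch_rejected(self, small_glm_data):
        tus, fm, _ = small_glm_data
        with pytest.raises(ValueError, match="batch size"):
            glm.fit_batches(tus, fm, n_batches=2, batch_size=99)


class TestPredictZeta:
    def test_kappa_zero_gives_unit_rates(self, small_glm_data):
        _, fm, _ = small_glm_data
        for z in glm.predict_zeta(np.zeros(fm.n_features), fm):
            np.testing.assert_array_equal(z, 1.0)

    def test_single_standardized_unit_value(self):
        fm = FeatureMatrix(
            names=["f"], raw=[np.array([[1.0], [0.0]])],
            means=np.array([0.0]), sds=np.array([1.0]),
        )
        z = glm.predict_zeta(np.array([-0.2]), fm)[0]
        assert z[0] == pytest.approx(np.exp(-0.2))
        assert z[1] == pytest.approx(1.0)

    def test_monotone_in_positively_weighted_feature(self):
        vals = np.linspace(-2, 2, 9).reshape(-1, 1)
        fm = FeatureMatrix(names=["f"], raw=[vals])
        z = glm.predict_zeta(np.array([0.3]), fm)[0]
        assert np.all(np.diff(z) > 0)

    def test_sparse_and_dense_paths_agree(self, rng):
        dense = (rng.random((100, 6)) < 0.2).astype(float)
        kappa = rng.normal(scale=0.2, size=6)
        fm_d = standardize(FeatureMatrix(names=list("abcdef"), raw=[dense]))
        fm_s = standardize(
            FeatureMatrix(names=list("abcdef"), raw=[sp.csr_matrix(dense)])
        )
        np.testing.assert_allclose(
            glm.predict_zeta(kappa, fm_d)[0],
            glm.predict_zeta(kappa, fm_s)[0],
            rtol=1e-10,
        )
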