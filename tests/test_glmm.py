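import warnings

import numpy as np
import pytest
from scipy.special import expit

from panglmm.glmm import PangenomeGLMM, _irls_logistic, fit_null_model, training_auc
from panglmm.grm import RelatednessMatrix, compute_grm

from conftest import make_trait


class TestLogitLink:
    def test_unstructured_trait_gives_small_tau_and_glm_alpha(self, null_dataset):
        """Trait independent of the pangenome: tau ~ 0 and fixed effects
        agree with a plain logistic regression."""
        G, T, _, Psi = null_dataset
        fit = PangenomeGLMM(T, Psi).fit()
        assert fit.converged
        assert fit.tau < 0.5
        alpha_glm, _ = _irls_logistic(T.X, T.y)
        assert np.allclose(fit.alpha, alpha_glm, atol=0.3)

    def test_tau_zero_matches_logistic_irls(self, null_dataset):
        G, T, _, Psi = null_dataset
        fit = PangenomeGLMM(T, Psi).fit(tau0=0.0, fix_tau=True, tol=1e-10, max_iter=200)
        alpha_glm, _ = _irls_logistic(T.X, T.y, max_iter=100, tol=1e-12)
        assert np.allclose(fit.alpha, alpha_glm, atol=1e-6)
        assert np.allclose(fit.b, 0.0)

    def test_structured_trait_gives_positive_tau(self, structured_dataset):
        G, T, strain, Psi = structured_dataset
        fit = PangenomeGLMM(T, Psi).fit()
        assert fit.tau > 0.5
        # random effects track the strain that drives the trait
        assert abs(np.corrcoef(fit.b, strain)[0, 1]) > 0.5

    def test_sample_permutation_invariance(self, structured_dataset):
        G, T, _, Psi = structured_dataset
        fit = PangenomeGLMM(T, Psi).fit()
        rng = np.random.default_rng(5)
        perm = rng.permutation(T.n_samples)
        Tp = T.take_samples(perm)
        Psip = Psi.take_samples(perm)
        fitp = PangenomeGLMM(Tp, Psip).fit()
        assert fitp.tau == pytest.approx(fit.tau, rel=1e-6)
        assert np.allclose(fitp.b, fit.b[perm], atol=1e-6)

    def test_mu_in_unit_interval_and_projection_annihilates_X(self, structured_dataset):
        G, T, _, Psi = structured_dataset
        fit = PangenomeGLMM(T, Psi).fit()
        assert np.all((fit.mu > 0) & (fit.mu < 1))
        PX = np.column_stack([fit.apply_P(T.X[:, j]) for j in range(T.X.shape[1])])
        assert np.abs(PX).max() < 1e-8

    def test_misaligned_ids_rejected(self, structured_dataset):
        G, T, _, Psi = structured_dataset
        bad = RelatednessMatrix(Psi.sample_ids[::-1].copy(), Psi.values)
        with pytest.raises(ValueError, match="align"):
            PangenomeGLMM(T, bad)


class TestIdentityLink:
    def _block_grm(self, n=120, m=12):
        vals = np.zeros((n, n))
        rhos = np.linspace(0.2, 0.9, n // m)
        for k, rho in enumerate(rhos):
            vals[k * m:(k + 1) * m, k * m:(k + 1) * m] = rho
        np.fill_diagonal(vals, 1.0)
        ids = np.array([f"s{i}" for i in range(n)], dtype=object)
        return RelatednessMatrix(ids, vals)

    def test_recovers_variance_components(self):
        Psi = self._block_grm()
        n = Psi.n_samples
        rng = np.random.default_rng(4)
        L = np.linalg.cholesky(Psi.values + 1e-10 * np.eye(n))
        taus, s2s = [], []
        x = rng.normal(size=n)
        for _ in range(20):
            y = 1.0 + 0.5 * x + np.sqrt(2.0) * (L @ rng.normal(size=n)) \
                + rng.normal(size=n)
            T = make_trait(Psi.sample_ids, y, x, kind="quantitative")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = PangenomeGLMM(T, Psi).fit(tol=1e-6, max_iter=200)
            taus.append(fit.tau)
            s2s.append(fit.sigma2)
        assert np.mean(taus) == pytest.approx(2.0, abs=0.6)
        assert np.mean(s2s) == pytest.approx(1.0, abs=0.3)

    def test_identity_grm_aliasing_splits_total_variance(self):
        """With Psi = I, tau and sigma2 are only identified through their
        sum; the fit still converges and the sum matches total variance."""
        n = 150
        ids = np.array([f"s{i}" for i in range(n)], dtype=object)
        rng = np.random.default_rng(8)
        y = rng.normal(0, np.sqrt(3.0), size=n)
        T = make_trait(ids, y, kind="quantitative")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = PangenomeGLMM(T, RelatednessMatrix(ids, np.eye(n))).fit(max_iter=200)
        assert fit.tau + fit.sigma2 == pytest.approx(np.var(y, ddof=1), rel=0.2)


class TestTrainingAuc:
    def test_perfect_separation_and_anticoncordance(self, rng):
        n = 40
        ids = [f"s{i}" for i in range(n)]
        y = np.array([0] * 20 + [1] * 20, dtype=float)
        T = make_trait(ids, y)
        Psi = RelatednessMatrix(np.asarray(ids, dtype=object), np.eye(n))
        fit = PangenomeGLMM(T, Psi).fit()
        fit.eta = np.arange(n, dtype=float)          # perfect separator
        assert fit.training_auc() == pytest.approx(1.0)
        fit.eta = -np.arange(n, dtype=float)
        assert fit.training_auc() == pytest.approx(0.0)

    def test_random_predictor_near_half(self, rng):
        n = 2000
        ids = np.array([f"s{i}" for i in range(n)], dtype=object)
        y = rng.binomial(1, 0.5, n).astype(float)
        eta = rng.normal(size=n)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, eta) == pytest.approx(0.5, abs=0.05)

    def test_single_class_errors(self):
        n = 10
        ids = [f"s{i}" for i in range(n)]
        T = make_trait(ids, np.zeros(n) + 1.0)
        with pytest.raises(Exception):
            PangenomeGLMM(T, RelatednessMatrix(np.asarray(ids, dtype=object),
                                               np.eye(n))).fit().training_auc()
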