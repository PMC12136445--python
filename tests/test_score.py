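import warnings
from itertools import product
from math import comb

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import norm

from panglmm.glmm import PangenomeGLMM
from panglmm.grm import RelatednessMatrix
from panglmm.io import PangenomeMatrix
from panglmm.score import (
    _spa_one_tail,
    associations_to_frame,
    glm_baseline_gene,
    run_beta_tests,
    run_glm_baseline,
    score_test_gene,
    spa_pvalue,
)

from conftest import make_trait


class TestScoreTestGene:
    def test_constant_gene_untestable(self, null_dataset):
        G, T, _, Psi = null_dataset
        fit = PangenomeGLMM(T, Psi).fit()
        a = score_test_gene(fit, np.ones(T.n_samples))
        assert a.untestable and a.p_value == 1.0

    def test_covariate_collinear_gene_null(self, rng):
        """A gene identical to a covariate carries no extra information:
        the adjustment annihilates it."""
        n = 80
        ids = np.array([f"s{i}" for i in range(n)], dtype=object)
        g = rng.binomial(1, 0.5, n).astype(float)
        y = rng.binomial(1, 0.5, n).astype(float)
        T = make_trait(ids, y, extra_cov=g)
        fit = PangenomeGLMM(T, RelatednessMatrix(ids, np.eye(n))).fit()
        a = score_test_gene(fit, g)
        assert a.untestable or a.p_value > 0.99

    def test_batch_matches_single_and_is_deterministic(self, structured_dataset):
        G, T, _, Psi = structured_dataset
        fit = PangenomeGLMM(T, Psi).fit()
        sub = PangenomeMatrix(G.sample_ids, G.gene_ids[:30], G.values[:, :30])
        batch = run_beta_tests(fit, sub)
        for j in [0, 7, 29]:
            single = score_test_gene(fit, sub.values[:, j].astype(float))
            assert batch[j].p_value == pytest.approx(single.p_value, rel=1e-10)
            assert batch[j].beta_hat == pytest.approx(single.beta_hat, rel=1e-10)
        # identical columns give identical results
        dup = PangenomeMatrix(G.sample_ids, np.array(["a", "b"], dtype=object),
                              np.repeat(G.values[:, [5]], 2, axis=1))
        r = run_beta_tests(fit, dup)
        assert r[0].p_value == r[1].p_value

    def test_effect_sign_matches_presence_difference(self, structured_dataset):
        G, T, strain, Psi = structured_dataset
        fit = PangenomeGLMM(T, Psi).fit()
        # construct a gene enriched in cases
        g = ((T.y == 1) & (np.arange(len(T.y)) % 3 != 0)).astype(float)
        a = score_test_gene(fit, g)
        assert a.beta_hat > 0
        assert np.sign(a.z_signed) == np.sign(a.beta_hat)

    def test_signed_z_matches_p(self, structured_dataset):
        G, T, _, Psi = structured_dataset
        fit = PangenomeGLMM(T, Psi).fit()
        a = score_test_gene(fit, G.values[:, 850].astype(float))
        if not a.untestable:
            expected = np.sign(a.beta_hat) * norm.isf(a.p_value / 2.0)
            assert a.z_signed == pytest.approx(expected)


class TestSpa:
    def test_zero_score_gives_one(self):
        mu = np.full(12, 0.5)
        g = np.array([1.0] * 6 + [0.0] * 6)
        var = float(np.sum(g * g * mu * (1 - mu)))
        assert spa_pvalue(g, mu, 0.0, var) == 1.0

    def test_six_carrier_enumeration(self):
        """Exhaustive 2^12 oracle: SPA tails within 10% relative error."""
        mu = np.full(12, 0.5)
        g = np.array([1.0] * 6 + [0.0] * 6)
        for s in [1.0, 2.0, 3.0]:
            exact_up = sum(comb(6, k) for k in range(7) if k - 3 >= s) / 64
            p, ok = _spa_one_tail(g, mu, s)
            assert ok
            assert p == pytest.approx(exact_up, rel=0.10)

    def test_random_configs_enumeration(self):
        rng = np.random.default_rng(3)
        checked = 0
        ys = np.array(list(product([0, 1], repeat=12)), dtype=float)
        for _ in range(10):
            mu = rng.uniform(0.1, 0.9, 12)
            g = rng.integers(0, 2, 12).astype(float)
            if g.sum() in (0, 12):
                continue
            probs = np.prod(np.where(ys == 1, mu, 1 - mu), axis=1)
            S = ys @ g - mu @ g
            for k in range(int(g.sum()) + 1):
                s = k - float(mu @ g)
                if s <= 0.5:
                    continue
                exact = probs[S >= s - 1e-9].sum()
                if not (1e-5 < exact < 0.25):
                    continue
                p, ok = _spa_one_tail(g, mu, s)
                assert ok
                assert p == pytest.approx(exact, rel=0.10)
                checked += 1
        assert checked >= 10

    def test_spa_approaches_normal_when_balanced(self):
        """With balanced fitted means and many carriers the saddlepoint and
        normal approximations coincide."""
        rng = np.random.default_rng(1)
        n = 5000
        mu = np.full(n, 0.5)
        g = rng.normal(size=n)          # non-lattice
        var = float(np.sum(g * g * 0.25))
        s = 2.5 * np.sqrt(var)
        p_spa = spa_pvalue(g, mu, s, var)
        p_norm = 2 * norm.sf(2.5)
        assert p_spa == pytest.approx(p_norm, rel=0.02)

    def test_imbalanced_spa_larger_than_normal(self):
        """Rare gene, few cases: the normal tail is anti-conservative and
        SPA corrects it upward."""
        rng = np.random.default_rng(2)
        n = 500
        mu = np.concatenate([np.full(50, 0.5), np.full(450, 0.05)])
        g = (rng.uniform(size=n) < 0.04).astype(float)
        g_adj = g - g.mean()
        var = float(np.sum(g_adj ** 2 * mu * (1 - mu)))
        s = 3.5 * np.sqrt(var)
        p_spa = spa_pvalue(g_adj, mu, s, var)
        p_norm = 2 * norm.sf(3.5)
        assert p_spa > p_norm


class TestGlmBaseline:
    def test_two_by_two_table_log_odds(self):
        """y x g counts [[30,10],[10,30]] has odds ratio 9."""
        y = np.array([0] * 40 + [1] * 40, dtype=float)
        g = np.array([0] * 30 + [1] * 10 + [0] * 10 + [1] * 30, dtype=float)
        ids = [f"s{i}" for i in range(80)]
        T = make_trait(ids, y)
        a = glm_baseline_gene(T, g)
        assert a.beta_hat == pytest.approx(np.log(9.0), abs=1e-3)

    def test_constant_gene_untestable(self):
        T = make_trait([f"s{i}" for i in range(20)],
                       np.r_[np.zeros(10), np.ones(10)])
        assert glm_baseline_gene(T, np.ones(20)).untestable

    def test_matches_statsmodels_wald(self, rng):
        n = 150
        ids = np.array([f"s{i}" for i in range(n)], dtype=object)
        x = rng.normal(size=n)
        g = rng.binomial(1, 0.4, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.2 + 0.5 * g - 0.3 * x)))).astype(float)
        T = make_trait(ids, y, extra_cov=x)
        a = glm_baseline_gene(T, g)
        Xf = np.column_stack([T.X, g])
        ref = sm.GLM(y, Xf, family=sm.families.Binomial()).fit()
        assert a.beta_hat == pytest.approx(ref.params[-1], abs=1e-5)
        assert a.p_value == pytest.approx(ref.pvalues[-1], abs=1e-5)

    def test_unstructured_data_glm_and_mixed_agree(self, rng):
        n = 200
        ids = np.array([f"s{i}" for i in range(n)], dtype=object)
        g = rng.binomial(1, 0.5, n).astype(float)
        y = rng.binomial(1, 0.5, n).astype(float)
        T = make_trait(ids, y)
        fit = PangenomeGLMM(T, RelatednessMatrix(ids, np.eye(n))).fit(
            tau0=0.0, fix_tau=True, tol=1e-10)
        a_mixed = score_test_gene(fit, g, spa_z_trigger=np.inf)
        a_glm = glm_baseline_gene(T, g)
        assert a_mixed.p_value == pytest.approx(a_glm.p_value, abs=0.02)

    def test_frame_export(self, structured_dataset):
        G, T, _, Psi = structured_dataset
        fit = PangenomeGLMM(T, Psi).fit()
        sub = PangenomeMatrix(G.sample_ids, G.gene_ids[:10], G.values[:, :10])
        df = associations_to_frame(run_beta_tests(fit, sub))
        assert set(["p_value", "beta_hat", "z_signed", "spa_used"]) <= set(df.columns)
        assert len(df) == 10
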