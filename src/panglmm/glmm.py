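"""Generalized linear mixed model with a relatedness-structured random effect.

The null ("strain") model for a host trait y is

    E[f(y)] = X alpha + b,      b ~ N(0, tau * Psi)

with f the logit link for binary traits or the identity link for
quantitative traits, X the covariate matrix and Psi the species
relatedness matrix.  The variance component tau measures how strongly the
species' population structure tracks the trait.  Fitting follows the
GMMAT/SAIGE recipe: penalized quasi-likelihood linearization to a working
linear mixed model, with average-information REML updates for the
variance components.

The model object is constructed from data and ``fit()`` returns a results
object carrying the estimates, cached projection factors for downstream
per-gene score tests, and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotrf, dpotri
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .grm import RelatednessMatrix
from .io import TraitTable

__all__ = ["PangenomeGLMM", "GLMMResults", "fit_null_model", "training_auc"]

_MU_EPS = 1e-8


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-10):
    """Plain logistic regression by IRLS with a tiny ridge for stability.

    Returns (alpha, separated) where ``separated`` flags quasi-separation
    (unbounded coefficients); in that case the ridge-penalized solution at
    the last stable iteration is returned.
    """
    n, q = X.shape
    alpha = np.zeros(q)
    alpha[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    separated = False
    for _ in range(max_iter):
        eta = X @ alpha
        mu = expit(eta)
        mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
        w = mu * (1 - mu)
        XtWX = (X * w[:, None]).T @ X + 1e-8 * np.eye(q)
        step = np.linalg.solve(XtWX, X.T @ (y - mu))
        alpha = alpha + step
        # quasi-separation: diverging predictor that classifies perfectly
        if np.abs(eta).max() > 12 and np.all((eta > 0) == (y == 1)):
            separated = True
            break
        if np.abs(step).max() < tol:
            break
    return alpha, separated


def _sym_inv(V: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive definite matrix via Cholesky."""
    c, info = dpotrf(V, lower=1, overwrite_a=0)
    if info != 0:
        raise np.linalg.LinAlgError(f"covariance not positive definite (info={info})")
    vi, info = dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("inversion failed")
    return vi + np.tril(vi, -1).T


def _rel_change(new: np.ndarray, old: np.ndarray) -> float:
    return float(np.max(2.0 * np.abs(new - old) / (np.abs(new) + np.abs(old) + 1e-2)))


class PangenomeGLMM:
    """Trait ~ covariates + relatedness-structured random effect.

    Parameters
    ----------
    trait : TraitTable
        Aligned trait/covariate table; ``trait_kind`` selects the link.
    grm : RelatednessMatrix
        Species relatedness; made positive semidefinite via a minimal
        diagonal ridge unless ``ensure_psd=False``.
    """

    def __init__(self, trait: TraitTable, grm: RelatednessMatrix, ensure_psd: bool = True):
        if not np.array_equal(trait.sample_ids, grm.sample_ids):
            raise ValueError("trait table and GRM sample ids differ; align first")
        if ensure_psd:
            grm = grm.ensure_psd()
        self.trait = trait
        self.grm = grm
        self.link = "logit" if trait.trait_kind == "binary" else "identity"
        self.X = np.asarray(trait.X, dtype=float)
        self.y = np.asarray(trait.y, dtype=float)
        self.Psi = np.asarray(grm.values, dtype=float)
        self.n, self.q = self.X.shape

    @classmethod
    def from_dataframe(cls, df, trait: str, covariates=None, grm: RelatednessMatrix = None,
                       trait_kind: str | None = None):
        """Build from a pandas DataFrame indexed (or keyed) by sample id."""
        covariates = covariates or []
        ids = df.index.astype(str).to_numpy(dtype=object)
        y = df[trait].to_numpy(dtype=float)
        if trait_kind is None:
            trait_kind = "binary" if np.isin(y, [0.0, 1.0]).all() else "quantitative"
        X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates])
        tt = TraitTable(ids, y, X, ["(Intercept)"] + covariates, trait_kind)
        return cls(tt, grm)

    # -- core fitting ----------------------------------------------------

    def fit(self, tol: float = 1e-4, max_iter: int = 50, tau0: float | None = None,
            fix_tau: bool = False) -> "GLMMResults":
        """Fit by PQL with AI-REML variance-component updates.

        ``fix_tau=True`` holds tau at ``tau0`` (e.g. 0 to reduce the model
        to a plain GLM while keeping the score-test machinery).
        """
        return self._fit_core(self.y, tol=tol, max_iter=max_iter, tau0=tau0,
                              fix_tau=fix_tau)

    def _fit_core(self, y: np.ndarray, tol: float = 1e-4, max_iter: int = 50,
                  tau0: float | None = None, fix_tau: bool = False) -> "GLMMResults":
        X, Psi, n, q = self.X, self.Psi, self.n, self.q
        binary = self.link == "logit"
        eye = np.eye(n)

        if binary:
            alpha, separated = _irls_logistic(X, y)
            if separated:
                warnings.warn("quasi-separation in initial logistic fit; "
                              "continuing from penalized start", stacklevel=3)
            eta = X @ alpha
            mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
            W = mu * (1 - mu)
            resid_work = (y - mu) / W
            sigma2 = 1.0
        else:
            alpha, *_ = np.linalg.lstsq(X, y, rcond=None)
            eta = X @ alpha
            mu = eta
            resid_work = y - mu
            sigma2 = float(np.var(resid_work, ddof=q))
            W = np.full(n, 1.0)

        mean_diag = float(np.mean(np.diag(Psi)))
        if tau0 is not None:
            tau = float(tau0)
        elif binary:
            tau = max(0.5 * float(np.var(resid_work)) / mean_diag, 1e-4)
        else:
            tau = max(float(np.var(resid_work)) / (2.0 * mean_diag), 1e-4)
        if not binary:
            sigma2 = max(sigma2 / 2.0, 1e-8)

        b = np.zeros(n)
        converged = False
        ill_conditioned = False
        n_iter = 0
        prev = np.concatenate([alpha, [tau, sigma2]])
        for n_iter in range(1, max_iter + 1):
            if binary:
                mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
                W = mu * (1 - mu)
                Ytil = eta + (y - mu) / W
                V = np.diag(1.0 / W) + tau * Psi
            else:
                Ytil = y
                V = sigma2 * eye + tau * Psi

            Vinv = _sym_inv(V)
            VinvX = Vinv @ X
            XtVinvX = X.T @ VinvX
            cXtVX = cho_factor(XtVinvX, lower=True, check_finite=False)

            VinvY = Vinv @ Ytil
            alpha_new = cho_solve(cXtVX, X.T @ VinvY, check_finite=False)
            Py = VinvY - VinvX @ cho_solve(cXtVX, VinvX.T @ Ytil, check_finite=False)

            def apply_P(v):
                return Vinv @ v - VinvX @ cho_solve(cXtVX, VinvX.T @ v, check_finite=False)

            # AI-REML step for the variance components
            PsiPy = Psi @ Py
            PsiVinvX = Psi @ VinvX
            tr_PPsi = float(np.sum(Vinv * Psi)) - float(
                np.trace(cho_solve(cXtVX, VinvX.T @ PsiVinvX, check_finite=False))
            )
            score_tau = 0.5 * (Py @ PsiPy - tr_PPsi)
            P_PsiPy = apply_P(PsiPy)
            ai_tt = 0.5 * float(PsiPy @ P_PsiPy)

            # fixed and random effects at the current components
            alpha = alpha_new
            b = tau * (Psi @ Py)
            eta = X @ alpha + b
            if fix_tau and binary:
                pass
            elif fix_tau:
                # identity link with tau held: scalar sigma2 update
                tr_PV0 = float(np.trace(Vinv)) - float(
                    np.trace(cho_solve(cXtVX, VinvX.T @ VinvX, check_finite=False)))
                score_s2 = 0.5 * (Py @ Py - tr_PV0)
                P_Py = apply_P(Py)
                ai_ss = 0.5 * float(Py @ P_Py)
                if ai_ss > 1e-12:
                    sigma2 = max(sigma2 + score_s2 / ai_ss, 1e-8)
            elif binary:
                if ai_tt > 1e-12:
                    delta = score_tau / ai_tt
                else:
                    ill_conditioned = True
                    delta = np.sign(score_tau) * 0.1 * max(tau, 1.0)
                step = 1.0
                tau_new = tau + delta
                while tau_new < 0 and step > 1e-4:
                    step *= 0.5
                    tau_new = tau + step * delta
                if tau_new < 0:
                    tau_new = tau / 2.0
                if tau_new < 1e-6 and score_tau < 0:
                    tau_new = 0.0
                tau = tau_new
            else:
                tr_PV0 = float(np.trace(Vinv)) - float(
                    np.trace(cho_solve(cXtVX, VinvX.T @ VinvX, check_finite=False)))
                score_s2 = 0.5 * (Py @ Py - tr_PV0)
                P_Py = apply_P(Py)
                ai = np.empty((2, 2))
                ai[0, 0] = 0.5 * float(Py @ P_Py)
                ai[0, 1] = ai[1, 0] = 0.5 * float(Py @ P_PsiPy)
                ai[1, 1] = ai_tt
                sc = np.array([score_s2, score_tau])
                try:
                    cond = np.linalg.cond(ai)
                    if cond > 1e10:
                        raise np.linalg.LinAlgError
                    delta = np.linalg.solve(ai, sc)
                except np.linalg.LinAlgError:
                    ill_conditioned = True
                    delta = sc / (np.abs(np.diag(ai)) + 1e-8)
                step = 1.0
                theta = np.array([sigma2, tau])
                theta_new = theta + delta
                floor = np.array([1e-8, 0.0])
                while (theta_new < floor - 1e-15).any() and step > 1e-4:
                    step *= 0.5
                    theta_new = theta + step * delta
                theta_new = np.maximum(theta_new, floor)
                if theta_new[1] < 1e-6 and score_tau < 0:
                    theta_new[1] = 0.0
                sigma2, tau = float(theta_new[0]), float(theta_new[1])

            cur = np.concatenate([alpha, [tau, sigma2]])
            if _rel_change(cur, prev) < tol:
                converged = True
                break
            prev = cur

        if not converged:
            warnings.warn(f"mixed model did not converge in {max_iter} iterations",
                          stacklevel=3)

        # final refresh of all cached quantities at the converged components
        if binary:
            mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
            W = mu * (1 - mu)
            Ytil = eta + (y - mu) / W
            V = np.diag(1.0 / W) + tau * Psi
        else:
            Ytil = y
            V = sigma2 * eye + tau * Psi
        Vinv = _sym_inv(V)
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        cXtVX = cho_factor(XtVinvX, lower=True, check_finite=False)
        VinvY = Vinv @ Ytil
        alpha = cho_solve(cXtVX, X.T @ VinvY, check_finite=False)
        Py = VinvY - VinvX @ cho_solve(cXtVX, VinvX.T @ Ytil, check_finite=False)
        b = tau * (Psi @ Py)
        eta = X @ alpha + b
        if binary:
            mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
            W = mu * (1 - mu)
        else:
            mu = eta
            W = np.full(n, 1.0 / sigma2)

        return GLMMResults(
            model=self, y=y, alpha=alpha, b=b, tau=float(tau), sigma2=float(sigma2),
            mu=mu, W=W, eta=eta, link=self.link, converged=converged, n_iter=n_iter,
            ill_conditioned=ill_conditioned,
            _Vinv=Vinv, _VinvX=VinvX, _XtVinvX=XtVinvX,
        )


@dataclass
class GLMMResults:
    """Fitted null model: estimates plus cached projection factors.

    The projection ``P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1`` from the
    converged fit is what the per-gene score tests need; ``apply_P``
    applies it without forming P densely.
    """

    model: PangenomeGLMM
    y: np.ndarray
    alpha: np.ndarray
    b: np.ndarray
    tau: float
    sigma2: float
    mu: np.ndarray
    W: np.ndarray
    eta: np.ndarray
    link: str
    converged: bool
    n_iter: int
    ill_conditioned: bool
    _Vinv: np.ndarray
    _VinvX: np.ndarray
    _XtVinvX: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)

    def apply_P(self, v: np.ndarray) -> np.ndarray:
        Vv = self._Vinv @ v
        return Vv - self._VinvX @ np.linalg.solve(self._XtVinvX, self._VinvX.T @ v)

    def adjust_covariates(self, g: np.ndarray) -> np.ndarray:
        """Project the covariates out of g in the working-weight metric."""
        X, W = self.model.X, self.W
        XtWX = (X * W[:, None]).T @ X
        return g - X @ np.linalg.solve(XtWX, (X * W[:, None]).T @ g)

    def tau_statistic(self) -> float:
        """T = mean(b_i^2), the population-structure association statistic."""
        return float(np.mean(self.b ** 2))

    def training_auc(self) -> float:
        """AUC of the fitted linear predictor against the binary trait.

        In-sample by necessity: the random effects are per-host parameters,
        so the fitted model does not generalize to unseen hosts.
        """
        if self.link != "logit":
            raise ValueError("training AUC is defined for binary traits only")
        if len(np.unique(self.y)) < 2:
            raise ValueError("AUC undefined: trait has a single class")
        return float(roc_auc_score(self.y, self.eta))

    def summary(self) -> str:
        lines = [
            "Pangenome GLMM (PQL + AI-REML)",
            "=" * 46,
            f"link: {self.link}    n: {self.n}    converged: {self.converged}"
            f" ({self.n_iter} iter)",
            f"tau (structure variance): {self.tau:.4f}",
        ]
        if self.link == "identity":
            lines.append(f"sigma2 (residual variance): {self.sigma2:.4f}")
        lines.append(f"T = mean(b^2): {self.tau_statistic():.4f}")
        if self.link == "logit" and len(np.unique(self.y)) == 2:
            lines.append(f"training AUC: {self.training_auc():.3f}")
        if self.model.grm.ridge > 0:
            lines.append(f"GRM diagonal ridge: {self.model.grm.ridge:.2e}")
        lines.append("-" * 46)
        lines.append(f"{'coef':<16}{'estimate':>12}")
        for name, a in zip(self.model.trait.covariate_names, self.alpha):
            lines.append(f"{name:<16}{a:>12.4f}")
        return "\n".join(lines)

    # implemented in sibling modules; bound here for a cohesive results API
    def tau_test(self, B: int = 1000, seed: int | None = None):
        from .tau import tau_test as _tau_test
        return _tau_test(self, B=B, seed=seed)

    def score_tests(self, G):
        from .score import run_beta_tests
        return run_beta_tests(self, G)


def fit_null_model(trait: TraitTable, grm: RelatednessMatrix, **opts) -> GLMMResults:
    """Functional wrapper: construct the model and fit it."""
    return PangenomeGLMM(trait, grm).fit(**opts)


def training_auc(fit: GLMMResults, y: np.ndarray | None = None) -> float:
    if y is not None and len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: trait has a single class")
    if y is None:
        return fit.training_auc()
    return float(roc_auc_score(y, fit.eta))
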