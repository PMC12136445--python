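"""Permutation test for trait-population structure association.

The statistic T = mean(b_i^2) summarizes how much of the trait the
relatedness-structured random effects absorb.  Its null distribution is
obtained by permuting the trait across samples (covariates stay attached
to their samples) and refitting the mixed model for each permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .glmm import GLMMResults, PangenomeGLMM
from .grm import RelatednessMatrix
from .io import TraitTable

__all__ = ["TauResult", "tau_statistic", "tau_test"]


@dataclass
class TauResult:
    """Outcome of the permutation test for population structure."""

    tau_hat: float
    T_obs: float
    T_perm: np.ndarray
    p_value: float
    B: int
    auc: float | None
    b: np.ndarray
    seed: int | None
    n_failed: int = 0
    fit: GLMMResults | None = None

    def summary(self) -> str:
        auc = f"{self.auc:.3f}" if self.auc is not None else "n/a"
        return (
            f"tau test: tau_hat={self.tau_hat:.4f}  T_obs={self.T_obs:.4f}  "
            f"p={self.p_value:.4g} (B={self.B})  training AUC={auc}"
        )


def tau_statistic(fit: GLMMResults) -> float:
    """T = (sum_i b_i^2) / n for the fitted random effects."""
    return fit.tau_statistic()


def tau_test(fit: GLMMResults, B: int = 1000, seed: int | None = None) -> TauResult:
    """Permutation p-value for the observed T statistic.

    The trait vector is permuted ``B`` times; the null model is refit for
    each permutation and its T recorded.  p = (1 + #{T_perm >= T_obs}) /
    (B + 1), so p is never zero and ties count as exceedances
    (conservative).

    Parameters
    ----------
    fit : GLMMResults
        Converged null-model fit on the observed trait.
    B : int
        Number of permutations; the attainable minimum p is 1/(B+1).
    seed : int, optional
        Seed for the permutation stream; recorded for reproducibility.
    """
    if B < 20:
        warnings.warn(f"B={B} permutations gives very coarse p-value resolution",
                      stacklevel=2)
    model = fit.model
    T_obs = fit.tau_statistic()
    rng = np.random.default_rng(seed)
    T_perm = np.empty(B)
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(B):
            y_perm = rng.permutation(model.y)
            try:
                perm_fit = model._fit_core(y_perm)
                T_perm[i] = perm_fit.tau_statistic()
            except Exception:
                n_failed += 1
                T_perm[i] = np.nan
    if n_failed:
        warnings.warn(f"{n_failed}/{B} permutation refits failed and were dropped",
                      stacklevel=2)
    valid = T_perm[~np.isnan(T_perm)]
    p = (1.0 + float(np.sum(valid >= T_obs))) / (len(valid) + 1.0)
    auc = None
    if fit.link == "logit" and len(np.unique(fit.y)) == 2:
        auc = fit.training_auc()
    return TauResult(
        tau_hat=fit.tau, T_obs=T_obs, T_perm=T_perm, p_value=p, B=B,
        auc=auc, b=fit.b.copy(), seed=seed, n_failed=n_failed, fit=fit,
    )


def run_tau_test(trait: TraitTable, grm: RelatednessMatrix, B: int = 1000,
                 seed: int | None = None, **fit_opts) -> TauResult:
    """Fit the null model and run the permutation test in one call."""
    fit = PangenomeGLMM(trait, grm).fit(**fit_opts)
    return tau_test(fit, B=B, seed=seed)
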