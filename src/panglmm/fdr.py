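"""Local false discovery rates with an empirically fitted null.

Gene presence/absence patterns co-occur across strains, so per-gene test
statistics are strongly correlated and tail-area FDR procedures
(Benjamini-Hochberg, q-values) are unreliable.  Instead, two-sided
p-values are mapped to signed z-values, the marginal z density is
estimated by Poisson regression of histogram counts on a natural spline
basis, and an empirical null N(mean, sd) with mass pi0 is fitted by
maximum likelihood to the central z-values (between the 10th and 90th
percentiles).  The local false discovery rate at z is then

    fdr(z) = pi0 * phi((z - mean)/sd) / sd / f_hat(z),  clipped to [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from patsy import dmatrix
from scipy.optimize import minimize
from scipy.stats import norm

from .score import GeneAssociation

__all__ = ["FdrModel", "p_to_signed_z", "fit_local_fdr", "call_significant"]


def p_to_signed_z(p, sign):
    """Map a two-sided p-value and an effect sign to a signed z-value.

    z = +Phi^-1(1 - p/2) for positive effects, the mirror image for
    negative effects, and 0 for sign 0.  p = 0 is clamped (with a warning)
    to 1e-300, the smallest value whose quantile is representable.
    """
    p = np.asarray(p, dtype=float)
    sign = np.asarray(sign, dtype=float)
    if (p == 0).any():
        warnings.warn("p-value of 0 clamped to smallest usable float", stacklevel=2)
    p = np.maximum(p, 1e-300)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    z = np.where(sign >= 0, norm.isf(p / 2.0), norm.ppf(p / 2.0))
    z = np.where(sign == 0, 0.0, z)
    if z.ndim == 0:
        return float(z)
    return z


@dataclass
class FdrModel:
    """Fitted empirical-null localFDR model.

    The marginal density estimate is stored as log f on a fine grid;
    evaluation interpolates (linearly extrapolating in the tails), which
    also makes the model JSON-serializable.
    """

    null_mean: float
    null_sd: float
    pi0: float
    grid_z: np.ndarray
    grid_logf: np.ndarray
    central_range: tuple[float, float]
    n_obs: int
    bins: int
    spline_df: int

    def marginal_density(self, z) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        logf = np.interp(z, self.grid_z, self.grid_logf)
        # linear extrapolation of log f beyond the grid
        g, lf = self.grid_z, self.grid_logf
        lo_slope = (lf[1] - lf[0]) / (g[1] - g[0])
        hi_slope = (lf[-1] - lf[-2]) / (g[-1] - g[-2])
        logf = np.where(z < g[0], lf[0] + lo_slope * (z - g[0]), logf)
        logf = np.where(z > g[-1], lf[-1] + hi_slope * (z - g[-1]), logf)
        return np.exp(logf)

    def local_fdr(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        scalar = z.ndim == 0
        z = np.atleast_1d(z)
        f0 = norm.pdf(z, loc=self.null_mean, scale=self.null_sd)
        f = np.maximum(self.marginal_density(z), 1e-300)
        fdr = np.clip(self.pi0 * f0 / f, 0.0, 1.0)
        return float(fdr[0]) if scalar else fdr

    def to_json(self, path) -> None:
        obj = {
            "null_mean": self.null_mean, "null_sd": self.null_sd, "pi0": self.pi0,
            "grid_z": self.grid_z.tolist(), "grid_logf": self.grid_logf.tolist(),
            "central_range": list(self.central_range), "n_obs": self.n_obs,
            "bins": self.bins, "spline_df": self.spline_df,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "FdrModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            obj["null_mean"], obj["null_sd"], obj["pi0"],
            np.asarray(obj["grid_z"]), np.asarray(obj["grid_logf"]),
            tuple(obj["central_range"]), obj["n_obs"], obj["bins"], obj["spline_df"],
        )


def _truncated_normal_mle(z0: np.ndarray, lo: float, hi: float):
    """MLE of (mean, sd) for a normal truncated to [lo, hi]."""

    def nll(theta):
        m, log_s = theta
        s = np.exp(log_s)
        mass = norm.cdf((hi - m) / s) - norm.cdf((lo - m) / s)
        if mass <= 1e-12:
            return 1e10
        return -(np.sum(norm.logpdf(z0, m, s)) - len(z0) * np.log(mass))

    res = minimize(nll, x0=[np.median(z0), np.log(max(z0.std(), 1e-3))],
                   method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-7, "maxiter": 2000})
    m, s = res.x[0], float(np.exp(res.x[1]))
    return float(m), s


def fit_local_fdr(z: np.ndarray, lo_pct: float = 10.0, hi_pct: float = 90.0,
                  bins: int = 120, spline_df: int = 7) -> FdrModel:
    """Fit the marginal z density and the empirical null.

    Parameters
    ----------
    z : array
        Signed z-values, pooled across species (>= 200 required for a
        stable density estimate).
    lo_pct, hi_pct : float
        Percentile window of z-values assumed to be dominated by the null
        when fitting N(mean, sd) by (truncated) maximum likelihood.
    bins, spline_df : int
        Histogram bins and natural-spline degrees of freedom for the
        Poisson density fit.
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < 200:
        raise ValueError(f"need at least 200 z-values for localFDR, got {len(z)}")
    if np.ptp(z) < 1e-12:
        raise ValueError("degenerate z-values (all equal)")

    # marginal density: Poisson regression of histogram counts on a spline
    edges = np.linspace(z.min(), z.max(), bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    width = edges[1] - edges[0]
    design = dmatrix(f"cr(x, df={spline_df})", {"x": centers}, return_type="dataframe")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(counts, design, family=sm.families.Poisson()).fit()
    grid_z = np.linspace(z.min(), z.max(), 512)
    from patsy import build_design_matrices
    grid_design = np.asarray(
        build_design_matrices([design.design_info], {"x": grid_z})[0])
    eta = grid_design @ pois.params.to_numpy()
    grid_logf = eta - np.log(len(z) * width)

    # empirical null on the central percentile window
    lo, hi = np.percentile(z, [lo_pct, hi_pct])
    z0 = z[(z >= lo) & (z <= hi)]
    m, s = _truncated_normal_mle(z0, lo, hi)
    mass = norm.cdf((hi - m) / s) - norm.cdf((lo - m) / s)
    pi0 = float(np.clip((len(z0) / len(z)) / max(mass, 1e-12), 1e-6, 1.0))

    return FdrModel(m, s, pi0, grid_z, grid_logf, (float(lo), float(hi)),
                    len(z), bins, spline_df)


def call_significant(assocs, model: FdrModel, threshold: float = 0.2):
    """Fill localFDR values and flag discoveries (strict fdr < threshold).

    Accepts a list of GeneAssociation (filled in place, returns a boolean
    array) or an array of z-values (returns the boolean array only).
    """
    if len(assocs) == 0:
        return np.zeros(0, dtype=bool)
    if isinstance(assocs[0], GeneAssociation):
        zvals = np.array([a.z_signed for a in assocs])
        fdr = model.local_fdr(zvals)
        for a, f in zip(assocs, fdr):
            a.local_fdr = float(f)
        return fdr < threshold
    fdr = model.local_fdr(np.asarray(assocs, dtype=float))
    return fdr < threshold
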