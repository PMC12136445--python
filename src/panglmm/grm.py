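"""Genetic relatedness from gene presence/absence profiles.

The species-level GRM is 1 minus the per-gene-normalized Manhattan
distance between binary gene presence/absence profiles: two hosts
carrying identical gene repertoires of a species have relatedness 1,
hosts with fully complementary repertoires have relatedness 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PangenomeMatrix

__all__ = ["RelatednessMatrix", "compute_grm", "grm_pcs", "read_grm", "write_grm"]


@dataclass
class RelatednessMatrix:
    """n-by-n symmetric relatedness matrix with entries in [0, 1].

    ``ridge`` records the diagonal adjustment applied by :meth:`ensure_psd`
    (0 until applied); 1-minus-Manhattan relatedness is not guaranteed
    positive semidefinite, and the mixed model needs a valid covariance.
    """

    sample_ids: np.ndarray
    values: np.ndarray
    ridge: float = 0.0

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("relatedness matrix must be square, matching sample ids")
        if not np.isfinite(self.values).all():
            raise ValueError("relatedness matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relatedness matrix must be symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def ensure_psd(self, eps: float = 1e-6) -> "RelatednessMatrix":
        """Return a positive semidefinite copy via a minimal diagonal ridge.

        delta = max(0, -lambda_min) + eps is added to the diagonal when the
        smallest eigenvalue is negative; otherwise the matrix is returned
        unchanged (ridge 0).
        """
        lam_min = float(np.linalg.eigvalsh(self.values)[0])
        if lam_min >= 0:
            return self
        delta = -lam_min + eps
        vals = self.values + delta * np.eye(self.n_samples)
        out = RelatednessMatrix(self.sample_ids, vals)
        out.ridge = delta
        return out

    def take_samples(self, idx) -> "RelatednessMatrix":
        idx = np.asarray(idx, dtype=int)
        out = RelatednessMatrix(self.sample_ids[idx], self.values[np.ix_(idx, idx)])
        out.ridge = self.ridge
        return out


def compute_grm(G: PangenomeMatrix) -> RelatednessMatrix:
    """Relatedness = 1 - Manhattan distance / number of genes.

    For binary profiles the Manhattan distance between samples i and j is
    ``sum_k |G[i,k] - G[j,k]|``, computed here via inner products:
    ``d_ij = r_i + r_j - 2 (G G^T)_ij`` with ``r_i`` the row sums.
    """
    if G.n_genes == 0:
        raise ValueError("cannot compute relatedness from an empty gene matrix")
    B = G.values.astype(np.float64)
    gram = B @ B.T
    r = np.diag(gram)
    dist = r[:, None] + r[None, :] - 2.0 * gram
    vals = 1.0 - dist / G.n_genes
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 1.0)
    return RelatednessMatrix(G.sample_ids, vals)


def grm_pcs(Psi: RelatednessMatrix, k: int, center: bool = True) -> np.ndarray:
    """Leading principal components of the relatedness matrix.

    The matrix is double-centered by default (classical principal
    coordinates), eigendecomposed, and the top-``k`` eigenvectors scaled by
    the square root of their (nonnegative-clipped) eigenvalues are
    returned, columns ordered by decreasing eigenvalue.  Sign convention:
    each column's largest-magnitude loading is positive.
    """
    n = Psi.n_samples
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    A = Psi.values
    if center:
        J = np.eye(n) - np.ones((n, n)) / n
        A = J @ A @ J
        A = (A + A.T) / 2.0
    lam, vec = np.linalg.eigh(A)
    order = np.argsort(lam)[::-1][:k]
    lam = np.clip(lam[order], 0.0, None)
    pcs = vec[:, order] * np.sqrt(lam)[None, :]
    for j in range(k):
        col = pcs[:, j]
        i = np.argmax(np.abs(col))
        if col[i] < 0:
            pcs[:, j] = -col
    return pcs


def write_grm(Psi: RelatednessMatrix, path) -> None:
    pd.DataFrame(Psi.values, index=Psi.sample_ids, columns=Psi.sample_ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_grm(path) -> RelatednessMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RelatednessMatrix(
        df.index.astype(str).to_numpy(dtype=object), df.to_numpy(dtype=float)
    )
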