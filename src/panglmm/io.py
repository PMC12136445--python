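"""Data containers and TSV input/output for pangenome association testing.

The three tables a within-species association analysis needs are a binary
sample-by-gene presence/absence matrix, a per-sample trait/covariate table,
and (optionally) a sample-by-species relative abundance table.  All are
plain TSV with a header row; gzip is handled transparently by pandas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PangenomeMatrix",
    "TraitTable",
    "AbundanceTable",
    "PanglmmFormatError",
    "read_pangenome",
    "write_pangenome",
    "read_trait_table",
    "align_samples",
    "filter_variable_genes",
]


class PanglmmFormatError(ValueError):
    """Raised when an input table violates the expected format."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise PanglmmFormatError(f"duplicate {what}: {dups[:5]}")


@dataclass
class PangenomeMatrix:
    """Binary sample-by-gene presence/absence matrix for one species.

    Attributes
    ----------
    sample_ids : ndarray of str, shape (n,)
    gene_ids : ndarray of str, shape (p,)
    values : ndarray of uint8, shape (n, p)
        Entries are exactly 0 (gene family absent) or 1 (present).
    """

    sample_ids: np.ndarray
    gene_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.gene_ids):
            raise PanglmmFormatError("matrix shape does not match id lengths")
        if n < 2 or p < 1:
            raise PanglmmFormatError(f"need at least 2 samples and 1 gene, got {n}x{p}")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.gene_ids, "gene ids")
        bad = (self.values != 0) & (self.values != 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanglmmFormatError(
                f"non-binary entry {self.values[i, j]!r} at sample "
                f"{self.sample_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )
        self.values = self.values.astype(np.uint8)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def take_samples(self, idx) -> "PangenomeMatrix":
        return PangenomeMatrix(self.sample_ids[idx], self.gene_ids, self.values[idx])


@dataclass
class TraitTable:
    """Per-sample trait and covariates.

    ``X`` always contains an intercept column (named ``(Intercept)``); the
    trait is binary (0/1, logit link) or quantitative (identity link).
    """

    sample_ids: np.ndarray
    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str]
    trait_kind: str = "binary"

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        _check_unique(self.sample_ids, "sample ids")
        if self.trait_kind not in ("binary", "quantitative"):
            raise PanglmmFormatError(f"unknown trait_kind {self.trait_kind!r}")
        if self.trait_kind == "binary" and not np.isin(self.y, [0.0, 1.0]).all():
            raise PanglmmFormatError("binary trait must contain only 0/1")
        if self.X.shape != (len(self.sample_ids), len(self.covariate_names)):
            raise PanglmmFormatError("covariate matrix shape mismatch")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise PanglmmFormatError("covariate matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take_samples(self, idx) -> "TraitTable":
        return TraitTable(
            self.sample_ids[idx], self.y[idx], self.X[idx],
            list(self.covariate_names), self.trait_kind,
        )


@dataclass
class AbundanceTable:
    """Sample-by-species relative abundance table (entries in [0, 1])."""

    sample_ids: np.ndarray
    species_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.species_ids = np.asarray(self.species_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.species_ids, "species ids")
        if (self.values < 0).any():
            raise PanglmmFormatError("relative abundances must be nonnegative")
        if (self.values.sum(axis=1) > 1 + 1e-6).any():
            warnings.warn("per-sample abundances sum to more than 1", stacklevel=2)

    def take_samples(self, idx) -> "AbundanceTable":
        return AbundanceTable(self.sample_ids[idx], self.species_ids, self.values[idx])


def read_pangenome(path, orientation: str = "samples_in_rows") -> PangenomeMatrix:
    """Read a binary presence/absence TSV.

    Parameters
    ----------
    path : str or Path
        TSV with a header row; the first column holds row identifiers.
    orientation : {"samples_in_rows", "genes_in_rows"}
        Profiler merge outputs commonly put gene families in rows; pass
        ``"genes_in_rows"`` to transpose on read.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "genes_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    vals = df.to_numpy()
    if vals.dtype == object or not np.isin(np.unique(vals), [0, 1]).all():
        flat = pd.DataFrame(vals).stack()
        bad = flat[~flat.isin([0, 1])]
        if len(bad):
            (row, col) = bad.index[0]
            raise PanglmmFormatError(
                f"non-binary entry {bad.iloc[0]!r} at row {df.index[row]!r}, "
                f"column {df.columns[col]!r} in {path}"
            )
    return PangenomeMatrix(
        df.index.astype(str).to_numpy(dtype=object),
        df.columns.astype(str).to_numpy(dtype=object),
        vals.astype(np.uint8),
    )


def write_pangenome(G: PangenomeMatrix, path) -> None:
    """Write samples-in-rows TSV; round-trips bitwise with read_pangenome."""
    G.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_trait_table(
    path,
    trait: str,
    covariates: list[str] | None = None,
    trait_kind: str | None = None,
    sample_col: str | None = None,
) -> TraitTable:
    """Read a sample metadata TSV into a TraitTable.

    Samples with missing trait or covariate values are dropped with a
    warning.  ``trait_kind`` is inferred (binary iff the trait takes only
    values 0 and 1) unless given explicitly.
    """
    df = pd.read_csv(path, sep="\t")
    sample_col = sample_col or df.columns[0]
    if trait not in df.columns:
        raise PanglmmFormatError(f"trait column {trait!r} not in {list(df.columns)}")
    covariates = covariates or []
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise PanglmmFormatError(f"covariate columns not found: {missing}")
    keep = df[[trait] + covariates].notna().all(axis=1)
    if not keep.all():
        dropped = df.loc[~keep, sample_col].tolist()
        warnings.warn(
            f"dropping {len(dropped)} samples with missing trait/covariates: "
            f"{dropped[:5]}", stacklevel=2,
        )
        df = df[keep]
    y = df[trait].to_numpy(dtype=float)
    if trait_kind is None:
        trait_kind = "binary" if np.isin(y, [0.0, 1.0]).all() else "quantitative"
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates])
    return TraitTable(
        df[sample_col].astype(str).to_numpy(dtype=object),
        y, X, ["(Intercept)"] + covariates, trait_kind,
    )


def align_samples(G: PangenomeMatrix, T: TraitTable):
    """Restrict both tables to their common samples, in a common order.

    The order follows ``G``'s sample order restricted to the intersection.
    Idempotent; raises if the intersection is empty.
    """
    t_pos = {s: i for i, s in enumerate(T.sample_ids)}
    g_keep = [i for i, s in enumerate(G.sample_ids) if s in t_pos]
    if not g_keep:
        raise PanglmmFormatError("no samples shared between pangenome and trait table")
    dropped_g = [s for s in G.sample_ids if s not in t_pos]
    g_set = set(G.sample_ids.tolist())
    dropped_t = [s for s in T.sample_ids if s not in g_set]
    if dropped_g or dropped_t:
        warnings.warn(
            f"align_samples dropped {len(dropped_g)} pangenome-only and "
            f"{len(dropped_t)} trait-only samples "
            f"(e.g. {(dropped_g + dropped_t)[:5]})", stacklevel=2,
        )
    g_idx = np.asarray(g_keep, dtype=int)
    t_idx = np.asarray([t_pos[s] for s in G.sample_ids[g_idx]], dtype=int)
    return G.take_samples(g_idx), T.take_samples(t_idx)


@dataclass
class FilterReport:
    n_removed_core: int
    n_removed_rare: int
    n_kept: int


def filter_variable_genes(
    G: PangenomeMatrix,
    min_absent: int = 10,
    min_present: int = 30,
    return_report: bool = False,
):
    """Drop near-core and rare gene families before association testing.

    A gene is kept iff it is absent in at least ``min_absent`` samples and
    present in at least ``min_present`` samples.  Genes failing the first
    condition are effectively core (uninformative for strain structure);
    genes failing the second are too rare to test.
    """
    if min_absent < 0 or min_present < 0:
        raise ValueError("thresholds must be nonnegative")
    present = G.values.sum(axis=0).astype(int)
    absent = G.n_samples - present
    is_core = absent < min_absent
    is_rare = (~is_core) & (present < min_present)
    keep = (~is_core) & (~is_rare)
    if not keep.any():
        raise PanglmmFormatError(
            f"all {G.n_genes} genes removed by variability filter "
            f"(min_absent={min_absent}, min_present={min_present}); "
            "lower the thresholds"
        )
    out = PangenomeMatrix(G.sample_ids, G.gene_ids[keep], G.values[:, keep])
    report = FilterReport(int(is_core.sum()), int(is_rare.sum()), int(keep.sum()))
    if return_report:
        return out, report
    return out
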