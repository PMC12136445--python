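"""Species-level relative-abundance association test.

The conventional baseline: logistic regression of the case/control label
on a species' relative abundance plus covariates, one species at a time,
after removing species below an abundance floor.  P-values feed the
localFDR module (threshold 0.1) alongside the structure-test results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AbundanceTable, TraitTable
from .score import _logistic_wald

__all__ = ["run_abundance_tests"]


def run_abundance_tests(A: AbundanceTable, T: TraitTable,
                        min_rel_abund: float = 0.0005,
                        log_transform: bool = False,
                        pseudocount: float = 1e-6) -> pd.DataFrame:
    """Per-species logistic regression of the trait on relative abundance.

    Species whose mean relative abundance is below ``min_rel_abund``
    (default 0.05%) are removed.  Abundance enters untransformed by
    default; ``log_transform`` switches to log10(x + pseudocount).

    Returns a DataFrame indexed by species id with columns
    ``log_odds``, ``se``, ``z``, ``p_value``, ``untestable``, ``note``.
    """
    if T.trait_kind != "binary":
        raise ValueError("abundance test is defined for binary traits")
    if not np.array_equal(A.sample_ids, T.sample_ids):
        raise ValueError("abundance table and trait table sample ids differ; align first")
    mean_ab = A.values.mean(axis=0)
    keep = mean_ab >= min_rel_abund
    rows = []
    for j in np.where(keep)[0]:
        x = A.values[:, j].astype(float)
        if log_transform:
            x = np.log10(x + pseudocount)
        if len(np.unique(x)) < 2:
            rows.append({"species_id": A.species_ids[j], "log_odds": np.nan,
                         "se": np.nan, "z": np.nan, "p_value": 1.0,
                         "untestable": True, "note": "constant abundance"})
            continue
        Xfull = np.column_stack([T.X, x])
        coef, se, separated = _logistic_wald(Xfull, T.y)
        z = coef[-1] / se[-1]
        from scipy.stats import norm
        rows.append({
            "species_id": A.species_ids[j], "log_odds": float(coef[-1]),
            "se": float(se[-1]), "z": float(z),
            "p_value": float(2.0 * norm.sf(abs(z))), "untestable": False,
            "note": "separation: penalized fit" if separated else "",
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("species_id")
    df.attrs["n_removed_low_abundance"] = int((~keep).sum())
    return df
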