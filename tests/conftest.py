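import numpy as np
import pytest

from panglmm.grm import RelatednessMatrix, compute_grm
from panglmm.io import PangenomeMatrix, TraitTable
from panglmm.simulate import TauSimConfig, simulate_tau_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_pangenome(rng):
    """60 samples x 40 genes, random binary."""
    n, p = 60, 40
    vals = rng.integers(0, 2, size=(n, p)).astype(np.uint8)
    return PangenomeMatrix(
        np.array([f"s{i:03d}" for i in range(n)], dtype=object),
        np.array([f"g{j:03d}" for j in range(p)], dtype=object),
        vals,
    )


@pytest.fixture
def structured_dataset():
    """Strain-structured pangenome with a trait driven by the strain."""
    cfg = TauSimConfig(n=100, theta=0.714, seed=77)
    G, T, strain = simulate_tau_dataset(cfg)
    return G, T, strain, compute_grm(G)


@pytest.fixture
def null_dataset():
    """Pangenome with a trait independent of all genes."""
    cfg = TauSimConfig(n=100, theta=0.5, seed=31)
    G, T, strain = simulate_tau_dataset(cfg)
    return G, T, strain, compute_grm(G)


def make_trait(ids, y, extra_cov=None, kind="binary"):
    n = len(ids)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    if extra_cov is not None:
        cols.append(extra_cov)
        names.append("x")
    return TraitTable(np.asarray(ids, dtype=object), np.asarray(y, dtype=float),
                      np.column_stack(cols), names, kind)
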