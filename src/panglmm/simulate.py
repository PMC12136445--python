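"""Synthetic strain-structured pangenomes and trait generators.

Two simulation families are provided, each with an experiment harness.

Strain ("tau") simulations build a pangenome of core genes (presence
probability 0.8), accessory genes (0.2), and a block of strain-linked
genes that are present only in hosts carrying a latent strain
(prevalence 0.5), with per-gene conditional presence probabilities drawn
so the mean presence odds ratio given the strain is a stated value
(default 1.8).  The binary trait is either independent of the pangenome
(type-I-error protocol) or generated from strain carriage at an odds
ratio theta/(1-theta) (power protocol).  An age-like covariate
~ Normal(45, 15) is always included.

PC ("beta") simulations start from a base relatedness matrix, decompose
it into its first 10 principal components, and simulate 90 genes per PC
with per-sample presence probability Phi(PC_std), plus 100 unstructured
genes with presence probabilities Uniform(0.2, 0.8).  The trait is 1
when the loadings on PC1 and PC2 have opposite signs, tying it
nonlinearly to 180 structured genes; for power studies 100 causal genes
are appended with presence probability (1-y)(1-theta) + y*theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .glmm import PangenomeGLMM
from .grm import RelatednessMatrix, compute_grm, grm_pcs
from .io import PangenomeMatrix, TraitTable
from .score import run_beta_tests, run_glm_baseline
from .tau import tau_test

__all__ = [
    "TauSimConfig", "BetaSimConfig",
    "simulate_tau_dataset", "simulate_beta_dataset",
    "tau_fpr_experiment", "tau_power_experiment", "beta_fpr_power_experiment",
    "strain_gene_presence_interval", "theta_for_odds_ratio",
]


def theta_for_odds_ratio(odds_ratio: float) -> float:
    """theta with theta/(1-theta) equal to the requested odds ratio."""
    return odds_ratio / (1.0 + odds_ratio)


def strain_gene_presence_interval(mean_or: float = 1.8, half_width: float = 0.15):
    """Uniform interval for strain-linked gene presence probabilities.

    Probabilities p_g are drawn from Uniform(c - h, c + h) with the center
    c chosen so that E[p/(1-p)] over the interval equals ``mean_or``
    against an even-odds reference; closed form from integrating p/(1-p):
    c = 1 - h (R + 1)/(R - 1) with R = exp(2 h (mean_or + 1)).
    """
    R = np.exp(2.0 * half_width * (mean_or + 1.0))
    c = 1.0 - half_width * (R + 1.0) / (R - 1.0)
    return float(c - half_width), float(c + half_width)


@dataclass
class TauSimConfig:
    """Strain-structured pangenome + trait protocol (defaults as stated)."""

    n: int = 100
    n_core: int = 400
    p_core: float = 0.8
    n_acc: int = 400
    p_acc: float = 0.2
    n_strain_genes: int = 200
    strain_prev: float = 0.5
    strain_gene_or: float = 1.8
    theta: float = 0.5          # 0.5 = trait independent of the strain
    covariate_mean: float = 45.0
    covariate_sd: float = 15.0
    n_strains: int = 1
    seed: int | None = None

    def __post_init__(self):
        if not (0.5 <= self.theta < 1.0):
            raise ValueError("theta must lie in [0.5, 1)")
        for p in (self.p_core, self.p_acc, self.strain_prev):
            if not (0.0 < p < 1.0):
                raise ValueError("probabilities must lie in (0, 1)")


@dataclass
class BetaSimConfig:
    """PC-structured gene matrix + sign-rule trait protocol."""

    k_pcs: int = 10
    genes_per_pc: int = 90
    n_random: int = 100
    random_p_range: tuple[float, float] = (0.2, 0.8)
    n_causal: int = 100
    theta: float = 0.5          # 0.5 = no causal genes appended
    covariate_mean: float = 45.0
    covariate_sd: float = 15.0
    seed: int | None = None

    def __post_init__(self):
        if not (0.5 <= self.theta < 1.0):
            raise ValueError("theta must lie in [0.5, 1)")


def simulate_tau_dataset(cfg: TauSimConfig, rng: np.random.Generator | None = None):
    """Simulate one strain-structured pangenome with trait and covariate.

    Returns (PangenomeMatrix, TraitTable, strain) where ``strain`` is the
    n-vector of latent strain carriage driving the strain-linked gene
    block (the first strain, when ``n_strains > 1``).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n
    blocks = []
    blocks.append(rng.binomial(1, cfg.p_core, size=(n, cfg.n_core)))
    blocks.append(rng.binomial(1, cfg.p_acc, size=(n, cfg.n_acc)))
    lo, hi = strain_gene_presence_interval(cfg.strain_gene_or)
    strains = []
    genes_per_strain = cfg.n_strain_genes // cfg.n_strains
    for _ in range(cfg.n_strains):
        strain = rng.binomial(1, cfg.strain_prev, size=n)
        p_g = rng.uniform(lo, hi, size=genes_per_strain)
        # gene absent whenever the strain is absent
        block = rng.binomial(1, p_g[None, :], size=(n, genes_per_strain))
        block *= strain[:, None]
        strains.append(strain)
        blocks.append(block)
    G = np.concatenate(blocks, axis=1).astype(np.uint8)
    strain = strains[0]

    if cfg.theta == 0.5:
        y = rng.binomial(1, 0.5, size=n).astype(float)
    else:
        strain_delta = (1 - strain) * (1 - cfg.theta) + strain * cfg.theta
        y = rng.binomial(1, strain_delta).astype(float)
    age = rng.normal(cfg.covariate_mean, cfg.covariate_sd, size=n)

    sample_ids = np.array([f"s{i:04d}" for i in range(n)], dtype=object)
    gene_ids = (
        [f"core{i:04d}" for i in range(cfg.n_core)]
        + [f"acc{i:04d}" for i in range(cfg.n_acc)]
        + [f"strain{i:04d}" for i in range(genes_per_strain * cfg.n_strains)]
    )
    Gmat = PangenomeMatrix(sample_ids, np.array(gene_ids, dtype=object), G)
    T = TraitTable(sample_ids, y, np.column_stack([np.ones(n), age]),
                   ["(Intercept)", "age"], "binary")
    return Gmat, T, strain


def simulate_beta_dataset(cfg: BetaSimConfig, Psi: RelatednessMatrix,
                          rng: np.random.Generator | None = None):
    """Simulate a PC-structured gene matrix and sign-rule trait.

    Returns (PangenomeMatrix, TraitTable, labels) with per-gene truth
    labels in {"pc1", "pc2", "other_pc", "random", "causal"}.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = Psi.n_samples
    if n < cfg.k_pcs:
        raise ValueError(f"need at least k_pcs={cfg.k_pcs} samples, got {n}")
    pcs = grm_pcs(Psi, cfg.k_pcs)
    pcs_std = pcs / pcs.std(axis=0, ddof=1)
    probs = norm.cdf(pcs_std)                       # n x k

    blocks, labels = [], []
    for j in range(cfg.k_pcs):
        blocks.append(rng.binomial(1, probs[:, [j]], size=(n, cfg.genes_per_pc)))
        lab = "pc1" if j == 0 else ("pc2" if j == 1 else "other_pc")
        labels += [lab] * cfg.genes_per_pc
    p_rand = rng.uniform(*cfg.random_p_range, size=cfg.n_random)
    blocks.append(rng.binomial(1, p_rand[None, :], size=(n, cfg.n_random)))
    labels += ["random"] * cfg.n_random

    y = ((pcs_std[:, 0] > 0) ^ (pcs_std[:, 1] > 0)).astype(float)

    if cfg.theta > 0.5:
        y_delta = (1 - y) * (1 - cfg.theta) + y * cfg.theta
        blocks.append(rng.binomial(1, y_delta[:, None], size=(n, cfg.n_causal)))
        labels += ["causal"] * cfg.n_causal

    G = np.concatenate(blocks, axis=1).astype(np.uint8)
    age = rng.normal(cfg.covariate_mean, cfg.covariate_sd, size=n)
    sample_ids = Psi.sample_ids
    gene_ids = np.array([f"g{i:05d}_{lab}" for i, lab in enumerate(labels)], dtype=object)
    Gmat = PangenomeMatrix(sample_ids, gene_ids, G)
    T = TraitTable(sample_ids, y, np.column_stack([np.ones(n), age]),
                   ["(Intercept)", "age"], "binary")
    return Gmat, T, np.array(labels, dtype=object)


# -- experiment harnesses ----------------------------------------------


def _tau_p_one_iteration(cfg: TauSimConfig, B: int, rng: np.random.Generator) -> float:
    G, T, _ = simulate_tau_dataset(cfg, rng)
    Psi = compute_grm(G)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = PangenomeGLMM(T, Psi).fit()
        res = tau_test(fit, B=B, seed=int(rng.integers(2**31 - 1)))
    return res.p_value


def tau_fpr_experiment(n: int = 100, iters: int = 1000, B: int = 100,
                       seed: int | None = None, alpha: float = 0.05,
                       progress: bool = False) -> dict:
    """Type-I error of the permutation structure test under the null.

    The trait is simulated independently of the pangenome; the rejection
    rate at permutation p < alpha estimates the false positive rate.
    """
    rng = np.random.default_rng(seed)
    cfg = TauSimConfig(n=n, theta=0.5)
    pvals = np.empty(iters)
    for i in range(iters):
        pvals[i] = _tau_p_one_iteration(cfg, B, rng)
        if progress and (i + 1) % 25 == 0:
            print(f"  tau FPR iteration {i + 1}/{iters}", flush=True)
    return {"rejection_rate": float(np.mean(pvals < alpha)),
            "p_values": pvals, "iters": iters, "n": n, "B": B, "alpha": alpha}


def tau_power_experiment(ns=(60, 100, 250), odds_ratios=(1.0, 1.5, 2.0, 2.5),
                         iters: int = 125, B: int = 100, seed: int | None = None,
                         alpha: float = 0.05, progress: bool = False) -> pd.DataFrame:
    """Power of the structure test when the trait tracks strain carriage."""
    rng = np.random.default_rng(seed)
    rows = []
    for n in ns:
        for oratio in odds_ratios:
            cfg = TauSimConfig(n=n, theta=theta_for_odds_ratio(oratio))
            pvals = np.empty(iters)
            for i in range(iters):
                pvals[i] = _tau_p_one_iteration(cfg, B, rng)
            power = float(np.mean(pvals < alpha))
            rows.append({"n": n, "odds_ratio": oratio, "power": power,
                         "iters": iters, "B": B})
            if progress:
                print(f"  tau power n={n} OR={oratio}: {power:.3f}", flush=True)
    return pd.DataFrame(rows)


def _empirical_threshold(neg_p: np.ndarray, fpr: float = 0.05) -> float:
    """Largest p cutoff whose empirical FPR on negatives is <= fpr."""
    k = int(np.floor(fpr * len(neg_p)))
    if k == 0:
        return 0.0
    return float(np.sort(neg_p)[k - 1])


def beta_fpr_power_experiment(thetas=(0.5,), n: int = 100, replicates: int = 3,
                              seed: int | None = None, base_grm: RelatednessMatrix | None = None,
                              progress: bool = False) -> pd.DataFrame:
    """Gene-test FPR and power for the mixed model versus the plain GLM.

    Each replicate simulates a PC-structured gene matrix (from
    ``base_grm`` if supplied, else from a fresh strain-structured base
    pangenome's GRM), runs both per-gene testing approaches on identical
    data, and reports the false positive rate over the negative genes
    (all genes except those simulated from PC1, PC2, or the trait) and,
    when causal genes are present, power at the empirical-FPR-0.05
    threshold derived from the negatives.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for theta in thetas:
        for rep in range(replicates):
            if base_grm is None:
                # two strain blocks: the trait rule needs two genuine
                # structure axes (PC1 and PC2), as observed species have
                base_cfg = TauSimConfig(n=n, n_strains=2, n_strain_genes=400)
                baseG, _, _ = simulate_tau_dataset(base_cfg, rng)
                Psi0 = compute_grm(baseG)
            else:
                Psi0 = base_grm
            cfg = BetaSimConfig(theta=theta)
            G, T, labels = simulate_beta_dataset(cfg, Psi0, rng)
            Psi = compute_grm(G)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = PangenomeGLMM(T, Psi).fit()
                mixed = run_beta_tests(fit, G)
                glm = run_glm_baseline(T, G)
            p_mixed = np.array([a.p_value for a in mixed])
            p_glm = np.array([a.p_value for a in glm])
            neg = ~np.isin(labels, ["pc1", "pc2", "causal"])
            row = {
                "theta": theta, "replicate": rep, "n": Psi0.n_samples,
                "tau_hat": fit.tau, "n_negatives": int(neg.sum()),
                "fpr_mixed": float(np.mean(p_mixed[neg] < 0.05)),
                "fpr_glm": float(np.mean(p_glm[neg] < 0.05)),
            }
            if theta > 0.5:
                causal = labels == "causal"
                thr_m = _empirical_threshold(p_mixed[neg])
                thr_g = _empirical_threshold(p_glm[neg])
                row["power_mixed"] = float(np.mean(p_mixed[causal] <= thr_m))
                row["power_glm"] = float(np.mean(p_glm[causal] <= thr_g))
            rows.append(row)
            if progress:
                print(f"  beta theta={theta} rep={rep}: "
                      f"tau_hat={row['tau_hat']:.2f} "
                      f"fpr m/g={row['fpr_mixed']:.3f}/{row['fpr_glm']:.3f}",
                      flush=True)
    return pd.DataFrame(rows)
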