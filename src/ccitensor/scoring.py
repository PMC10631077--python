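"""Competing ligand-receptor co-expression scores and the label-permutation test.

All four scores work on cell-type-averaged expression of the ligand and
receptor genes (means taken over the normalized matrix):

* sum score        S[s,t] = x_l[s] + x_r[t]
* product score    S[s,t] = x_l[s] * x_r[t]      (= the CCI-tensor slice)
* Halpern's score  S[s,t] = sqrt(Z_l[s]^2 + Z_r[t]^2) after Z-scaling
  each gene's mean vector across the J cell types
* Cabello-Aguilar's score  S[s,t] = sqrt(prod) / (mu + sqrt(prod)), with
  mu the grand mean of the normalized matrix

The label-permutation test shuffles the cell-type labels of all cells
(one global shuffle per permutation, reused across pairs), recomputes the
score tensor and reports the one-tailed empirical p-value, i.e. the
proportion of permuted scores >= the observed score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .io import CellTypeLabels, ExpressionMatrix, LRPairTable, average_by_celltype

METHODS = ("sum", "product", "halpern", "cabello_aguilar")


@dataclass
class ScoreTensor:
    values: np.ndarray  # (J, J, K)
    method: str
    celltype_names: list[str]
    pair_ids: list[tuple[str, str]]
    mu: float | None = None  # cabello_aguilar only


@dataclass
class PermutationResult:
    pvalues: np.ndarray  # (J, J, K) in [0, 1]
    n_perm: int
    seed: int
    method: str
    celltype_names: list[str]
    pair_ids: list[tuple[str, str]]
    alternative: str = "greater"


def celltype_mean(expr: ExpressionMatrix, labels: CellTypeLabels, gene: str) -> np.ndarray:
    """Mean expression of one gene per cell type (J-length vector)."""
    return average_by_celltype(expr, labels).row(gene)


def sum_score(xl: np.ndarray, xr: np.ndarray) -> np.ndarray:
    xl, xr = np.asarray(xl, float), np.asarray(xr, float)
    return xl[:, None] + xr[None, :]


def product_score(xl: np.ndarray, xr: np.ndarray) -> np.ndarray:
    xl, xr = np.asarray(xl, float), np.asarray(xr, float)
    return xl[:, None] * xr[None, :]


def _zscale(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        warnings.warn("zero-variance vector in Halpern's score; Z set to zero")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def halpern_score(xl: np.ndarray, xr: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Euclidean norm of the two Z-scores; large when EITHER side deviates.

    ``ddof=1`` (sample standard deviation) by default; ``ddof=0`` switches
    to the population convention.
    """
    if len(xl) < 2 or len(xr) < 2:
        raise ValueError("Halpern's score requires at least 2 cell types")
    zl, zr = _zscale(xl, ddof), _zscale(xr, ddof)
    return np.sqrt(zl[:, None] ** 2 + zr[None, :] ** 2)


def cabello_aguilar_score(xl: np.ndarray, xr: np.ndarray, mu: float) -> np.ndarray:
    if mu <= 0:
        raise ValueError("mu must be positive")
    root = np.sqrt(product_score(xl, xr))
    return root / (mu + root)


def compute_mu(expr_normalized: ExpressionMatrix) -> float:
    """Grand mean of the normalized matrix (Cabello-Aguilar scaling factor)."""
    if expr_normalized.values.size == 0:
        raise ValueError("empty matrix")
    return float(expr_normalized.values.mean())


def _pair_mean_rows(
    means: np.ndarray, gene_ids: list[str], pairs: LRPairTable
) -> tuple[np.ndarray, np.ndarray]:
    idx = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for p in pairs.pairs for g in p if g not in idx]
    if missing:
        raise ValueError(f"pair genes absent from matrix: {sorted(set(missing))[:5]}")
    L = np.array([idx[l] for l, _ in pairs.pairs])
    R = np.array([idx[r] for _, r in pairs.pairs])
    return means[L], means[R]  # each (K, J)


def _score_from_means(XL: np.ndarray, XR: np.ndarray, method: str, mu: float | None,
                      ddof: int = 1) -> np.ndarray:
    """Vectorized (J, J, K) score tensor from (K, J) ligand/receptor means."""
    if method == "sum":
        return (XL[:, :, None] + XR[:, None, :]).transpose(1, 2, 0)
    if method == "product":
        return np.einsum("ks,kt->stk", XL, XR)
    if method == "halpern":
        sd_l = XL.std(axis=1, ddof=ddof, keepdims=True)
        sd_r = XR.std(axis=1, ddof=ddof, keepdims=True)
        flat = (sd_l == 0).sum() + (sd_r == 0).sum()
        if flat:
            warnings.warn(f"{flat} zero-variance gene vector(s); their Z set to zero")
        ZL = np.where(sd_l > 0, (XL - XL.mean(axis=1, keepdims=True)) / np.where(sd_l > 0, sd_l, 1.0), 0.0)
        ZR = np.where(sd_r > 0, (XR - XR.mean(axis=1, keepdims=True)) / np.where(sd_r > 0, sd_r, 1.0), 0.0)
        return np.sqrt(ZL[:, :, None] ** 2 + ZR[:, None, :] ** 2).transpose(1, 2, 0)
    if method == "cabello_aguilar":
        if mu is None or mu <= 0:
            raise ValueError("cabello_aguilar requires mu > 0")
        root = np.sqrt(np.einsum("ks,kt->stk", XL, XR))
        return root / (mu + root)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def score_all_pairs(
    expr: ExpressionMatrix,
    labels: CellTypeLabels,
    pairs: LRPairTable,
    method: str,
    ddof: int = 1,
) -> ScoreTensor:
    """(J, J, K) score tensor for all pairs; ``expr`` should be the
    normalized matrix used throughout the pipeline."""
    X = average_by_celltype(expr, labels)
    XL, XR = _pair_mean_rows(X.values, X.gene_ids, pairs)
    mu = compute_mu(expr) if method == "cabello_aguilar" else None
    values = _score_from_means(XL, XR, method, mu, ddof)
    return ScoreTensor(values, method, labels.celltype_names, pairs.pairs, mu)


def permutation_test(
    expr: ExpressionMatrix,
    labels: CellTypeLabels,
    pairs: LRPairTable,
    method: str,
    P: int = 1000,
    seed: int = 0,
    ddof: int = 1,
    pseudocount: bool = False,
) -> PermutationResult:
    """One-tailed label-permutation p-values for every (s, t, k) triplet.

    Each of the P permutations applies one global shuffle of the cell
    labels (group sizes n_j preserved), recomputes the score tensor and
    counts exceedances ``score_perm >= score_obs``.  p = count / P, or
    (count + 1) / (P + 1) with ``pseudocount=True``.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if labels.n_celltypes < 2:
        raise ValueError("permutation test requires at least 2 cell types")
    A = labels.indicator(expr.cell_ids)  # (H, J)
    # restrict to the genes that occur in pairs
    used = sorted({g for p in pairs.pairs for g in p})
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in used if g not in gidx]
    if missing:
        raise ValueError(f"pair genes absent from matrix: {missing[:5]}")
    sub = expr.values[[gidx[g] for g in used]]  # (G_u, H)
    mu = compute_mu(expr) if method == "cabello_aguilar" else None

    def score_tensor(means: np.ndarray) -> np.ndarray:
        XL, XR = _pair_mean_rows(means, used, pairs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat permuted vectors are expected
            return _score_from_means(XL, XR, method, mu, ddof)

    obs = score_tensor(sub @ A)
    rng = np.random.default_rng(seed)
    count = np.zeros_like(obs)
    H = len(expr.cell_ids)
    for _ in range(P):
        perm = rng.permutation(H)
        count += score_tensor(sub @ A[perm]) >= obs
    p = (count + 1) / (P + 1) if pseudocount else count / P
    return PermutationResult(p, P, seed, method, labels.celltype_names, pairs.pairs)


def binarize_by_pvalue(
    pr: PermutationResult, alpha: float = 0.05, bh_correct: bool = False
) -> np.ndarray:
    """0/1 tensor: 1 iff p < alpha (optionally on BH-adjusted p-values)."""
    p = pr.pvalues
    if bh_correct:
        p = scipy.stats.false_discovery_control(p.ravel()).reshape(p.shape)
    return (p < alpha).astype(int)
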