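"""Non-negative factorizations fitted by multiplicative updates.

Three layers:

* :func:`nmf_multiplicative` -- Frobenius-loss NMF (Lee-Seung updates),
  used both on its own and as the workhorse of rank estimation.
* :func:`estimate_rank` -- picks the smallest rank whose explained-RSS
  ratio ``(RSS_1 - RSS_k) / (RSS_1 - RSS_full)`` reaches ``thr_rank``
  (0 at rank 1, 1 at full rank; default threshold 0.8).
* :func:`ntd2` / :func:`ntd3` -- non-negative Tucker decomposition of the
  J x J x K CCI-tensor.  NTD-2 fixes the pair-mode factor to the K x K
  identity, so the core keeps one fiber G[r1, r2, :] of pair loadings per
  (ligand-pattern, receptor-pattern) combination; NTD-3 also learns a
  K x R3 pair factor.

Matricization follows the convention ``unfold(T, n) = moveaxis(T, n, 0)
.reshape(shape[n], -1)`` with the remaining modes in ascending order, and
the matching Kronecker ordering; any self-consistent choice yields the
same model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

EPS_DEFAULT = 1e-10


def unfold(T: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricization: mode-n fibers as rows."""
    return np.moveaxis(T, mode, 0).reshape(T.shape[mode], -1)


def fold(M: np.ndarray, mode: int, shape: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given shape."""
    full = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(M.reshape(full), 0, mode)


def mode_dot(T: np.ndarray, M: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n product T x_n M (M of shape new_dim x shape[mode])."""
    return np.moveaxis(np.tensordot(M, T, axes=(1, mode)), 0, mode)


def multi_mode_dot(T: np.ndarray, mats, skip_none: bool = True) -> np.ndarray:
    for mode, M in enumerate(mats):
        if M is None and skip_none:
            continue
        T = mode_dot(T, M, mode)
    return T


# ---------------------------------------------------------------------------
# NMF


@dataclass
class NMFResult:
    W: np.ndarray
    H: np.ndarray
    rss_trace: np.ndarray
    seed: int

    @property
    def rss(self) -> float:
        return float(self.rss_trace[-1])


def nmf_multiplicative(
    M: np.ndarray,
    k: int,
    n_iter: int = 200,
    seed: int = 0,
    eps: float = EPS_DEFAULT,
) -> NMFResult:
    """Frobenius NMF M ~ W H via Lee-Seung multiplicative updates."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or np.any(M < 0):
        raise ValueError("NMF requires a non-negative 2-D matrix")
    if not 1 <= k <= min(M.shape):
        raise ValueError(f"rank k={k} out of range for shape {M.shape}")
    total = M.sum()
    if total == 0:
        raise ValueError("NMF input is all-zero")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(M.mean() / k)
    W = rng.uniform(0.1, 1.0, size=(M.shape[0], k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, M.shape[1])) * scale
    rss = np.empty(n_iter)
    for it in range(n_iter):
        H *= (W.T @ M) / np.maximum(W.T @ W @ H, eps)
        W *= (M @ H.T) / np.maximum(W @ H @ H.T, eps)
        rss[it] = np.linalg.norm(M - W @ H) ** 2
    return NMFResult(W, H, rss, seed)


@dataclass
class RankEstimate:
    chosen_rank: int
    ratio_curve: np.ndarray  # ratio at candidate ranks 1..max
    rss_curve: np.ndarray
    thr_rank: float


def estimate_rank(
    M: np.ndarray,
    thr_rank: float = 0.8,
    n_iter: int = 200,
    seed: int = 0,
    n_restarts: int = 2,
    max_rank: int | None = None,
) -> RankEstimate:
    """Smallest rank whose explained-RSS ratio reaches ``thr_rank``.

    ``ratio_k = (RSS_1 - RSS_k) / (RSS_1 - RSS_max)`` with RSS_k the
    best-of-restarts NMF residual at rank k; the ratio grows from 0 at
    rank 1 to 1 at full rank.  Exactly rank-1 input (RSS_1 = RSS_full)
    degenerates to rank 1 with a warning.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("rank estimation requires a matrix with >= 2 columns")
    kmax = max_rank or min(M.shape)
    kmax = min(kmax, min(M.shape))
    rss = np.empty(kmax)
    for k in range(1, kmax + 1):
        rss[k - 1] = min(
            nmf_multiplicative(M, k, n_iter=n_iter, seed=seed + 1000 * r).rss
            for r in range(n_restarts)
        )
    denom = rss[0] - rss[-1]
    if denom <= 1e-12 * max(rss[0], 1.0):
        warnings.warn("RSS flat across ranks (input ~ rank 1); choosing rank 1")
        return RankEstimate(1, np.zeros(kmax), rss, thr_rank)
    ratio = (rss[0] - rss) / denom
    ok = np.flatnonzero(ratio >= thr_rank)
    chosen = int(ok[0]) + 1 if ok.size else kmax
    return RankEstimate(chosen, ratio, rss, thr_rank)


def estimate_tensor_ranks(
    values: np.ndarray,
    thr_rank: float = 0.8,
    n_iter: int = 200,
    seed: int = 0,
) -> tuple[int, int]:
    """NTD-2 ranks (R1, R2) from the mode-1 and mode-2 unfoldings."""
    J = values.shape[0]
    r1 = estimate_rank(unfold(values, 0), thr_rank, n_iter, seed, max_rank=J).chosen_rank
    r2 = estimate_rank(unfold(values, 1), thr_rank, n_iter, seed, max_rank=J).chosen_rank
    return r1, r2


# ---------------------------------------------------------------------------
# NTD


@dataclass
class NTDResult:
    A1: np.ndarray  # J x R1, ligand cell-type patterns
    A2: np.ndarray  # J x R2, receptor cell-type patterns
    core: np.ndarray  # (R1, R2, K) for NTD-2, (R1, R2, R3) for NTD-3
    A3: np.ndarray | None = None  # K x R3, NTD-3 only
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    eps: float = EPS_DEFAULT
    seed: int = 0
    n_iter: int = 0

    def reconstruct(self) -> np.ndarray:
        T = mode_dot(mode_dot(self.core, self.A1, 0), self.A2, 1)
        if self.A3 is not None:
            T = mode_dot(T, self.A3, 2)
        return T

    @property
    def loss(self) -> float:
        return float(self.loss_trace[-1])


def _init_factors(shape, ranks, update, rng, eps):
    factors = []
    for n in range(3):
        if update[n]:
            factors.append(rng.uniform(0.1, 1.0, size=(shape[n], ranks[n])))
        else:
            factors.append(None)  # identity
    core = rng.uniform(0.1, 1.0, size=tuple(ranks))
    return factors, core


def _ntd_single(
    values: np.ndarray,
    ranks: tuple[int, int, int],
    update: tuple[bool, bool, bool],
    n_iter: int,
    seed: int,
    eps: float,
    tol: float = 1e-10,
    patience: int = 5,
) -> NTDResult:
    rng = np.random.default_rng(seed)
    factors, core = _init_factors(values.shape, ranks, update, rng, eps)
    # scale the core so the initial reconstruction matches the data mean
    recon = multi_mode_dot(core, factors)
    rmean = recon.mean()
    if rmean > 0:
        core *= values.mean() / max(rmean, eps)
    losses = []
    still = 0
    for it in range(n_iter):
        for n in range(3):
            if not update[n]:
                continue
            # B = values x_{m != n} A_m^T  (identity modes pass through)
            proj = [None if (m == n or factors[m] is None) else factors[m].T for m in range(3)]
            B = multi_mode_dot(values, proj)
            num = unfold(B, n) @ unfold(core, n).T
            gram = [
                None if (m == n or factors[m] is None) else factors[m].T @ factors[m]
                for m in range(3)
            ]
            GG = multi_mode_dot(core, gram)
            den = factors[n] @ (unfold(GG, n) @ unfold(core, n).T)
            factors[n] = np.maximum(factors[n] * num / np.maximum(den, eps), eps)
        # core update
        projT = [None if f is None else f.T for f in factors]
        num = multi_mode_dot(values, projT)
        gram = [None if f is None else f.T @ f for f in factors]
        den = multi_mode_dot(core, gram)
        core = np.maximum(core * num / np.maximum(den, eps), eps)
        loss = float(np.linalg.norm(values - multi_mode_dot(core, factors)) ** 2)
        losses.append(loss)
        if it > 0:
            prev = losses[-2]
            still = still + 1 if abs(prev - loss) < tol * max(prev, 1.0) else 0
            if still >= patience:
                break
    A1 = factors[0]
    A2 = factors[1]
    A3 = factors[2]
    return NTDResult(A1, A2, core, A3, np.array(losses), eps, seed, len(losses))


def _check_tensor(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or np.any(values < 0):
        raise ValueError("NTD requires a non-negative 3-order tensor")
    if values.sum() == 0:
        raise ValueError("NTD input tensor is all-zero")
    return values


def ntd2(
    chi,
    R1: int,
    R2: int,
    n_iter: int = 100,
    seed: int = 0,
    eps: float = EPS_DEFAULT,
    n_restarts: int = 3,
) -> NTDResult:
    """NTD-2 of the CCI-tensor: core (R1, R2, K), pair mode left identity.

    Runs ``n_restarts`` seeded initializations and returns the lowest-loss
    solution (its seed is recorded on the result).
    """
    values = _check_tensor(getattr(chi, "values", chi))
    J, _, K = values.shape
    if not (1 <= R1 <= J and 1 <= R2 <= J):
        raise ValueError(f"ranks ({R1},{R2}) out of range for J={J}")
    best = None
    for r in range(n_restarts):
        res = _ntd_single(values, (R1, R2, K), (True, True, False), n_iter, seed + 10000 * r, eps)
        if best is None or res.loss < best.loss:
            best = res
    return best


def ntd3(
    chi,
    R1: int,
    R2: int,
    R3: int,
    n_iter: int = 100,
    seed: int = 0,
    eps: float = EPS_DEFAULT,
    n_restarts: int = 3,
    update_a3: bool = True,
) -> NTDResult:
    """NTD-3 of the CCI-tensor with a learned K x R3 pair factor.

    ``update_a3=False`` freezes the pair factor at the identity (requires
    R3 = K), which makes the model definitionally identical to NTD-2.
    """
    values = _check_tensor(getattr(chi, "values", chi))
    J, _, K = values.shape
    if not (1 <= R1 <= J and 1 <= R2 <= J and 1 <= R3 <= K):
        raise ValueError(f"ranks ({R1},{R2},{R3}) out of range for shape {values.shape}")
    if not update_a3 and R3 != K:
        raise ValueError("freezing A3 at the identity requires R3 = K")
    best = None
    for r in range(n_restarts):
        res = _ntd_single(
            values, (R1, R2, R3), (True, True, update_a3), n_iter, seed + 10000 * r, eps
        )
        if best is None or res.loss < best.loss:
            best = res
    return best
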